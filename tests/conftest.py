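import numpy as np
import pandas as pd
import pytest

from ffl_dynamics.expression import ExpressionMatrix
from ffl_dynamics.synthetic import SimConfig, simulate_catalog, simulate_expression


def small_config(**kw) -> SimConfig:
    """Desk-scale cohort used by most integration-style tests."""
    defaults = dict(
        n_genes=400,
        n_mirnas=15,
        n_tfs=40,
        n_controls=10,
        n_cases_per_stage=12,
        frac_de_per_stage=0.15,
        n_planted_ffls=5,
        n_decoy_edges=80,
        n_gene_sets=20,
        set_size_range=(8, 20),
        planted_enriched_sets=3,
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_expression(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_cfg, small_cohort):
    _, truth = small_cohort
    return simulate_catalog(small_cfg, truth)


def make_matrix(values: np.ndarray, groups, stages=None, feature_ids=None) -> ExpressionMatrix:
    """Hand-rolled ExpressionMatrix for unit fixtures."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"g{i}" for i in range(n_feat)]
    sample_ids = [f"s{i}" for i in range(n_samp)]
    ann = pd.DataFrame(
        {
            "group": list(groups),
            "stage": pd.array(stages if stages is not None else [pd.NA] * n_samp, dtype="Int64"),
            "recurrence": [pd.NA] * n_samp,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"), columns=sample_ids)
    return ExpressionMatrix(vals, ann)
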