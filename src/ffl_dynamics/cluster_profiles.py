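"""Expression-profile clustering of SDE genes across disease stages.

Each gene contributes a time-course profile: the control baseline (0) followed
by the per-stage mean log2 fold change versus controls.  Profiles are
standardized per gene (mean 0, sd 1), then hierarchically clustered with the
city-block (Manhattan) distance and complete linkage and cut into k clusters
(k = 2 recovers the classic "up then decay" / "down then recover" split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix, leaf ids, cluster cut."""

    linkage: np.ndarray
    leaves: list[str]
    assignments: pd.Series  # leaf id -> cluster label (1-based)
    k: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def standardize_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-row (x - mean) / sd; constant rows are excluded with a warning."""
    arr = profiles.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population sd
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning("excluding %d constant profile rows", int(constant.sum()))
    out = (arr[~constant] - mean[~constant]) / sd[~constant]
    return pd.DataFrame(out, index=profiles.index[~constant], columns=profiles.columns)


def build_profiles(tables: dict[int, pd.DataFrame], genes, mode: str = "stage-means",
                   expr=None) -> pd.DataFrame:
    """Standardized per-gene profiles over (baseline, stage 1..S).

    ``mode='stage-means'`` (default) uses per-stage mean log2fc vs control with
    a leading 0 baseline point.  ``mode='samples'`` standardizes the raw
    per-sample expression rows of ``expr`` instead.
    """
    genes = list(genes)
    if mode == "samples":
        if expr is None:
            raise ValueError("mode='samples' requires the expression matrix")
        missing = [g for g in genes if g not in expr.features]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
        return standardize_rows(expr.values.loc[genes])
    if mode != "stage-means":
        raise ValueError("mode must be 'stage-means' or 'samples'")
    stages = sorted(tables)
    for g in genes:
        for s in stages:
            if g not in tables[s].index:
                raise KeyError(f"gene {g} absent from stage {s} table")
    data = {"baseline": [0.0] * len(genes)}
    for s in stages:
        data[f"stage{s}"] = [float(tables[s].loc[g, "log2fc"]) for g in genes]
    profiles = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return standardize_rows(profiles)


def hcluster(profiles: pd.DataFrame, k: int = 2) -> Dendrogram:
    """Complete-linkage agglomeration under the city-block metric, cut at k."""
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of rows ({len(profiles)})")
    Z = linkage(profiles.to_numpy(dtype=float), method="complete", metric="cityblock")
    labels = fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(labels, index=profiles.index, name="cluster")
    return Dendrogram(Z, list(profiles.index), assignments, k)


def cluster_means(profiles: pd.DataFrame, dend: Dendrogram) -> pd.DataFrame:
    """Mean standardized profile per cluster, with a qualitative pattern label.

    The label is assigned by the sign of the first post-baseline (stage 1)
    mean: negative -> ``down-then-recover``, positive -> ``up-then-decay``.
    """
    means = profiles.groupby(dend.assignments).mean()
    stage_cols = [c for c in profiles.columns if c != "baseline"]
    first = stage_cols[0] if stage_cols else profiles.columns[0]
    means["pattern"] = ["down-then-recover" if v < 0 else "up-then-decay" for v in means[first]]
    means.index.name = "cluster"
    return means
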