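"""Expression matrix container with sample annotations.

Values are log2 intensities with features (probes or gene symbols) on rows and
samples on columns.  Sample annotations carry the case/control group, the
disease stage for case samples (controls have none), and an optional
recurrence label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """A features x samples log2 expression matrix plus sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    samples
        DataFrame indexed by sample id with columns ``group`` (``case`` or
        ``control``), ``stage`` (integer for cases, NA for controls) and
        ``recurrence`` (``yes``/``no``/NA).
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            # allow annotation supersets but keep order aligned with columns
            missing = [s for s in self.values.columns if s not in self.samples.index]
            if missing:
                raise ValueError(f"samples missing annotations: {missing[:5]}")
            self.samples = self.samples.loc[list(self.values.columns)]
        if self.samples["group"].isna().any():
            bad = list(self.samples.index[self.samples["group"].isna()])
            raise ValueError(f"missing group annotation for samples: {bad[:5]}")
        unknown = set(self.samples["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    # -- convenience accessors -------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == "control"])

    def case_samples(self, stage: int | None = None) -> list[str]:
        mask = self.samples["group"] == "case"
        if stage is not None:
            mask &= self.samples["stage"] == stage
        return list(self.samples.index[mask])

    def stages(self) -> list[int]:
        vals = self.samples.loc[self.samples["group"] == "case", "stage"].dropna()
        return sorted(int(s) for s in vals.unique())

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.samples.copy())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.samples.loc[sample_ids].copy())
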