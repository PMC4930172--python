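"""Per-stage differential expression with empirical-Bayes moderated t-statistics.

Each stage's case samples are compared against the single shared control group
(controls have no time point).  The statistic is the classic moderated t: the
per-gene residual variance s_g^2 (pooled, df_g = n1 + n2 - 2) is shrunk toward
a prior variance s0^2 with prior degrees of freedom d0,

    s_tilde_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)
    t_tilde_g   = log2fc_g / (s_tilde_g * sqrt(1/n1 + 1/n2))

with p-values from a t distribution on df_g + d0 degrees of freedom.  The
prior (d0, s0^2) is estimated by moment-matching the scaled-chi-square (i.e.
scaled F) distribution of the observed s_g^2 on the log scale, the standard
empirical-Bayes fit for microarray linear models.  With d0 = 0 the statistic
reduces exactly to the ordinary pooled-variance two-sample t.

Genes are called significantly differentially expressed (SDE) when the
BH-adjusted p-value is below ``adj_p_threshold`` (strict) and the linear fold
change 2^|log2fc| exceeds ``fc_threshold`` (strict), in either direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)


@dataclass
class DEConfig:
    """Thresholds and moderation settings for SDE calling."""

    adj_p_threshold: float = 0.001
    fc_threshold: float = 1.2  # linear scale
    moderation: str = "moderated"  # or "ordinary"

    def __post_init__(self) -> None:
        if self.adj_p_threshold <= 0:
            raise ValueError("adj_p_threshold must be > 0")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1 (linear scale)")
        if self.moderation not in ("moderated", "ordinary"):
            raise ValueError("moderation must be 'moderated' or 'ordinary'")


def _trigamma_inverse(y: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(-dif / x < 1e-12):
            break
    return x


def fit_scaled_chisq_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled chi-square prior to observed gene variances.

    Returns (d0, s0sq): the prior degrees of freedom (possibly ``inf``) and the
    prior variance.  Matching is done on z = log(s2): under the model z is a
    shifted log-F variate whose mean and variance are digamma/trigamma
    expressions in df and d0.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        # not enough informative genes to estimate a prior
        return 0.0, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.sum((e - emean) ** 2) / (len(e) - 1))
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(evar))
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(emean))
    return d0, s0sq


def moderated_t_test(m, stage: int, cfg: DEConfig | None = None) -> pd.DataFrame:
    """Differential expression of stage-``stage`` cases versus all controls.

    Returns a table with one row per gene: group means, log2 fold change,
    linear fold change, residual variance, moderated statistic, raw and
    BH-adjusted p-values, and the SDE flag.
    """
    cfg = cfg or DEConfig()
    case_ids = m.case_samples(stage)
    ctrl_ids = m.control_samples()
    n1, n2 = len(case_ids), len(ctrl_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"stage {stage}: need >=2 samples per group (got {n1} cases, {n2} controls)")

    case = m.values[case_ids].to_numpy(dtype=float)
    ctrl = m.values[ctrl_ids].to_numpy(dtype=float)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    lfc = mean_case - mean_ctrl

    df_resid = n1 + n2 - 2
    ss = ((case - mean_case[:, None]) ** 2).sum(axis=1) + ((ctrl - mean_ctrl[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if cfg.moderation == "moderated":
        d0, s0sq = fit_scaled_chisq_prior(s2, df_resid)
    else:
        d0, s0sq = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / se
    # degenerate genes: no variance anywhere
    zero_se = se == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (lfc == 0), 0.0, t)
        t = np.where(zero_se & (lfc != 0), np.sign(lfc) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isfinite(t) | np.isinf(t), p, 1.0)

    table = pd.DataFrame(
        {
            "gene": m.features,
            "stage": stage,
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "log2fc": lfc,
            "fold_change": np.exp2(np.abs(lfc)),
            "s2": s2,
            "df": float(df_resid),
            "d0": d0,
            "s2_post": s2_post,
            "t": t,
            "p": p,
        }
    ).set_index("gene")
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["sde"] = (table["adj_p"] < cfg.adj_p_threshold) & (table["fold_change"] > cfg.fc_threshold)
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    q(i) = min_{k >= i} ( m * p(k) / k ) over the ascending order, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_sde(table: pd.DataFrame, cfg: DEConfig | None = None) -> set[str]:
    """Gene ids with adjusted p < threshold and linear fold change > threshold."""
    cfg = cfg or DEConfig()
    mask = (table["adj_p"] < cfg.adj_p_threshold) & (table["fold_change"] > cfg.fc_threshold)
    return set(table.index[mask])


def sde_summary(tables: dict[int, pd.DataFrame], cfg: DEConfig | None = None) -> dict:
    """Per-stage SDE counts, union size, and the cross-stage intersection set."""
    if len(tables) < 2:
        raise ValueError("need >=2 stages to summarize")
    sets = {stage: call_sde(t, cfg) for stage, t in tables.items()}
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    return {
        "per_stage": {stage: len(s) for stage, s in sorted(sets.items())},
        "union": len(union),
        "intersection": inter,
        "sets": sets,
    }


def top_k(tables: dict[int, pd.DataFrame], k: int, candidates=None) -> list[str]:
    """Top-k genes ranked by minimum adjusted p across stages.

    Ties broken by larger maximum \\|log2fc\\| across stages, then by gene id.
    ``candidates`` restricts ranking to a subset (e.g. the shared SDE set);
    by default every SDE gene of any stage is a candidate.
    """
    if candidates is None:
        candidates = set().union(*(call_sde(t) for t in tables.values()))
    candidates = sorted(candidates)
    if k > len(candidates):
        logger.warning("requested top %d of %d candidates; truncating", k, len(candidates))
        k = len(candidates)
    min_p = {g: min(t.loc[g, "adj_p"] for t in tables.values() if g in t.index) for g in candidates}
    max_lfc = {g: max(abs(t.loc[g, "log2fc"]) for t in tables.values() if g in t.index) for g in candidates}
    ranked = sorted(candidates, key=lambda g: (min_p[g], -max_lfc[g], g))
    return ranked[:k]
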