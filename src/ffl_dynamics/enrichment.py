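"""Hypergeometric gene-set enrichment with subpathway collapsing.

For each stage's SDE set the over-representation of every supplied gene set is
scored with the one-sided hypergeometric upper tail

    p = P(X >= x) = sum_{i=x}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n)

where N is the background universe size, K the set size, n the SDE count and
x the overlap — equivalent to a one-sided Fisher exact test on the 2x2 table.
BH adjustment is applied across all sets of a collection; a set is significant
at adjusted p < alpha (default 0.05).  When several significant subpathways
share a parent pathway only the minimum-adjusted-p one is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ffl_dynamics.diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe, with optional parent ids."""

    sets: dict[str, set[str]]
    universe: set[str]
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [sid for sid, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")



def hypergeom_pval(x: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= x) for overlap x, universe N, set size K, draw n."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def hypergeom_enrich(sde: set[str], collection: GeneSetCollection, alpha: float = 0.05,
                     stage: int | None = None) -> pd.DataFrame:
    """Enrichment table for one SDE set against a gene-set collection."""
    if not collection.universe:
        raise ValueError("empty background universe")
    dropped = len(sde - collection.universe)
    if dropped:
        logger.info("dropping %d SDE genes outside the universe", dropped)
    sde_in = sde & collection.universe
    if not sde_in:
        raise ValueError("no SDE genes inside the background universe")

    N = len(collection.universe)
    n = len(sde_in)
    rows = []
    for set_id in sorted(collection.sets):
        members = collection.sets[set_id] & collection.universe
        K = len(members)
        x = len(members & sde_in)
        rows.append(
            {
                "set_id": set_id,
                "stage": stage,
                "overlap": x,
                "set_size": K,
                "sde_size": n,
                "universe_size": N,
                "p": hypergeom_pval(x, N, K, n),
                "parent_pathway_id": collection.parents.get(set_id, ""),
            }
        )
    table = pd.DataFrame(rows).set_index("set_id")
    table["adj_p"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["adj_p"] < alpha
    return table


def collapse_subpathways(table: pd.DataFrame) -> pd.DataFrame:
    """Keep, per parent pathway, only the minimum-adjusted-p significant subpathway.

    Ties are broken toward the lexicographically smallest set id.
    Non-significant rows are dropped.
    """
    sig = table[table["significant"]].copy()
    if sig.empty:
        return sig
    sig = sig.sort_values(["adj_p", "set_id"], kind="mergesort")
    # rows without a parent id are their own parent (never collapsed together)
    parent = sig["parent_pathway_id"].where(sig["parent_pathway_id"] != "", sig.index.to_series())
    keep = ~parent.duplicated(keep="first")
    return sig[keep].sort_index()


def significance_matrix(tables: dict[int, pd.DataFrame], alpha: float = 0.05,
                        filter_pattern: str | None = None) -> pd.DataFrame:
    """Set x stage matrix of adjusted p-values with 'ns'/'NA' markers.

    Cells hold the adjusted p when significant, ``'ns'`` when tested but not
    significant, and ``'NA'`` when the set had zero overlap with the stage's
    SDE genes.  ``filter_pattern`` removes sets whose id contains the pattern
    (case-insensitive), e.g. ``'cancer'``.
    """
    if not tables:
        raise ValueError("need >=1 stage table")
    stages = sorted(tables)
    all_sets = sorted(set().union(*(set(t.index) for t in tables.values())))
    if filter_pattern:
        before = len(all_sets)
        all_sets = [s for s in all_sets if filter_pattern.lower() not in s.lower()]
        if not all_sets:
            logger.warning("filter %r removed all %d sets", filter_pattern, before)
    # keep only sets significant in >=1 stage (the matrix shows enriched sets)
    enriched = [
        s
        for s in all_sets
        if any(s in tables[st].index and bool(tables[st].loc[s, "significant"]) for st in stages)
    ]
    out = pd.DataFrame(index=pd.Index(enriched, name="set_id"), columns=[f"stage{s}" for s in stages], dtype=object)
    for s in stages:
        t = tables[s]
        for set_id in enriched:
            if set_id not in t.index:
                out.loc[set_id, f"stage{s}"] = "NA"
            elif t.loc[set_id, "overlap"] == 0:
                out.loc[set_id, f"stage{s}"] = "NA"
            elif t.loc[set_id, "adj_p"] < alpha:
                out.loc[set_id, f"stage{s}"] = float(t.loc[set_id, "adj_p"])
            else:
                out.loc[set_id, f"stage{s}"] = "ns"
    return out
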