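"""Probe-level filtering and probe-to-gene collapsing.

The preprocessing chain mirrors standard microarray practice for processed
(log2) matrices: drop probes that never reach a minimum intensity, drop probes
annotated to several genes (ambiguous) or to none, average the remaining
probes per gene, and keep protein-coding genes.  The intended order is

    filter_low_intensity -> drop_multigene_probes -> collapse_to_genes
        -> keep_protein_coding

and every step is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ffl_dynamics.expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ProbeMap:
    """Probe annotations: probe -> gene symbols, gene -> protein_coding flag.

    A probe may map to zero (unannotated) or several gene symbols.  A gene
    without a biotype entry is treated as non-coding.
    """

    probes: dict[str, tuple[str, ...]]
    coding: dict[str, bool]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeMap":
        probes: dict[str, list[str]] = {}
        coding: dict[str, bool] = {}
        for probe, gene, biotype in df[["probe_id", "gene_symbol", "biotype"]].itertuples(index=False):
            probes.setdefault(probe, [])
            if gene:
                if gene not in probes[probe]:
                    probes[probe].append(gene)
                coding[gene] = coding.get(gene, False) or (biotype == "protein_coding")
        return cls({p: tuple(g) for p, g in probes.items()}, coding)

    def genes_for(self, probe: str) -> tuple[str, ...]:
        return self.probes[probe]


def filter_low_intensity(m: ExpressionMatrix, threshold: float = 7.0) -> ExpressionMatrix:
    """Keep features whose maximum log2 intensity over all samples is >= threshold."""
    keep = m.values.max(axis=1) >= threshold
    if not keep.any():
        logger.warning("intensity filter at %.3g removed every feature", threshold)
    return ExpressionMatrix(m.values.loc[keep], m.samples.copy())


def drop_multigene_probes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Remove probes annotated to >= 2 distinct genes, and unannotated probes."""
    missing = [p for p in m.features if p not in pm.probes]
    if missing:
        raise KeyError(f"probes absent from probe map: {missing[:10]}")
    keep = [p for p in m.features if len(pm.genes_for(p)) == 1]
    return ExpressionMatrix(m.values.loc[keep], m.samples.copy())


def collapse_to_genes(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Average probes per gene; rows sorted by gene symbol.

    Requires every probe to map to exactly one gene (run
    :func:`drop_multigene_probes` first).
    """
    multi = [p for p in m.features if len(pm.genes_for(p)) != 1]
    if multi:
        raise ValueError(f"probes not single-gene, run drop_multigene_probes first: {multi[:10]}")
    genes = pd.Index([pm.genes_for(p)[0] for p in m.features], name="feature_id")
    collapsed = m.values.groupby(genes).mean().sort_index()
    return ExpressionMatrix(collapsed, m.samples.copy())


def keep_protein_coding(m: ExpressionMatrix, pm: ProbeMap) -> ExpressionMatrix:
    """Restrict a gene-level matrix to genes flagged protein-coding."""
    flags = []
    unflagged = []
    for g in m.features:
        if g not in pm.coding:
            unflagged.append(g)
        flags.append(pm.coding.get(g, False))
    if unflagged:
        logger.warning("%d genes without biotype treated as non-coding (e.g. %s)", len(unflagged), unflagged[:5])
    keep = pd.Series(flags, index=m.features)
    if not keep.any():
        logger.warning("no protein-coding genes retained")
    return ExpressionMatrix(m.values.loc[keep], m.samples.copy())


def preprocess(m: ExpressionMatrix, pm: ProbeMap, intensity_threshold: float = 7.0) -> ExpressionMatrix:
    """Full probe-to-gene preprocessing chain."""
    m = filter_low_intensity(m, intensity_threshold)
    m = drop_multigene_probes(m, pm)
    m = collapse_to_genes(m, pm)
    return keep_protein_coding(m, pm)
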