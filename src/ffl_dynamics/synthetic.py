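"""Synthetic staged case/control cohort with known ground truth.

The generator emulates a three-stage disease cohort profiled against a single
shared control group (controls carry no time point), together with the
regulatory inputs the pipeline consumes:

* a gene-level log2 expression matrix with a planted set of differentially
  expressed genes whose effect decays geometrically across stages (sharp
  change at the acute stage, slow change afterwards);
* an optional probe-level expansion exercising the preprocessing chain
  (duplicate probes with mean-zero offsets, multi-gene probes, unannotated
  probes, non-coding genes, low-intensity features);
* a typed interaction catalog containing planted miRNA-TF feed-forward loops
  plus decoy edges, rejection-sampled so that the planted loops are exactly
  the enumerable set among DE nodes;
* gene-set collections with planted enrichment and a subpathway -> parent
  pathway map;
* a planted two-gene classifier signal (the TF and target of the first planted
  loop), with an extra recurrence signal among case samples.

Identical (config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ffl_dynamics import io as fio
from ffl_dynamics.enrichment import GeneSetCollection
from ffl_dynamics.expression import ExpressionMatrix
from ffl_dynamics.network import InteractionCatalog, Motif, build_catalog

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


class GenerationError(RuntimeError):
    """Rejection sampling could not satisfy a structural constraint."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the emulated study: 14 controls versus 28 cases per stage
    over 3 stages, 2000 genes with 10% planted DE at |log2FC| = 1 and
    per-gene noise sd 0.5, 10 planted feed-forward loops among 500 decoy
    edges, and a two-gene diagnostic signal at 2 sd separation.
    """

    n_genes: int = 2000
    n_mirnas: int = 40
    n_tfs: int = 150
    n_controls: int = 14
    n_cases_per_stage: int = 28
    n_stages: int = 3
    frac_de_per_stage: float = 0.10
    de_log2fc: float = 1.0
    noise_sd: float = 0.5
    n_planted_ffls: int = 10
    n_decoy_edges: int = 500
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 40)
    planted_enriched_sets: int = 5
    biomarker_delta: float = 2.0
    seed: int = 0
    # secondary knobs (fixed design choices, exposed for testing)
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    decay: float = 0.7
    frac_low_intensity: float = 0.05
    low_intensity_mean: float = 5.0
    enriched_de_fraction: float = 0.6
    recurrence_fraction: float = 0.25
    decoy_retry_factor: int = 100

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_tfs", "n_controls", "n_cases_per_stage", "n_stages"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("n_planted_ffls", "n_decoy_edges", "n_gene_sets", "planted_enriched_sets"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 < self.frac_de_per_stage < 1:
            raise ConfigurationError("frac_de_per_stage must lie in (0, 1)")
        if self.de_log2fc < 0:
            raise ConfigurationError("de_log2fc must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.n_tfs >= self.n_genes:
            raise ConfigurationError("n_tfs must be smaller than n_genes")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("set_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ConfigurationError("set_size_range exceeds the gene universe (n_genes)")
        if self.planted_enriched_sets > self.n_gene_sets:
            raise ConfigurationError("planted_enriched_sets cannot exceed n_gene_sets")
        n_de = round(self.frac_de_per_stage * self.n_genes)
        if self.n_planted_ffls > min(self.n_mirnas, self.n_tfs, n_de // 2):
            raise ConfigurationError("n_planted_ffls too large for n_mirnas/n_tfs/planted DE pool")

    # deterministic id universes -------------------------------------------------

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def tf_ids(self) -> list[str]:
        return self.gene_ids()[: self.n_tfs]

    def mirna_ids(self) -> list[str]:
        return [f"hsa-mir-{i:03d}" for i in range(1, self.n_mirnas + 1)]


@dataclass
class GroundTruth:
    """Planted structure: DE genes, FFLs, enriched sets, biomarkers, labels."""

    de_genes_per_stage: dict[int, set[str]]
    de_signs: dict[str, int]
    planted_ffls: list[Motif]
    enriched_sets: list[str] = field(default_factory=list)
    biomarker_genes: tuple[str, str] = ("", "")
    class_labels: dict[str, str] = field(default_factory=dict)
    low_intensity_genes: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "de_genes_per_stage": {str(s): sorted(g) for s, g in self.de_genes_per_stage.items()},
            "de_signs": dict(sorted(self.de_signs.items())),
            "planted_ffls": [list(m) for m in self.planted_ffls],
            "enriched_sets": sorted(self.enriched_sets),
            "biomarker_genes": list(self.biomarker_genes),
            "class_labels": dict(sorted(self.class_labels.items())),
            "low_intensity_genes": sorted(self.low_intensity_genes),
        }


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# -- expression ---------------------------------------------------------------

def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Gene-level cohort matrix plus ground truth.

    Controls are gene-wise Normal(mu_g, noise_sd^2); case samples at stage s
    shift the planted DE genes by sign_g * de_log2fc * decay^(s-1).  The two
    biomarker genes (TF and target of the first planted loop when loops are
    planted) get a non-decaying shift of biomarker_delta * noise_sd, plus half
    that again for recurrent cases.
    """
    rng = _rng(config, 0)
    genes = config.gene_ids()
    tfs = config.tf_ids()
    non_tf_genes = genes[config.n_tfs :]

    # planted FFL members are DE by construction
    ffl_tfs = [str(x) for x in rng.choice(tfs, size=config.n_planted_ffls, replace=False)] if config.n_planted_ffls else []
    ffl_genes = (
        [str(x) for x in rng.choice(non_tf_genes, size=config.n_planted_ffls, replace=False)]
        if config.n_planted_ffls
        else []
    )
    planted_ffls = [Motif(m, t, g) for m, t, g in zip(config.mirna_ids(), ffl_tfs, ffl_genes)]

    n_de = round(config.frac_de_per_stage * config.n_genes)
    forced = list(dict.fromkeys(ffl_tfs + ffl_genes))
    remaining_pool = [g for g in genes if g not in set(forced)]
    extra = [str(x) for x in rng.choice(remaining_pool, size=n_de - len(forced), replace=False)]
    de_pool = forced + extra

    # low-intensity fillers never overlap DE genes or biomarkers
    eligible_low = [g for g in genes if g not in set(de_pool)]
    n_low = min(int(round(config.frac_low_intensity * config.n_genes)), len(eligible_low))
    low_genes = {str(x) for x in rng.choice(eligible_low, size=n_low, replace=False)} if n_low else set()

    mu = pd.Series(rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes), index=genes)
    mu[sorted(low_genes)] = rng.normal(config.low_intensity_mean, 0.5, len(low_genes))

    signs = {g: int(s) for g, s in zip(de_pool, rng.choice([-1, 1], size=len(de_pool)))}
    biomarkers = (
        (planted_ffls[0].tf, planted_ffls[0].gene) if planted_ffls else tuple(de_pool[:2])
    )

    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    ann_rows: list[dict] = []
    class_labels: dict[str, str] = {}

    for i in range(1, config.n_controls + 1):
        sid = f"ctrl{i:02d}"
        sample_ids.append(sid)
        columns.append(mu.to_numpy() + rng.normal(0.0, config.noise_sd, config.n_genes))
        ann_rows.append({"sample_id": sid, "group": "control", "stage": pd.NA, "recurrence": pd.NA})
        class_labels[sid] = "control"

    recurrent = rng.random(config.n_cases_per_stage) < config.recurrence_fraction
    null_model = config.de_log2fc == 0  # full null: no planted signal at all
    shift_base = pd.Series(0.0, index=mu.index)
    for g, s in signs.items():
        shift_base[g] = float(s)

    for stage in range(1, config.n_stages + 1):
        stage_effect = config.de_log2fc * config.decay ** (stage - 1)
        shift = shift_base * stage_effect
        if not null_model:
            # biomarker signal is stage-constant and sign-positive
            for b in biomarkers:
                shift[b] = config.biomarker_delta * config.noise_sd
        for p in range(1, config.n_cases_per_stage + 1):
            sid = f"case_p{p:02d}_s{stage}"
            sample_ids.append(sid)
            extra_shift = shift.copy()
            if recurrent[p - 1] and not null_model:
                for b in biomarkers:
                    extra_shift[b] += 0.5 * config.biomarker_delta * config.noise_sd
            columns.append(mu.to_numpy() + extra_shift.to_numpy() + rng.normal(0.0, config.noise_sd, config.n_genes))
            ann_rows.append(
                {
                    "sample_id": sid,
                    "group": "case",
                    "stage": stage,
                    "recurrence": "yes" if recurrent[p - 1] else "no",
                }
            )
            class_labels[sid] = "case"

    values = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(genes, name="feature_id"), columns=sample_ids
    )
    samples = pd.DataFrame(ann_rows).set_index("sample_id")
    samples["stage"] = samples["stage"].astype("Int64")

    de_sets = {s: set(de_pool) for s in range(1, config.n_stages + 1)} if config.de_log2fc > 0 else {
        s: set() for s in range(1, config.n_stages + 1)
    }
    truth = GroundTruth(
        de_genes_per_stage=de_sets,
        de_signs=signs if config.de_log2fc > 0 else {},
        planted_ffls=planted_ffls,
        biomarker_genes=biomarkers,
        class_labels=class_labels,
        low_intensity_genes=low_genes,
    )
    return ExpressionMatrix(values, samples), truth


# -- probe-level expansion ----------------------------------------------------

def expand_to_probes(config: SimConfig, expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[tuple[str, str, str]]]:
    """Probe-level matrix + probe-map rows exercising the preprocessing chain.

    10% of genes get two probes with mean-zero offsets (collapsing recovers the
    gene value exactly); a handful of multi-gene, unannotated and non-coding
    probes are added for the filters to remove.
    """
    rng = _rng(config, 3)
    genes = list(expr.features)
    dup = set(rng.choice(genes, size=max(1, len(genes) // 10), replace=False))
    rows: list[tuple[str, str, str]] = []
    probe_values: dict[str, np.ndarray] = {}
    for g in genes:
        base = expr.values.loc[g].to_numpy()
        if g in dup:
            delta = rng.uniform(0.1, 0.5)
            probe_values[f"{g}_p1"] = base + delta
            probe_values[f"{g}_p2"] = base - delta
            rows += [(f"{g}_p1", g, "protein_coding"), (f"{g}_p2", g, "protein_coding")]
        else:
            probe_values[f"{g}_p1"] = base
            rows.append((f"{g}_p1", g, "protein_coding"))
    n_samples = expr.n_samples
    for j in range(1, 11):
        pid = f"junk_multi{j:02d}"
        probe_values[pid] = rng.normal(10.0, 1.0, n_samples)
        ga, gb = rng.choice(genes, size=2, replace=False)
        rows += [(pid, ga, "protein_coding"), (pid, gb, "protein_coding")]
    for j in range(1, 11):
        pid = f"junk_unannot{j:02d}"
        probe_values[pid] = rng.normal(10.0, 1.0, n_samples)
        rows.append((pid, "", ""))
    for j in range(1, 11):
        pid = f"nc{j:02d}_p1"
        probe_values[pid] = rng.normal(10.0, 1.0, n_samples)
        rows.append((pid, f"NC{j:02d}", "lincRNA"))
    values = pd.DataFrame(probe_values, index=expr.values.columns).T
    values.index.name = "feature_id"
    return ExpressionMatrix(values, expr.samples.copy()), rows


# -- interaction catalog ------------------------------------------------------

def _completes_only_planted(edges: dict[str, set[tuple[str, str]]], sde: set[str],
                            mirnas: set[str], planted: set[Motif]) -> bool:
    """Whether the enumerable FFL set of the edge maps equals the planted set."""
    mt: dict[str, set[str]] = {}
    for s, t in edges["mirna_tf"]:
        mt.setdefault(s, set()).add(t)
    tm = edges["tf_mirna"]
    mtarg: dict[str, set[str]] = {}
    for s, t in edges["mirna_gene"] | edges["mirna_tf"]:
        mtarg.setdefault(s, set()).add(t)
    ttarg: dict[str, set[str]] = {}
    for s, t in edges["tf_gene"]:
        ttarg.setdefault(s, set()).add(t)
    found: set[Motif] = set()
    for m, ts in mt.items():
        for t in ts:
            if t not in sde or (t, m) not in tm:
                continue
            for g in mtarg.get(m, set()) & ttarg.get(t, set()) & sde:
                if g not in mirnas:
                    found.add(Motif(m, t, g))
    return found == planted


def simulate_catalog(config: SimConfig, truth: GroundTruth) -> InteractionCatalog:
    """Typed edge catalog: planted FFL edges plus rejection-sampled decoys.

    Decoys are drawn uniformly over edge types and role-consistent endpoints;
    a decoy is rejected when it would complete a feed-forward loop (beyond the
    planted ones) among the union of per-stage DE genes.  Sampling is bounded
    at ``decoy_retry_factor`` times the requested decoy count.
    """
    rng = _rng(config, 1)
    mirnas = config.mirna_ids()
    tfs = config.tf_ids()
    genes = config.gene_ids()
    sde_union = set().union(*truth.de_genes_per_stage.values()) if truth.de_genes_per_stage else set()
    # only loops whose TF and target are DE are enumerable downstream
    planted = {mo for mo in truth.planted_ffls if mo.tf in sde_union and mo.gene in sde_union}
    mirna_set = set(mirnas)

    edges: dict[str, set[tuple[str, str]]] = {t: set() for t in ("mirna_gene", "mirna_tf", "tf_gene", "tf_mirna")}
    records: list[tuple[str, str, str, str]] = []
    for m, t, g in truth.planted_ffls:
        for etype, (s, d) in (
            ("mirna_tf", (m, t)),
            ("tf_mirna", (t, m)),
            ("mirna_gene", (m, g)),
            ("tf_gene", (t, g)),
        ):
            if (s, d) not in edges[etype]:
                edges[etype].add((s, d))
                records.append((s, d, etype, "planted"))

    etypes = ("mirna_gene", "mirna_tf", "tf_gene", "tf_mirna")
    added = 0
    attempts = 0
    max_attempts = config.decoy_retry_factor * max(config.n_decoy_edges, 1)
    while added < config.n_decoy_edges:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not place {config.n_decoy_edges} decoy edges within "
                f"{max_attempts} attempts; reduce n_decoy_edges"
            )
        attempts += 1
        etype = etypes[rng.integers(len(etypes))]
        if etype == "mirna_gene":
            s, d = mirnas[rng.integers(len(mirnas))], genes[rng.integers(len(genes))]
        elif etype == "mirna_tf":
            s, d = mirnas[rng.integers(len(mirnas))], tfs[rng.integers(len(tfs))]
        elif etype == "tf_gene":
            s, d = tfs[rng.integers(len(tfs))], genes[rng.integers(len(genes))]
        else:
            s, d = tfs[rng.integers(len(tfs))], mirnas[rng.integers(len(mirnas))]
        if s == d or (s, d) in edges[etype]:
            continue
        edges[etype].add((s, d))
        if _completes_only_planted(edges, sde_union, mirna_set, planted):
            records.append((s, d, etype, "decoy"))
            added += 1
        else:
            edges[etype].remove((s, d))

    df = pd.DataFrame(records, columns=["source_id", "target_id", "edge_type", "evidence"])
    return build_catalog(df, set(tfs))


# -- gene sets ----------------------------------------------------------------

def simulate_gene_sets(config: SimConfig, truth: GroundTruth) -> GeneSetCollection:
    """Gene-set collection with planted enrichment in the stage-1 DE genes.

    Planted sets draw ``enriched_de_fraction`` of their members from the
    stage-1 DE pool; the rest and all decoy sets are uniform over the
    universe.  Every pair of consecutive subpathways shares a parent pathway.
    """
    rng = _rng(config, 2)
    genes = config.gene_ids()
    de1 = sorted(truth.de_genes_per_stage.get(1, set()))
    non_de = [g for g in genes if g not in set(de1)]
    lo, hi = config.set_size_range
    sets: dict[str, set[str]] = {}
    parents: dict[str, str] = {}
    truth.enriched_sets = []
    for i in range(1, config.n_gene_sets + 1):
        sid = f"SP{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i <= config.planted_enriched_sets and de1:
            n_from_de = min(max(1, int(np.ceil(config.enriched_de_fraction * size))), len(de1))
            members = set(rng.choice(de1, size=n_from_de, replace=False))
            fill = [g for g in non_de if g not in members]
            members |= set(rng.choice(fill, size=max(0, size - n_from_de), replace=False))
            truth.enriched_sets.append(sid)
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        sets[sid] = members
        parents[sid] = f"P{(i - 1) // 2 + 1:03d}"
    return GeneSetCollection(sets, set(genes), parents)


# -- writers ------------------------------------------------------------------

def write_inputs(outdir, config: SimConfig, with_probes: bool = True) -> dict[str, Path]:
    """Generate the full input bundle and write it as plain-text files.

    Returns the path of every artifact written.  Identical (config, seed)
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate_expression(config)
    catalog = simulate_catalog(config, truth)
    collection = simulate_gene_sets(config, truth)

    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "catalog": outdir / "catalog.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "parent_map": outdir / "subpathway_parents.tsv",
        "tf_list": outdir / "tf_list.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    fio.write_expression(expr, paths["expression"], paths["samples"])
    fio.write_catalog_edges(catalog.edges, paths["catalog"])
    fio.write_gmt({sid: sorted(collection.sets[sid]) for sid in sorted(collection.sets)}, paths["gene_sets"])
    fio.write_parent_map(collection.parents, paths["parent_map"])
    fio.write_tf_list(config.tf_ids(), paths["tf_list"])
    fio.write_ground_truth(truth, paths["ground_truth"])
    if with_probes:
        probes, rows = expand_to_probes(config, expr)
        paths["probe_expression"] = outdir / "probe_expression.tsv"
        paths["probe_map"] = outdir / "probe_map.tsv"
        fio.write_expression(probes, paths["probe_expression"], outdir / "samples.tsv")
        fio.write_probe_map(rows, paths["probe_map"])
    return paths
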