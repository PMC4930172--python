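"""End-to-end orchestration of the staged FFL-network analysis.

``run_all`` executes preprocess -> per-stage differential expression ->
profile clustering -> per-stage enrichment -> per-stage motif/network
construction -> cross-stage comparison -> biomarker classification, writing
every artifact under one output directory together with a manifest (input
hashes, config echo, package version).  Reruns on identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ffl_dynamics import __version__
from ffl_dynamics import io as fio
from ffl_dynamics import network as net
from ffl_dynamics.classify import evaluate_panel
from ffl_dynamics.cluster_profiles import build_profiles, cluster_means, hcluster
from ffl_dynamics.diffexpr import DEConfig, call_sde, moderated_t_test, sde_summary, top_k
from ffl_dynamics.dynamics import containment_check, extract_specific, venn_decompose
from ffl_dynamics.enrichment import GeneSetCollection, collapse_subpathways, hypergeom_enrich, significance_matrix
from ffl_dynamics.preprocess import ProbeMap, preprocess

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Paths and options for a full run.  Loadable from YAML/JSON."""

    expression: str
    samples: str
    catalog: str
    tf_list: str
    gene_sets: str
    parent_map: str
    outdir: str
    probe_map: str | None = None  # expression is probe-level iff given
    intensity_threshold: float = 7.0
    adj_p_threshold: float = 0.001
    fc_threshold: float = 1.2
    moderation: str = "moderated"
    enrich_alpha: float = 0.05
    enrich_filter: str | None = None
    top_n_profiles: int = 100
    n_clusters: int = 2
    degree_mode: str = "collapsed"
    bc_mode: str = "undirected"
    hub_fraction: float = 0.20
    allow_self_target: bool = True
    panel_genes: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "expression": self.expression,
            "samples": self.samples,
            "catalog": self.catalog,
            "tf_list": self.tf_list,
            "gene_sets": self.gene_sets,
            "parent_map": self.parent_map,
        }
        if self.probe_map:
            paths["probe_map"] = self.probe_map
        return paths

    def validate(self) -> None:
        for name, p in self.input_paths().items():
            if not Path(p).is_file():
                raise PipelineError(f"input '{name}' missing: {p}")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path, **kw) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", **kw)


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in vars(cfg).items()},
        "inputs": {name: _sha256(p) for name, p in cfg.input_paths().items()},
        "stages": [],
        "summary": {},
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    # 1. preprocess ------------------------------------------------------------
    stage("preprocess")
    try:
        expr = fio.read_expression(cfg.expression, cfg.samples)
        if cfg.probe_map:
            pm = ProbeMap.from_frame(fio.read_probe_map(cfg.probe_map))
            expr = preprocess(expr, pm, cfg.intensity_threshold)
        fio.write_expression(expr, out / "expression_genes.tsv", out / "samples_used.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(f"stage preprocess failed on {cfg.expression}: {exc}") from exc
    manifest["summary"]["genes_analyzed"] = expr.n_features

    # 2. differential expression -------------------------------------------------
    stage("diffexpr")
    de_cfg = DEConfig(cfg.adj_p_threshold, cfg.fc_threshold, cfg.moderation)
    stages_list = expr.stages()
    if not stages_list:
        raise PipelineError("stage diffexpr: no case stages found in sample annotations")
    tables = {}
    for s in stages_list:
        t = moderated_t_test(expr, s, de_cfg)
        tables[s] = t
        _write_tsv(
            t[["log2fc", "fold_change", "t", "p", "adj_p", "sde"]], out / f"de_stage{s}.tsv"
        )
        (out / f"sde_stage{s}.txt").write_text("".join(f"{g}\n" for g in sorted(call_sde(t, de_cfg))))
    summary = sde_summary(tables, de_cfg)
    manifest["summary"]["sde_per_stage"] = {str(k): v for k, v in summary["per_stage"].items()}
    manifest["summary"]["sde_union"] = summary["union"]
    manifest["summary"]["sde_shared"] = len(summary["intersection"])

    # 3. profile clustering ------------------------------------------------------
    stage("cluster")
    ranked = top_k(tables, min(cfg.top_n_profiles, max(1, summary["union"])))
    if len(ranked) >= cfg.n_clusters:
        profiles = build_profiles(tables, ranked)
        dend = hcluster(profiles, cfg.n_clusters)
        _write_tsv(dend.assignments.to_frame(), out / "cluster_assignments.tsv")
        _write_tsv(cluster_means(profiles, dend), out / "cluster_means.tsv")
        manifest["summary"]["clustered_genes"] = len(profiles)
    else:
        logger.warning("too few SDE genes to cluster (%d)", len(ranked))
        manifest["summary"]["clustered_genes"] = 0

    # 4. enrichment ---------------------------------------------------------------
    stage("enrich")
    sets = fio.read_gmt(cfg.gene_sets)
    parents = fio.read_parent_map(cfg.parent_map)
    universe = set(expr.features)  # background = all analyzed genes
    collection = GeneSetCollection({k: set(v) for k, v in sets.items()}, universe, parents)
    enr_tables = {}
    for s in stages_list:
        et = hypergeom_enrich(summary["sets"][s], collection, cfg.enrich_alpha, stage=s)
        enr_tables[s] = et
        _write_tsv(et, out / f"enrichment_stage{s}.tsv")
        _write_tsv(collapse_subpathways(et), out / f"enrichment_stage{s}_collapsed.tsv")
    sig = significance_matrix(enr_tables, cfg.enrich_alpha, cfg.enrich_filter)
    _write_tsv(sig, out / "enrichment_matrix.tsv")
    manifest["summary"]["enriched_sets_per_stage"] = {
        str(s): int(enr_tables[s]["significant"].sum()) for s in stages_list
    }

    # 5. motifs and networks ------------------------------------------------------
    stage("network")
    catalog = net.load_catalog([cfg.catalog], cfg.tf_list)
    nets = {}
    motif_counts = {}
    for s in stages_list:
        motifs = net.enumerate_motifs(catalog, summary["sets"][s], cfg.allow_self_target)
        motif_counts[str(s)] = len(motifs)
        rn = net.merge_motifs(motifs, s)
        nets[s] = rn
        _write_tsv(net.edge_table(rn), out / f"network_stage{s}_edges.tsv", index=False)
        _write_tsv(net.node_table(rn, cfg.hub_fraction, cfg.degree_mode, cfg.bc_mode), out / f"network_stage{s}_nodes.tsv")
    manifest["summary"]["motifs_per_stage"] = motif_counts
    manifest["summary"]["network_sizes"] = {
        str(s): {"nodes": len(nets[s].nodes), "edges": len(nets[s].edge_records())} for s in stages_list
    }

    # 6. cross-stage dynamics -----------------------------------------------------
    stage("compare")
    if len(stages_list) >= 2:
        sc = venn_decompose(nets)
        rows = [
            {"region": "+".join(map(str, r)), "nodes": n, "edges": e}
            for r, (n, e) in sc.region_sizes().items()
        ]
        _write_tsv(pd.DataFrame(rows), out / "venn_regions.tsv", index=False)
        for r in sc.all_regions():
            sub = extract_specific(sc, r)
            tag = "_".join(map(str, r))
            lines = [f"{u}\t{v}\t{lab}" for u, v, lab in sorted(sub.edges)]
            (out / f"specific_edges_{tag}.tsv").write_text("".join(f"{ln}\n" for ln in lines))
        containment = containment_check(sc)
        (out / "containment.json").write_text(
            json.dumps(
                {
                    "pairwise": {f"{a}->{b}": v for (a, b), v in containment["pairwise"].items()},
                    "in_union_of_others": {str(k): v for k, v in containment["in_union_of_others"].items()},
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        manifest["summary"]["venn_regions"] = {
            "+".join(map(str, r)): {"nodes": n, "edges": e} for r, (n, e) in sc.region_sizes().items()
        }

    # 7. classification -----------------------------------------------------------
    stage("classify")
    panel = cfg.panel_genes or _default_panel(nets, expr)
    if panel:
        try:
            report = evaluate_panel(panel, expr, task="diagnosis")
            if expr.samples["recurrence"].isin(["yes", "no"]).sum() >= 4:
                rec = evaluate_panel(panel, expr, task="recurrence")
                report["recurrence_loocv_auc"] = rec["train_loocv_auc"]
            (out / "classifier_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            manifest["summary"]["classifier"] = report
        except (KeyError, ValueError) as exc:
            raise PipelineError(f"stage classify failed for panel {panel}: {exc}") from exc
    else:
        logger.warning("no panel genes available; skipping classification")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest


def _default_panel(nets, expr) -> list[str]:
    """Fallback biomarker panel: TF and target of the stage-1 network's first motif."""
    for s in sorted(nets):
        for m in nets[s].motifs:
            if m.tf in expr.features and m.gene in expr.features and m.tf != m.gene:
                return [m.tf, m.gene]
    return []
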