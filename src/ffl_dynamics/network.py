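"""miRNA-TF feed-forward-loop enumeration and co-regulatory network analysis.

A co-regulatory motif (feed-forward loop, FFL) is a miRNA m and a transcription
factor t that regulate each other (m->t and t->m) together with a common target
gene g regulated by both (m->g and t->g).  Motifs are enumerated from a typed
interaction catalog restricted to a stage's SDE genes: the TF and the target
must be SDE (they are protein-coding genes in the expression matrix); miRNAs
are not filtered because matched miRNA profiles are typically unavailable.
The target may coincide with the TF (TF self-regulation) when
``allow_self_target`` is set.

Motifs of one stage merge into a RegNetwork: a directed graph whose nodes are
typed miRNA / TF / gene / TF+gene and whose edges carry the label ``inh``
(miRNA source, post-transcriptional inhibition) or ``reg`` (TF source,
transcriptional regulation).  Node importance uses degree and betweenness
centrality BC_i = sum over ordered pairs s != i != t of sigma_i(s,t)/sigma(s,t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from ffl_dynamics import io as fio

logger = logging.getLogger(__name__)

EDGE_TYPES = ("mirna_gene", "mirna_tf", "tf_gene", "tf_mirna")


class Motif(NamedTuple):
    """A feed-forward loop: miRNA and TF mutually regulating a shared target."""

    mirna: str
    tf: str
    gene: str


@dataclass
class InteractionCatalog:
    """Typed directed regulatory edges plus a node role registry.

    ``edges`` has columns source_id, target_id, edge_type, evidence; duplicate
    (source, target, type) rows are merged with evidence tags concatenated.
    Roles: sources of mirna_* edges and targets of *_mirna edges are miRNAs;
    TFs come from the supplied TF list; everything else appearing as a target
    is a gene.  An id may be both a TF and a gene, never both a miRNA and a
    TF/gene.
    """

    edges: pd.DataFrame
    tfs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = set(self.edges["edge_type"]) - set(EDGE_TYPES)
        if bad:
            raise ValueError(f"unknown edge types: {sorted(bad)}")
        self._validate_roles()

    def _validate_roles(self) -> None:
        conflicts = self.mirnas & (self.tfs | self.genes)
        if conflicts:
            rows = self.edges[
                self.edges["source_id"].isin(conflicts) | self.edges["target_id"].isin(conflicts)
            ]
            raise ValueError(
                f"ids used both as miRNA and as TF/gene: {sorted(conflicts)[:10]}; "
                f"offending rows:\n{rows.head(10)}"
            )
        et = self.edges["edge_type"]
        tf_src = self.edges["source_id"].isin(self.tfs)
        bad_tf = self.edges[(et.isin(["tf_gene", "tf_mirna"])) & ~tf_src]
        if len(bad_tf):
            raise ValueError(f"tf_* edges whose source is not in the TF list:\n{bad_tf.head(10)}")
        bad_mt = self.edges[(et == "mirna_tf") & ~self.edges["target_id"].isin(self.tfs)]
        if len(bad_mt):
            raise ValueError(f"mirna_tf edges whose target is not in the TF list:\n{bad_mt.head(10)}")

    @property
    def mirnas(self) -> set[str]:
        et = self.edges["edge_type"]
        src = set(self.edges.loc[et.isin(["mirna_gene", "mirna_tf"]), "source_id"])
        tgt = set(self.edges.loc[et == "tf_mirna", "target_id"])
        return src | tgt

    @property
    def genes(self) -> set[str]:
        et = self.edges["edge_type"]
        return set(self.edges.loc[et.isin(["mirna_gene", "tf_gene"]), "target_id"])

    def edge_set(self) -> set[tuple[str, str, str]]:
        return set(map(tuple, self.edges[["source_id", "target_id", "edge_type"]].to_numpy()))

    def __len__(self) -> int:
        return len(self.edges)


def _resolve_alias(name: str, alias_map: dict[str, str]) -> str:
    """Follow alias chains to a canonical id (cycle-safe)."""
    seen = {name}
    while name in alias_map:
        name = alias_map[name]
        if name in seen:
            break
        seen.add(name)
    return name


def normalize_mirna_ids(edges: pd.DataFrame, mirnas: set[str], alias_map: dict[str, str] | None) -> pd.DataFrame:
    """Case-fold miRNA ids and apply the alias map transitively."""
    amap = {k.lower(): v.lower() for k, v in (alias_map or {}).items()}

    def norm(x: str) -> str:
        return _resolve_alias(x.lower(), amap)

    edges = edges.copy()
    is_mirna_src = edges["edge_type"].isin(["mirna_gene", "mirna_tf"])
    is_mirna_tgt = edges["edge_type"] == "tf_mirna"
    edges.loc[is_mirna_src, "source_id"] = edges.loc[is_mirna_src, "source_id"].map(norm)
    edges.loc[is_mirna_tgt, "target_id"] = edges.loc[is_mirna_tgt, "target_id"].map(norm)
    return edges


def load_catalog(paths: Iterable, tf_list_path, alias_map: dict[str, str] | None = None) -> InteractionCatalog:
    """Load, merge and de-duplicate typed edge lists; normalize miRNA ids."""
    frames = [fio.read_catalog_edges(p) for p in paths]
    edges = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["source_id", "target_id", "edge_type", "evidence"])
    )
    tfs = fio.read_tf_list(tf_list_path)
    return build_catalog(edges, tfs, alias_map)


def build_catalog(edges: pd.DataFrame, tfs: set[str], alias_map: dict[str, str] | None = None) -> InteractionCatalog:
    edges = normalize_mirna_ids(edges, set(), alias_map)
    merged = (
        edges.groupby(["source_id", "target_id", "edge_type"], sort=True)["evidence"]
        .apply(lambda ev: ";".join(sorted({e for e in ev if e})))
        .reset_index()
    )
    return InteractionCatalog(merged, set(tfs))


def enumerate_motifs(cat: InteractionCatalog, sde: set[str], allow_self_target: bool = True) -> list[Motif]:
    """All FFL triples (m, t, g) with mutual m<->t regulation and shared target g.

    Requires t in ``sde`` and g in ``sde``; miRNAs are not SDE-filtered.  A
    miRNA's targets include both its mirna_gene and mirna_tf edges (a TF
    targeted by a miRNA is still a gene).  g == t is reported only when
    ``allow_self_target`` and the TF has a tf_gene self-loop.
    """
    et = cat.edges["edge_type"]
    mirna_targets: dict[str, set[str]] = {}
    for src, tgt in cat.edges.loc[et.isin(["mirna_gene", "mirna_tf"]), ["source_id", "target_id"]].itertuples(index=False):
        mirna_targets.setdefault(src, set()).add(tgt)
    tf_targets: dict[str, set[str]] = {}
    for src, tgt in cat.edges.loc[et == "tf_gene", ["source_id", "target_id"]].itertuples(index=False):
        tf_targets.setdefault(src, set()).add(tgt)
    tf_to_mirna: dict[str, set[str]] = {}
    for src, tgt in cat.edges.loc[et == "tf_mirna", ["source_id", "target_id"]].itertuples(index=False):
        tf_to_mirna.setdefault(src, set()).add(tgt)
    mirna_to_tf: dict[str, set[str]] = {}
    for src, tgt in cat.edges.loc[et == "mirna_tf", ["source_id", "target_id"]].itertuples(index=False):
        mirna_to_tf.setdefault(src, set()).add(tgt)

    mirnas = cat.mirnas
    motifs: list[Motif] = []
    for m, tfs_of_m in mirna_to_tf.items():
        for t in tfs_of_m:
            if t not in sde or m not in tf_to_mirna.get(t, ()):  # mutual regulation required
                continue
            shared = mirna_targets.get(m, set()) & tf_targets.get(t, set()) & sde
            for g in shared:
                if g in mirnas:
                    continue
                if g == t and not allow_self_target:
                    continue
                motifs.append(Motif(m, t, g))
    return sorted(motifs)


@dataclass
class RegNetwork:
    """Per-stage merged FFL network over a directed typed graph."""

    graph: nx.DiGraph
    stage: int | None = None
    motifs: list[Motif] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_records(self) -> set[tuple[str, str, str]]:
        """Edge identity triples (source, target, label)."""
        return {(u, v, d["label"]) for u, v, d in self.graph.edges(data=True)}

    def roles(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="role"))

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, r in self.graph.nodes(data="role") if r == role}


def merge_motifs(motifs: list[Motif], stage: int | None = None) -> RegNetwork:
    """Union of the four directed edges of every motif, with node roles resolved.

    A node is TF+gene iff it appears both in TF position and in target position
    within this network.  Edge labels: ``inh`` from miRNA sources, ``reg`` from
    TF sources.
    """
    g = nx.DiGraph()
    as_mirna, as_tf, as_gene = set(), set(), set()
    for m, t, tgt in motifs:
        as_mirna.add(m)
        as_tf.add(t)
        as_gene.add(tgt)
        g.add_edge(m, t, label="inh")
        g.add_edge(t, m, label="reg")
        g.add_edge(m, tgt, label="inh")
        g.add_edge(t, tgt, label="reg")
    for n in g.nodes:
        if n in as_mirna:
            role = "miRNA"
        elif n in as_tf and n in as_gene:
            role = "TF+gene"
        elif n in as_tf:
            role = "TF"
        else:
            role = "gene"
        g.nodes[n]["role"] = role
    return RegNetwork(g, stage, sorted(set(motifs)))


def degree(net: RegNetwork, mode: str = "collapsed") -> dict[str, int]:
    """Node degree.

    ``collapsed``: number of distinct neighbors in the undirected collapse (a
    mutual miRNA<->TF pair counts once; a self-loop adds 1).  ``directed``:
    number of incident directed edges (a self-loop adds 2).
    """
    g = net.graph
    if mode == "collapsed":
        out = {}
        for n in g.nodes:
            nbrs = set(g.predecessors(n)) | set(g.successors(n))
            out[n] = len(nbrs)  # a self-loop puts n in its own neighbor set once
        return out
    if mode == "directed":
        return {n: g.in_degree(n) + g.out_degree(n) for n in g.nodes}
    raise ValueError("mode must be 'collapsed' or 'directed'")


def betweenness(net: RegNetwork, mode: str = "undirected") -> dict[str, float]:
    """Betweenness centrality over ordered node pairs (unweighted shortest paths).

    Uses Brandes accumulation (networkx).  In the undirected collapse every
    unordered pair contributes twice, so the path a-b-c gives BC(b) = 2.
    """
    if mode == "undirected":
        u = nx.Graph()
        u.add_nodes_from(net.graph.nodes)
        u.add_edges_from((a, b) for a, b in net.graph.edges if a != b)
        bc = nx.betweenness_centrality(u, normalized=False)
        return {n: 2.0 * v for n, v in bc.items()}
    if mode == "directed":
        return dict(nx.betweenness_centrality(net.graph, normalized=False))
    raise ValueError("mode must be 'undirected' or 'directed'")


def call_hubs(deg: dict[str, int], top_fraction: float = 0.20) -> set[str]:
    """Nodes whose degree reaches the (1 - top_fraction) quantile, ties included."""
    if not deg:
        raise ValueError("empty degree map")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    cutoff = float(np.quantile(list(deg.values()), 1.0 - top_fraction))
    return {n for n, d in deg.items() if d >= cutoff}


def node_table(net: RegNetwork, hub_fraction: float = 0.20,
               degree_mode: str = "collapsed", bc_mode: str = "undirected") -> pd.DataFrame:
    """Per-node role, degree, betweenness and hub flag."""
    deg = degree(net, degree_mode)
    bc = betweenness(net, bc_mode)
    hubs = call_hubs(deg, hub_fraction) if deg else set()
    rows = [
        {"node": n, "role": net.graph.nodes[n]["role"], "degree": deg[n], "bc": bc[n], "hub": n in hubs}
        for n in sorted(net.graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["node", "role", "degree", "bc", "hub"]).set_index("node")


def edge_table(net: RegNetwork) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "label": d["label"], "stage": net.stage}
        for u, v, d in sorted(net.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "label", "stage"])


def network_from_edge_table(df: pd.DataFrame, roles: dict[str, str] | None = None) -> RegNetwork:
    """Rebuild a RegNetwork from a written edge table (roles re-derived if absent)."""
    g = nx.DiGraph()
    stage = None
    for r in df.itertuples(index=False):
        g.add_edge(r.source, r.target, label=r.label)
        stage = getattr(r, "stage", None)
    as_tf = {u for u, v, d in g.edges(data=True) if d["label"] == "reg"}
    as_mirna = {u for u, v, d in g.edges(data=True) if d["label"] == "inh"}
    # target position in a motif is always hit by a TF "reg" edge
    as_gene = {v for u, v, d in g.edges(data=True) if d["label"] == "reg" and v not in as_mirna}
    for n in g.nodes:
        if roles and n in roles:
            g.nodes[n]["role"] = roles[n]
        elif n in as_mirna:
            g.nodes[n]["role"] = "miRNA"
        elif n in as_tf and n in as_gene:
            g.nodes[n]["role"] = "TF+gene"
        elif n in as_tf:
            g.nodes[n]["role"] = "TF"
        else:
            g.nodes[n]["role"] = "gene"
    stage = int(stage) if stage is not None and not pd.isna(stage) else None
    return RegNetwork(g, stage)
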