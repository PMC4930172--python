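"""Cross-stage network comparison: Venn decomposition and specific subnetworks.

Every node and every edge (identity = source, target, label) of the per-stage
networks is assigned to exactly one region: the non-empty subset of stages in
which it occurs.  Stage- or transition-specific subnetworks are induced by the
edges of a chosen region; endpoints that are not themselves region-specific
are flagged shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

from ffl_dynamics.network import RegNetwork

logger = logging.getLogger(__name__)

Region = tuple[int, ...]  # sorted stage ids
EdgeId = tuple[str, str, str]


@dataclass
class StageComparison:
    """Exact-subset (Venn) decomposition of nodes and edges across stages."""

    stages: list[int]
    node_regions: dict[Region, set[str]]
    edge_regions: dict[Region, set[EdgeId]]

    def region_sizes(self) -> dict[Region, tuple[int, int]]:
        regions = sorted(set(self.node_regions) | set(self.edge_regions), key=lambda r: (len(r), r))
        return {
            r: (len(self.node_regions.get(r, ())), len(self.edge_regions.get(r, ())))
            for r in regions
        }

    def all_regions(self) -> list[Region]:
        out = []
        for k in range(1, len(self.stages) + 1):
            out.extend(tuple(c) for c in combinations(sorted(self.stages), k))
        return out


@dataclass
class SpecificSubnetwork:
    """Edges exactly specific to a stage subset, plus their endpoints."""

    subset: Region
    edges: set[EdgeId]
    specific_nodes: set[str] = field(default_factory=set)
    shared_nodes: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return self.specific_nodes | self.shared_nodes


def venn_decompose(nets: dict[int, RegNetwork]) -> StageComparison:
    """Assign every node/edge to the exact subset of stages containing it."""
    if len(nets) < 2:
        raise ValueError("need >=2 stage networks to compare")
    stages = sorted(nets)
    node_memb: dict[str, list[int]] = {}
    edge_memb: dict[EdgeId, list[int]] = {}
    for s in stages:
        for n in nets[s].nodes:
            node_memb.setdefault(n, []).append(s)
        for e in nets[s].edge_records():
            edge_memb.setdefault(e, []).append(s)
    node_regions: dict[Region, set[str]] = {}
    edge_regions: dict[Region, set[EdgeId]] = {}
    for n, member in node_memb.items():
        node_regions.setdefault(tuple(sorted(member)), set()).add(n)
    for e, member in edge_memb.items():
        edge_regions.setdefault(tuple(sorted(member)), set()).add(e)
    return StageComparison(stages, node_regions, edge_regions)


def extract_specific(sc: StageComparison, subset: Region) -> SpecificSubnetwork:
    """Subnetwork induced by the edges exactly in ``subset``.

    Endpoint nodes whose own exact region is ``subset`` are flagged specific;
    the rest are shared with other stages.
    """
    subset = tuple(sorted(subset))
    if not subset:
        raise ValueError("subset must be non-empty")
    edges = set(sc.edge_regions.get(subset, set()))
    if not edges:
        logger.warning("no edges exactly in stage subset %s", subset)
    endpoints = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    specific = endpoints & sc.node_regions.get(subset, set())
    return SpecificSubnetwork(subset, edges, specific, endpoints - specific)


def containment_check(sc: StageComparison) -> dict:
    """Pairwise subset relations between stage networks (nodes and edges).

    Also reports, per stage, whether it is contained in the union of the other
    stages — e.g. a chronic network fully covered by the acute and subacute
    ones.
    """
    stages = sc.stages
    node_sets = {s: set() for s in stages}
    edge_sets = {s: set() for s in stages}
    for region, nodes in sc.node_regions.items():
        for s in region:
            node_sets[s] |= nodes
    for region, edges in sc.edge_regions.items():
        for s in region:
            edge_sets[s] |= edges
    report: dict = {"pairwise": {}, "in_union_of_others": {}}
    for a in stages:
        for b in stages:
            if a == b:
                continue
            report["pairwise"][(a, b)] = {
                "nodes_subset": node_sets[a] <= node_sets[b],
                "edges_subset": edge_sets[a] <= edge_sets[b],
            }
        others_n = set().union(*(node_sets[s] for s in stages if s != a))
        others_e = set().union(*(edge_sets[s] for s in stages if s != a))
        report["in_union_of_others"][a] = {
            "nodes_subset": node_sets[a] <= others_n,
            "edges_subset": edge_sets[a] <= others_e,
        }
    return report
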