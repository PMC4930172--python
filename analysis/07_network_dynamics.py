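"""Compare the per-stage networks: Venn regions, containment, specific motifs.

Every node and edge is assigned to the exact subset of stages containing it;
stage-specific and transition-specific subnetworks are extracted and the
chronic-in-earlier-stages containment pattern is checked.
"""

import json

import pandas as pd

from common import RESULTS, WORKDIR, parse_args, require
from ffl_dynamics.dynamics import containment_check, extract_specific, venn_decompose
from ffl_dynamics.network import network_from_edge_table


def main() -> None:
    parse_args(__doc__)
    nets = {}
    for s in (1, 2, 3):
        f = WORKDIR / f"network_stage{s}_edges.tsv"
        require("06_ffl_networks.py", f)
        nets[s] = network_from_edge_table(pd.read_csv(f, sep="\t"))
        nets[s].stage = s
    sc = venn_decompose(nets)
    rows = [
        {"region": "+".join(map(str, r)), "nodes": n, "edges": e}
        for r, (n, e) in sc.region_sizes().items()
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "venn_regions.tsv", sep="\t", index=False)
    for row in rows:
        print(f"region exactly-in-stages {row['region']}: {row['nodes']} nodes, {row['edges']} edges")

    rep = containment_check(sc)
    chronic_contained = rep["in_union_of_others"][3]
    print(f"chronic network contained in acute+subacute union: "
          f"nodes={chronic_contained['nodes_subset']}, edges={chronic_contained['edges_subset']}")

    specific = {}
    for subset, label in (((1,), "acute_specific"), ((1, 2), "acute_to_subacute"), ((2, 3), "subacute_to_chronic")):
        sub = extract_specific(sc, subset)
        specific[label] = {
            "edges": len(sub.edges),
            "specific_nodes": sorted(sub.specific_nodes),
            "shared_nodes": sorted(sub.shared_nodes),
        }
        print(f"{label}: {len(sub.edges)} specific edges, "
              f"{len(sub.specific_nodes)} specific nodes")
    (RESULTS / "specific_subnetworks.json").write_text(json.dumps(specific, indent=2) + "\n")


if __name__ == "__main__":
    main()
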