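"""Per-stage subpathway enrichment with min-p collapapse per parent pathway.

Hypergeometric over-representation of each stage's SDE genes in the supplied
subpathway sets (background = all analyzed genes), BH-corrected at 0.05; of
several significant subpathways sharing a parent pathway only the strongest
is kept.  The stage x set significance matrix shows when each function peaks.
"""

import json

from common import RESULTS, WORKDIR, input_paths, parse_args, require
from ffl_dynamics import io as fio
from ffl_dynamics.diffexpr import call_sde, moderated_t_test
from ffl_dynamics.enrichment import (
    GeneSetCollection,
    collapse_subpathways,
    hypergeom_enrich,
    significance_matrix,
)


def main() -> None:
    parse_args(__doc__)
    paths = input_paths()
    require("02_preprocess.py", WORKDIR / "expression_genes.tsv")
    expr = fio.read_expression(WORKDIR / "expression_genes.tsv", WORKDIR / "samples_used.tsv")
    truth = json.loads(paths["ground_truth"].read_text())
    coll = GeneSetCollection(
        {k: set(v) for k, v in fio.read_gmt(paths["gene_sets"]).items()},
        set(expr.features),
        fio.read_parent_map(paths["parent_map"]),
    )
    tables = {}
    for s in expr.stages():
        sde = call_sde(moderated_t_test(expr, s))
        t = hypergeom_enrich(sde, coll, stage=s)
        tables[s] = t
        kept = collapse_subpathways(t)
        print(f"stage {s}: {int(t['significant'].sum())} significant subpathways, "
              f"{len(kept)} after per-pathway collapse")
    matrix = significance_matrix(tables)
    matrix.to_csv(RESULTS / "enrichment_matrix.tsv", sep="\t")
    planted = set(truth["enriched_sets"])
    hit = planted & set(matrix.index)
    print(f"planted enriched sets recovered in the matrix: {len(hit)}/{len(planted)}")


if __name__ == "__main__":
    main()
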