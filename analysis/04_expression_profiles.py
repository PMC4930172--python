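"""Cluster the top SDE genes' stage profiles into the two canonical patterns.

Standardized (baseline, stage 1..3) log2FC profiles are clustered with the
city-block metric and complete linkage; a 2-cut separates genes sharply
up-regulated in the acute stage from sharply down-regulated ones, both
relaxing toward baseline afterwards.
"""

from common import RESULTS, WORKDIR, parse_args, require
from ffl_dynamics import io as fio
from ffl_dynamics.cluster_profiles import build_profiles, cluster_means, hcluster
from ffl_dynamics.diffexpr import moderated_t_test, top_k


def main() -> None:
    parse_args(__doc__)
    require("02_preprocess.py", WORKDIR / "expression_genes.tsv")
    expr = fio.read_expression(WORKDIR / "expression_genes.tsv", WORKDIR / "samples_used.tsv")
    tables = {s: moderated_t_test(expr, s) for s in expr.stages()}
    ranked = top_k(tables, 100)
    profiles = build_profiles(tables, ranked)
    dend = hcluster(profiles, k=2)
    means = cluster_means(profiles, dend)
    dend.assignments.to_frame().to_csv(RESULTS / "cluster_assignments.tsv", sep="\t")
    means.to_csv(RESULTS / "cluster_means.tsv", sep="\t")
    print(f"clustered {len(profiles)} top SDE genes into 2 profile clusters:")
    for c in means.index:
        n = int((dend.assignments == c).sum())
        print(f"  cluster {c}: {n} genes, pattern {means.loc[c, 'pattern']}, "
              f"stage means {[round(float(means.loc[c, f'stage{s}']), 2) for s in (1, 2, 3)]}")


if __name__ == "__main__":
    main()
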