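"""Per-stage differential expression with the moderated t-statistic.

Each stage's cases are tested against the shared control group; genes with
BH-adjusted p < 0.001 and linear fold change > 1.2 are called SDE.  Reports
per-stage counts, the cross-stage shared set, and recovery of the planted DE
genes.
"""

import json

import pandas as pd

from common import RESULTS, WORKDIR, input_paths, parse_args, require
from ffl_dynamics import io as fio
from ffl_dynamics.diffexpr import DEConfig, moderated_t_test, sde_summary


def main() -> None:
    parse_args(__doc__)
    paths = input_paths()
    require("02_preprocess.py", WORKDIR / "expression_genes.tsv")
    expr = fio.read_expression(WORKDIR / "expression_genes.tsv", WORKDIR / "samples_used.tsv")
    truth = json.loads(paths["ground_truth"].read_text())

    cfg = DEConfig()
    tables = {}
    for s in expr.stages():
        t = moderated_t_test(expr, s, cfg)
        tables[s] = t
        t[["log2fc", "fold_change", "t", "p", "adj_p", "sde"]].to_csv(
            WORKDIR / f"de_stage{s}.tsv", sep="\t"
        )
    summary = sde_summary(tables, cfg)
    print("SDE counts per stage:", summary["per_stage"],
          f"(union {summary['union']}, shared {len(summary['intersection'])})")

    rows = []
    for s, count in summary["per_stage"].items():
        planted = set(truth["de_genes_per_stage"][str(s)])
        called = summary["sets"][s]
        recall = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(len(called), 1)
        rows.append({"stage": s, "sde_count": count, "recall": round(recall, 4), "fdp": round(fdp, 4)})
        print(f"  stage {s}: recall of planted DE {recall:.3f}, false-discovery proportion {fdp:.3f}")
    pd.DataFrame(rows).to_csv(RESULTS / "sde_counts.tsv", sep="\t", index=False)
    (WORKDIR / "sde_shared.txt").write_text(
        "".join(f"{g}\n" for g in sorted(summary["intersection"]))
    )


if __name__ == "__main__":
    main()
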