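"""Evaluate the planted two-gene panel with Naive Bayes + LOOCV.

The panel (the TF and target of the first planted feed-forward loop,
mirroring a motif-derived diagnostic signature) is scored by leave-one-out
cross-validated AUC for case/control discrimination and for recurrence
prediction among cases, alongside each single gene.
"""

import json

from common import RESULTS, WORKDIR, input_paths, parse_args, require
from ffl_dynamics import io as fio
from ffl_dynamics.classify import evaluate_panel


def main() -> None:
    parse_args(__doc__)
    paths = input_paths()
    require("02_preprocess.py", WORKDIR / "expression_genes.tsv")
    expr = fio.read_expression(WORKDIR / "expression_genes.tsv", WORKDIR / "samples_used.tsv")
    truth = json.loads(paths["ground_truth"].read_text())
    panel = [g for g in truth["biomarker_genes"] if g in expr.features]

    report = evaluate_panel(panel, expr, task="diagnosis")
    rec = evaluate_panel(panel, expr, task="recurrence")
    out = {
        "panel": panel,
        "diagnosis_loocv_auc": report["train_loocv_auc"],
        "diagnosis_single_gene_auc": report["single_gene_train_auc"],
        "recurrence_loocv_auc": rec["train_loocv_auc"],
        "recurrence_single_gene_auc": rec["single_gene_train_auc"],
    }
    (RESULTS / "classifier_report.json").write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    print(f"panel {panel}:")
    print(f"  diagnosis LOOCV AUC:  {out['diagnosis_loocv_auc']:.3f} "
          f"(single genes: {', '.join(f'{g}={a:.3f}' for g, a in out['diagnosis_single_gene_auc'].items())})")
    print(f"  recurrence LOOCV AUC: {out['recurrence_loocv_auc']:.3f} "
          f"(single genes: {', '.join(f'{g}={a:.3f}' for g, a in out['recurrence_single_gene_auc'].items())})")


if __name__ == "__main__":
    main()
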