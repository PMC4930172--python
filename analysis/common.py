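"""Shared paths and argument handling for the numbered analysis drivers.

Bulky intermediates (expression matrices, catalogs) live under scratch/ and
are regenerated on demand; only small summary tables land in results/.
"""

from __future__ import annotations

import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
WORKDIR = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    WORKDIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return args


def input_paths() -> dict[str, Path]:
    d = WORKDIR / "inputs"
    names = {
        "expression": "expression.tsv",
        "samples": "samples.tsv",
        "probe_expression": "probe_expression.tsv",
        "probe_map": "probe_map.tsv",
        "catalog": "catalog.tsv",
        "gene_sets": "gene_sets.gmt",
        "parent_map": "subpathway_parents.tsv",
        "tf_list": "tf_list.txt",
        "ground_truth": "ground_truth.json",
    }
    return {k: d / v for k, v in names.items()}


def require(step: str, *paths: Path) -> None:
    missing = [p for p in paths if not p.is_file()]
    if missing:
        raise SystemExit(f"run {step} first (missing: {missing[0]})")
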