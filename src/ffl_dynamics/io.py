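"""Readers and writers for the pipeline's plain-text exchange formats.

All tables are TSV.  Gene sets use GMT with a sidecar TSV mapping subpathway
ids to parent pathway ids.  Floating point output uses repr-round-tripping
formatting so that identical in-memory results serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ffl_dynamics.expression import ExpressionMatrix

ANNOT_COLUMNS = ["group", "stage", "recurrence"]


# -- expression ---------------------------------------------------------------

def write_expression(m: ExpressionMatrix, values_path, annot_path) -> None:
    m.values.to_csv(values_path, sep="\t", index_label="feature_id")
    ann = m.samples[ANNOT_COLUMNS].copy()
    ann.to_csv(annot_path, sep="\t", index_label="sample_id", na_rep="NA")


def read_expression(values_path, annot_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
    ann = pd.read_csv(annot_path, sep="\t", index_col="sample_id", na_values=["NA"], keep_default_na=False)
    if "stage" in ann.columns:
        ann["stage"] = pd.to_numeric(ann["stage"], errors="coerce").astype("Int64")
    return ExpressionMatrix(values, ann)


# -- probe map ----------------------------------------------------------------

def write_probe_map(rows: list[tuple[str, str, str]], path) -> None:
    """Rows are (probe_id, gene_symbol, biotype); gene_symbol may be empty."""
    df = pd.DataFrame(rows, columns=["probe_id", "gene_symbol", "biotype"])
    df.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)


# -- interaction catalog ------------------------------------------------------

def write_catalog_edges(edges: pd.DataFrame, path) -> None:
    edges[["source_id", "target_id", "edge_type", "evidence"]].to_csv(path, sep="\t", index=False)


def read_catalog_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"source_id", "target_id", "edge_type"}
    if not needed <= set(df.columns):
        raise ValueError(f"catalog file {path} missing columns {sorted(needed - set(df.columns))}")
    if "evidence" not in df.columns:
        df["evidence"] = ""
    return df


def write_tf_list(tfs, path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in sorted(tfs)))


def read_tf_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


# -- gene sets ----------------------------------------------------------------

def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            desc = (descriptions or {}).get(set_id, "na")
            fh.write("\t".join([set_id, desc, *sets[set_id]]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_parent_map(parents: dict[str, str], path) -> None:
    df = pd.DataFrame(sorted(parents.items()), columns=["subpathway_id", "parent_pathway_id"])
    df.to_csv(path, sep="\t", index=False)


def read_parent_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["subpathway_id"], df["parent_pathway_id"]))


# -- ground truth -------------------------------------------------------------

def write_ground_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
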