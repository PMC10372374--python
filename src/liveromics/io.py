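"""Readers and writers for the plain-text formats the toolkit exchanges.

Everything is tab-separated: abundance matrices (features in rows, first
column the feature ID), design tables, STRING-style edge lists, gene-disease
tables, GMT gene-set collections and one-symbol-per-line seed lists.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample abundance matrix; first column is the feature ID."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs: {dups[:5]}")
    return m


def write_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="feature")


def read_design(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"sample", "role"} - set(d.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    return d


def write_design(d: pd.DataFrame, path) -> None:
    d.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    """STRING-style links: protein1, protein2, combined_score."""
    e = pd.read_csv(path, sep=r"\s+", engine="python")
    need = {"protein1", "protein2", "combined_score"}
    if not need <= set(e.columns):
        raise ValueError(f"edge list needs columns {sorted(need)}")
    bad = e["combined_score"].isna()
    if bad.any():
        lines = (e.index[bad] + 2).tolist()  # header is line 1
        raise ValueError(f"malformed combined_score at lines {lines[:5]}")
    return e


def write_edge_list(e: pd.DataFrame, path) -> None:
    e.to_csv(path, sep="\t", index=False)


def read_disease_table(path) -> pd.DataFrame:
    d = pd.read_csv(path, sep="\t")
    need = {"disease_id", "gene", "gda_score"}
    if not need <= set(d.columns):
        raise ValueError(f"disease table needs columns {sorted(need)}")
    return d


def write_disease_table(d: pd.DataFrame, path) -> None:
    d.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        name, _desc, *genes = parts
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Dict[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_seed_list(path) -> List[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
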