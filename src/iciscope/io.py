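"""Readers and writers for the plain-text formats used throughout the pipeline.

Conventions:

* Expression and signature matrices are tab-separated, genes as rows with the
  gene identifier in the first column, samples (or cell types) as columns.
* Label tables (batch assignments, cluster labels, score groups) are
  two-column TSV: item identifier, label.
* Gene sets travel in GMT format: one set per line, ``name<TAB>description``
  followed by the member genes.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression (or signature) matrix from TSV.

    The first column is taken as the gene index. Raises ``ValueError`` on
    duplicate gene or sample identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "gene")


def read_labels(path: str | Path, value_name: str = "label") -> pd.Series:
    """Read a two-column TSV (item, label) into a Series indexed by item."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("label table needs at least two columns")
    s = df.set_index(df.columns[0])[df.columns[1]]
    s.name = value_name
    return s


def write_labels(labels: pd.Series, path: str | Path,
                 item_name: str = "sample") -> None:
    labels.rename_axis(item_name).to_frame().to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table (sample, time, event, ...) indexed by sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in clinical table")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [genes]}`` preserving order."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> dict:
    """Read a synthetic-cohort truth ledger (JSON)."""
    return json.loads(Path(path).read_text())


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))
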