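"""Readers and writers for the tool's tabular formats.

Expression matrices are TSV, genes in rows (first column ``gene``),
samples in columns, values on a log scale.  Gold-standard driver lists
are one symbol per line (``#`` comments allowed).  Per-patient rank
tables are the TSVs written by the ``rank`` command.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "read_expression",
    "read_gold_list",
    "read_rank_tables",
    "write_rank_table",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log-scale expression TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if df.shape[1] == 0:
        raise ValueError(f"{path}: expression table has no sample columns")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate gene symbols {list(dups[:10])}")
    return df.astype(float)


def read_gold_list(path) -> set[str]:
    """Read a gold-standard gene list, one symbol per line."""
    genes = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym)
    if not genes:
        raise ValueError(f"{path}: empty gold-standard list")
    return genes


def write_rank_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_rank_tables(rank_dir) -> pd.DataFrame:
    """Assemble a genes x patients percentile matrix from rank TSVs.

    Reads every ``*.ranks.tsv`` under ``rank_dir``; the patient id is
    the file stem before ``.ranks``.
    """
    rank_dir = Path(rank_dir)
    paths = sorted(rank_dir.glob("*.ranks.tsv"))
    if not paths:
        raise ValueError(f"no *.ranks.tsv files under {rank_dir}")
    columns = {}
    for path in paths:
        df = pd.read_csv(path, sep="\t")
        for col in ("gene", "percentile"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        patient = path.name[: -len(".ranks.tsv")]
        columns[patient] = pd.Series(
            df["percentile"].to_numpy(dtype=float), index=df["gene"].astype(str)
        )
    out = pd.DataFrame(columns)
    out.index.name = "gene"
    if out.isna().any().any():
        raise ValueError("rank tables cover different gene sets")
    return out
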