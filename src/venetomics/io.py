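"""Thin TSV helpers shared by the pipeline, CLI and analysis drivers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write an entity-by-sample matrix (index written as first column)."""
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a plain table without the index."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
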