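"""Plain-text readers/writers for the pipeline's tables.

Counts and truth tables travel as TSV; peaks as BED3+score (no header);
gene annotation as BED6 with 0-based half-open coordinates. Round-trips are
lossless for the integer interval columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """BED3+score, tab-separated, no header; extra columns appended in order."""
    cols = ["chrom", "start", "end"]
    extra = [c for c in peaks.columns if c not in cols]
    peaks[cols + extra].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, extra_columns: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (extra_columns or [])
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df.astype({"start": np.int64, "end": np.int64})


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    ann = ann.astype({"start": np.int64, "end": np.int64})
    ann["tss"] = np.where(ann["strand"] == "+", ann["start"], ann["end"] - 1)
    return ann
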