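"""Readers and writers for the small plain-text formats used across the package.

All genomic coordinates are 0-based, half-open (BED convention).  Readers
validate coordinates and report the offending file and line on error; writers
emit tab-separated text with deterministic formatting so that identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED3_COLS = ["chrom", "start", "end"]


def read_bed(path: str | os.PathLike, min_cols: int = 3) -> pd.DataFrame:
    """Read a BED file into a DataFrame with at least ``min_cols`` columns.

    Columns beyond the first six are kept as strings under ``extra_<i>``.
    Raises ``ValueError`` (with file and line number) on negative coordinates
    or ``end <= start``.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            rows.append(fields)
    if not rows:
        return pd.DataFrame(columns=names[:max(min_cols, 3)])
    width = max(len(r) for r in rows)
    cols = names[:min(width, 6)] + [f"extra_{i}" for i in range(max(0, width - 6))]
    df = pd.DataFrame([r + [""] * (width - len(r)) for r in rows], columns=cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a BED DataFrame (any number of columns, chrom/start/end first)."""
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            length = int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive chromosome length")
            sizes[fields[0]] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def merge_intervals(starts: Iterable[int], ends: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge possibly-overlapping half-open intervals.

    Touching intervals ([0,5) and [5,9)) are merged into one.
    """
    starts = np.asarray(list(starts), dtype=np.int64)
    ends = np.asarray(list(ends), dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s = [int(starts[0])]
    merged_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], int(e))
        else:
            merged_s.append(int(s))
            merged_e.append(int(e))
    return np.asarray(merged_s, dtype=np.int64), np.asarray(merged_e, dtype=np.int64)
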