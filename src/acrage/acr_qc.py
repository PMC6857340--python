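"""ACR identification and quality control from ATAC-seq read ends and peak sets.

Covers the read-level conventions of whole-embryo ATAC-seq processing:
transposase (Tn5) insertion-site correction of read 5' ends, read-depth
downsampling, replicate-consensus filtering of pooled peaks, 5'-end signal
quantification (counts / RPM / log10-RPM), FRiP, replicate Pearson
correlation, genomic-context classification and promoter-enrichment testing
against length-matched random controls.

Reads are represented as DataFrames with columns ``chrom``, ``pos``
(0-based position of the 5'-most base) and ``strand``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import merge_intervals

READ_COLS = ["chrom", "pos", "strand"]


def reads_from_bed6(df: pd.DataFrame) -> pd.DataFrame:
    """Extract 5' positions from a BED6 of single-base read records."""
    pos = np.where(df["strand"].to_numpy() == "+", df["start"].to_numpy(),
                   df["end"].to_numpy() - 1)
    return pd.DataFrame({"chrom": df["chrom"].to_numpy(), "pos": pos,
                         "strand": df["strand"].to_numpy()})


def tn5_correct(
    reads: pd.DataFrame,
    chrom_sizes: Mapping[str, int] | None = None,
    plus_shift: int = 4,
    minus_shift: int = -5,
) -> pd.DataFrame:
    """Shift read 5' ends to the Tn5 insertion centre and keep that single base.

    The Tn5 transposase duplicates 9 bp at the insertion site; the standard
    correction shifts plus-strand 5' ends by +4 and minus-strand ends by -5
    (net 9 bp).  Both shifts are configurable.  Positions shifted outside the
    chromosome are clamped with a warning when ``chrom_sizes`` is supplied.
    """
    pos = reads["pos"].to_numpy(dtype=np.int64)
    strand = reads["strand"].to_numpy()
    shifted = np.where(strand == "+", pos + plus_shift, pos + minus_shift)
    if chrom_sizes is not None:
        clamped = shifted.copy()
        for chrom, size in chrom_sizes.items():
            m = reads["chrom"].to_numpy() == chrom
            clamped[m] = np.clip(shifted[m], 0, size - 1)
        if (clamped != shifted).any():
            warnings.warn(
                f"{int((clamped != shifted).sum())} corrected read position(s) "
                "fell outside chromosome bounds and were clamped",
                stacklevel=2,
            )
        shifted = clamped
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "pos": shifted,
                         "strand": strand})


def downsample_reads(reads: pd.DataFrame, n_target: int, seed: int) -> pd.DataFrame:
    """Uniform sample of ``n_target`` reads without replacement (seeded).

    Samples with fewer aligned reads than the target are rejected rather than
    upsampled, mirroring read-depth-controlled datasets.
    """
    n = len(reads)
    if n_target > n:
        raise ValueError(f"cannot downsample {n} reads to {n_target}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_target, replace=False))
    return reads.iloc[idx].reset_index(drop=True)


# ----------------------------------------------------------------------
# peak consensus


def _normalize_peaks(df: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        s, e = merge_intervals(grp["start"], grp["end"])
        out[chrom] = np.column_stack([s, e])
    return out


def _overlap_sum(start: int, end: int, merged: np.ndarray) -> int:
    """Total overlap of [start, end) with sorted disjoint intervals."""
    if merged is None or not len(merged):
        return 0
    lo = int(np.searchsorted(merged[:, 1], start, side="right"))
    total = 0
    for i in range(lo, len(merged)):
        if merged[i, 0] >= end:
            break
        total += min(end, int(merged[i, 1])) - max(start, int(merged[i, 0]))
    return total


def consensus_acrs(
    pooled: pd.DataFrame,
    replicates: Sequence[pd.DataFrame],
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Retain pooled peaks reproducibly covered by every replicate's peaks.

    A pooled peak is kept iff, for every replicate, the summed overlap with
    that replicate's (merged) peaks is at least ``min_frac`` of the pooled
    peak's own length.  Retained peaks keep their input order and names
    (``acr_<i>`` assigned when no name column is present).
    """
    if not replicates:
        raise ValueError("at least one replicate peak set is required")
    if pooled.empty:
        return pooled.copy()
    rep_norm = [_normalize_peaks(r) if len(r) else {} for r in replicates]
    keep = []
    for i, row in enumerate(pooled.itertuples(index=False)):
        length = row.end - row.start
        ok = all(
            _overlap_sum(row.start, row.end, rn.get(row.chrom)) >= min_frac * length
            for rn in rep_norm
        )
        keep.append(ok)
    out = pooled.loc[keep].reset_index(drop=True)
    if "name" not in out.columns:
        out = out.assign(name=[f"acr_{i}" for i in range(len(out))])
    return out


# ----------------------------------------------------------------------
# signal quantification


def _count_in_intervals(positions: Mapping[str, np.ndarray], acrs: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(acrs), dtype=np.int64)
    for i, row in enumerate(acrs.itertuples(index=False)):
        pos = positions.get(row.chrom)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, row.end, side="left") - np.searchsorted(
            pos, row.start, side="left"
        )
    return counts


def _positions_by_chrom(reads: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(grp["pos"].to_numpy(dtype=np.int64))
        for chrom, grp in reads.groupby("chrom", sort=True)
    }


def quantify_signal(
    reads: pd.DataFrame,
    acrs: pd.DataFrame,
    total_reads: int | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-ACR 5'-end counts with RPM and log10-RPM columns.

    ACRs must be disjoint after normalization so every read is counted at most
    once.  ``total_reads`` defaults to the number of reads supplied; zero
    counts use ``pseudocount`` reads before the RPM log-transform.
    """
    for chrom, grp in acrs.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"ACRs overlap on {chrom}; normalize first")
    total = total_reads if total_reads is not None else len(reads)
    counts = _count_in_intervals(_positions_by_chrom(reads), acrs)
    rpm = counts * 1e6 / total if total > 0 else np.zeros_like(counts, dtype=float)
    eff = np.where(counts > 0, counts, pseudocount).astype(float)
    log10_rpm = np.log10(eff * 1e6 / total) if total > 0 else np.full(len(acrs), np.nan)
    names = acrs["name"] if "name" in acrs.columns else [f"acr_{i}" for i in range(len(acrs))]
    return pd.DataFrame(
        {"acr_id": list(names), "count": counts, "rpm": rpm, "log10_rpm": log10_rpm}
    )


def build_signal_table(
    samples: Mapping[tuple[str, str], pd.DataFrame],
    acrs: pd.DataFrame,
    totals: Mapping[tuple[str, str], int] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Long signal table over (stage, replicate) samples of read ends."""
    frames = []
    for (stage, rep), reads in samples.items():
        total = totals[(stage, rep)] if totals is not None else None
        tab = quantify_signal(reads, acrs, total_reads=total, pseudocount=pseudocount)
        tab.insert(1, "stage", stage)
        tab.insert(2, "replicate", rep)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def frip(reads: pd.DataFrame, acrs: pd.DataFrame) -> float:
    """Fraction of all aligned reads whose 5' ends fall inside ACRs.

    ENCODE-style quality bound: values > 0.2 are acceptable for ATAC-seq.
    """
    if len(reads) == 0:
        raise ValueError("FRiP undefined for zero reads")
    counts = _count_in_intervals(_positions_by_chrom(reads), acrs)
    return float(counts.sum()) / len(reads)


def replicate_correlation(signal_table: pd.DataFrame, stage: str | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of replicate log10-RPM signal at ACRs.

    Returns a symmetric matrix with unit diagonal.  A zero-variance replicate
    yields NaN entries and a warning.
    """
    tab = signal_table if stage is None else signal_table[signal_table["stage"] == stage]
    wide = tab.pivot_table(index="acr_id", columns="replicate", values="log10_rpm")
    if wide.shape[1] < 2:
        raise ValueError("need at least two replicates sharing an ACR universe")
    degenerate = [c for c in wide.columns if np.isclose(wide[c].std(ddof=0), 0.0)]
    if degenerate:
        warnings.warn(f"zero-variance replicate(s): {degenerate}; entries undefined",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = wide.corr(method="pearson")
    for c in corr.columns:
        corr.loc[c, c] = 1.0
    for c in degenerate:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr


# ----------------------------------------------------------------------
# genomic context


@dataclass
class GeneAnnotation:
    """Minimal gene annotation: gene bodies, strands, TSSs and exons.

    ``genes``: gene_id, chrom, strand, start, end (0-based half-open body).
    ``exons``: gene_id, chrom, start, end.  ``tss``: chrom, strand, pos - by
    default one per gene derived from the strand, but genes may list several.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    tss: pd.DataFrame

    @classmethod
    def from_tables(cls, genes: pd.DataFrame, exons: pd.DataFrame,
                    tss: pd.DataFrame | None = None) -> "GeneAnnotation":
        bad = ~genes["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"gene(s) without a valid strand: {list(genes.loc[bad, 'gene_id'])}")
        if tss is None:
            pos = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
            tss = pd.DataFrame({"gene_id": genes["gene_id"], "chrom": genes["chrom"],
                                "strand": genes["strand"], "pos": pos})
        return cls(genes.reset_index(drop=True), exons.reset_index(drop=True),
                   tss.reset_index(drop=True))


def _tss_windows(tss: pd.DataFrame, upstream: int, downstream: int) -> pd.DataFrame:
    """Strand-aware windows spanning ``upstream`` bp before to ``downstream``
    bp after each TSS (TSS base included)."""
    plus = tss["strand"] == "+"
    start = np.where(plus, tss["pos"] - upstream, tss["pos"] - downstream)
    end = np.where(plus, tss["pos"] + downstream + 1, tss["pos"] + upstream + 1)
    return pd.DataFrame({"chrom": tss["chrom"], "start": np.maximum(start, 0), "end": end})


def _interval_index(df: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        s, e = merge_intervals(grp["start"], grp["end"])
        out[chrom] = np.column_stack([s, e])
    return out


def _overlaps_any(chrom: str, start: int, end: int, index: dict[str, np.ndarray]) -> bool:
    return _overlap_sum(start, end, index.get(chrom)) > 0


def classify_genomic_context(
    acrs: pd.DataFrame,
    annotation: GeneAnnotation,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 1000,
    proximal_upstream: int = 5000,
    proximal_downstream: int = 1000,
) -> pd.Series:
    """Label each ACR promoter / exon / intron / proximal / distal.

    Precedence chain: promoter (2 kb upstream to 1 kb downstream of any TSS)
    beats exon beats intron (gene body) beats proximal (5 kb upstream to 1 kb
    downstream of any TSS) beats distal.  Labels partition the ACRs.
    """
    promoters = _interval_index(_tss_windows(annotation.tss, promoter_upstream,
                                             promoter_downstream))
    proximal = _interval_index(_tss_windows(annotation.tss, proximal_upstream,
                                            proximal_downstream))
    exons = _interval_index(annotation.exons)
    bodies = _interval_index(annotation.genes)
    labels = []
    for row in acrs.itertuples(index=False):
        if _overlaps_any(row.chrom, row.start, row.end, promoters):
            labels.append("promoter")
        elif _overlaps_any(row.chrom, row.start, row.end, exons):
            labels.append("exon")
        elif _overlaps_any(row.chrom, row.start, row.end, bodies):
            labels.append("intron")
        elif _overlaps_any(row.chrom, row.start, row.end, proximal):
            labels.append("proximal")
        else:
            labels.append("distal")
    index = acrs["name"] if "name" in acrs.columns else pd.RangeIndex(len(acrs))
    return pd.Series(labels, index=list(index), name="context")


@dataclass
class EnrichmentResult:
    table: np.ndarray  # rows: observed/control, cols: in-promoter / not
    odds_ratio: float
    p_value: float
    controls: pd.DataFrame


def place_random_controls(
    acrs: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    seed: int,
    max_attempts: int = 1000,
) -> pd.DataFrame:
    """Length-matched random control regions, mutually non-overlapping.

    Controls are placed by seeded rejection sampling uniformly over the
    genome; only overlap among controls themselves is rejected.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    lengths = sorted((int(r.end - r.start) for r in acrs.itertuples(index=False)),
                     reverse=True)
    for i, length in enumerate(lengths):
        for attempt in range(max_attempts):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            if chrom_sizes[chrom] <= length:
                continue
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            end = start + length
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                rows.append((chrom, start, end, f"control_{i}"))
                break
        else:
            raise RuntimeError(
                f"failed to place a {length} bp control after {max_attempts} attempts"
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def promoter_enrichment(
    acrs: pd.DataFrame,
    annotation: GeneAnnotation,
    chrom_sizes: Mapping[str, int],
    seed: int,
    controls: pd.DataFrame | None = None,
    **context_kwargs,
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of ACR promoter overlap vs random controls.

    Controls are length-matched 1:1 to the ACRs (see
    :func:`place_random_controls`); pass ``controls`` explicitly to force a
    placement.  The 2x2 table rows are {observed, control} and columns
    {promoter-overlapping, not}.
    """
    if controls is None:
        controls = place_random_controls(acrs, chrom_sizes, seed)
    obs_ctx = classify_genomic_context(acrs, annotation, **context_kwargs)
    ctl_ctx = classify_genomic_context(controls, annotation, **context_kwargs)
    a = int((obs_ctx == "promoter").sum())
    b = len(obs_ctx) - a
    c = int((ctl_ctx == "promoter").sum())
    d = len(ctl_ctx) - c
    table = np.array([[a, b], [c, d]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(table=table, odds_ratio=float(odds), p_value=float(p),
                            controls=controls)
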