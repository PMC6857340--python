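"""Relative accessibility signal by evolutionary age and recapitulation statistics.

For every developmental stage (and biological replicate), the signal of all
ACR segments in one age category is summed and expressed as a percentage of
the total over all categories ("relative signal").  A recapitulative pattern
means younger categories attain their maximum relative signal at later
stages; it is summarized here by

* the per-category peak stage (argmax of the replicate-mean trajectory,
  ties broken toward the later stage),
* a Kendall tau-b concordance between category youngness and peak stage,
  restricted to a stage window starting at the phylotypic stage, with an
  exact or sampled permutation p-value, and
* per-category Kruskal-Wallis tests across stages (replicate values), with
  Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evo_age import AgedSegment
from .io import merge_intervals

TABLE_COLS = ["stage", "category", "rank", "replicate", "percent"]


@dataclass
class RelativeTable:
    """Tidy stage x category x replicate percentage table.

    ``data`` columns: stage, category (node id), rank, replicate, percent.
    Percentages sum to 100 per (stage, replicate).  ``mode`` records the
    quantity summed: 'signal', 'length', 'conserved' or 'expression'.
    """

    data: pd.DataFrame
    mode: str
    stage_order: tuple[str, ...]

    def mean_trajectories(self) -> pd.DataFrame:
        """Replicate-mean percentage, categories x stages (stage order kept)."""
        wide = (
            self.data.groupby(["rank", "category", "stage"], sort=True)["percent"]
            .mean()
            .reset_index()
            .pivot(index=["rank", "category"], columns="stage", values="percent")
        )
        return wide[list(self.stage_order)]

    def check_normalization(self, tol: float = 1e-9) -> None:
        sums = self.data.groupby(["stage", "replicate"])["percent"].sum()
        bad = sums[(sums - 100.0).abs() > tol]
        if len(bad):
            raise AssertionError(f"percentages do not sum to 100: {bad.to_dict()}")


def _percentages(
    sums: pd.DataFrame, stage_order: Sequence[str], mode: str
) -> RelativeTable:
    """Normalize per-(stage, replicate) category sums to percentages."""
    totals = sums.groupby(["stage", "replicate"])["value"].transform("sum")
    zero = sums.loc[totals == 0, ["stage", "replicate"]].drop_duplicates()
    if len(zero):
        raise ValueError(f"zero total in stage/replicate cells: {zero.to_dict('records')}")
    out = sums.copy()
    out["percent"] = 100.0 * out["value"] / totals
    out = out[["stage", "category", "rank", "replicate", "percent"]]
    return RelativeTable(out.reset_index(drop=True), mode, tuple(stage_order))


def _segment_frame(aged_segments: Iterable[AgedSegment]) -> pd.DataFrame:
    rows = [
        (g.chrom, g.start, g.end, g.length, g.acr_id, g.category.node_id, g.category.rank)
        for g in aged_segments
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length", "acr_id", "category", "rank"]
    )


def relative_signal_table(
    aged_segments: Sequence[AgedSegment],
    signal_table: pd.DataFrame,
    stages: Sequence[str],
    segment_counts: pd.DataFrame | None = None,
) -> RelativeTable:
    """Relative signal per age category, stage and replicate.

    ``signal_table`` is a long table (acr_id, stage, replicate, count) of
    parent-ACR signal.  When ``segment_counts`` (same layout keyed by segment
    index) is not given, each segment inherits its parent ACR's signal
    apportioned by length - appropriate when reads are uniform within the
    ACR.  Pass recounted per-segment 5'-end counts for exact attribution.
    """
    segs = _segment_frame(aged_segments)
    if segs.empty:
        raise ValueError("no aged segments supplied")
    if segment_counts is not None:
        merged = segment_counts.copy()
        required = {"segment_index", "stage", "replicate", "count"}
        if not required <= set(merged.columns):
            raise ValueError(f"segment_counts needs columns {sorted(required)}")
        merged = merged.merge(
            segs[["category", "rank"]].reset_index(names="segment_index"),
            on="segment_index", how="left",
        )
        merged["value"] = merged["count"].astype(float)
    else:
        acr_len = segs.groupby("acr_id")["length"].transform("sum")
        segs = segs.assign(frac=segs["length"] / acr_len)
        merged = signal_table.merge(segs[["acr_id", "category", "rank", "frac"]],
                                    on="acr_id", how="inner")
        merged["value"] = merged["count"].astype(float) * merged["frac"]
    sums = (
        merged.groupby(["stage", "replicate", "category", "rank"], sort=True)["value"]
        .sum()
        .reset_index()
    )
    return _percentages(sums, stages, "signal")


def relative_length_table(
    aged_segments: Sequence[AgedSegment],
    per_stage_acr_membership: Mapping[str, set[str]],
    stages: Sequence[str],
) -> RelativeTable:
    """Relative summed segment length per age category and stage.

    ``per_stage_acr_membership`` maps each stage to the set of parent ACR ids
    whose peaks were called at that stage.  Length mode has no replicate
    axis; a single 'pooled' replicate is emitted.
    """
    segs = _segment_frame(aged_segments)
    rows = []
    for stage in stages:
        members = per_stage_acr_membership.get(stage, set())
        sub = segs[segs["acr_id"].isin(members)]
        sums = sub.groupby(["category", "rank"], sort=True)["length"].sum().reset_index()
        for r in sums.itertuples(index=False):
            rows.append((stage, r.category, r.rank, "pooled", float(r.length)))
    sums = pd.DataFrame(rows, columns=["stage", "category", "rank", "replicate", "value"])
    table = _percentages(sums, stages, "length")
    return table


def restrict_to_conserved(
    aged_segments: Sequence[AgedSegment], conserved: pd.DataFrame
) -> list[AgedSegment]:
    """Clip aged segments to conserved (negatively selected) elements.

    Intersection pieces inherit the parent's category and status.  Because
    conserved elements require alignment to at least one other genome,
    reference-specific segments vanish by construction when the conserved set
    is derived from cross-species alignments.
    """
    merged: dict[str, np.ndarray] = {}
    for chrom, grp in conserved.groupby("chrom", sort=True):
        s, e = merge_intervals(grp["start"], grp["end"])
        merged[chrom] = np.column_stack([s, e])
    out = []
    for g in aged_segments:
        ivs = merged.get(g.chrom)
        if ivs is None:
            continue
        lo = int(np.searchsorted(ivs[:, 1], g.start, side="right"))
        for i in range(lo, len(ivs)):
            if ivs[i, 0] >= g.end:
                break
            s = max(g.start, int(ivs[i, 0]))
            e = min(g.end, int(ivs[i, 1]))
            if e > s:
                out.append(AgedSegment(g.chrom, s, e, g.acr_id, g.category, g.status, g.method))
    return out


# ----------------------------------------------------------------------
# peak stages and concordance


def peak_stage(table: RelativeTable, stages: Sequence[str] | None = None) -> pd.DataFrame:
    """Stage index of the maximum replicate-mean percentage per category.

    Ties are broken toward the LATER stage (the hypothesis concerns late
    activation).  ``stages`` restricts the argmax to a sub-window; indices
    refer to the full stage order either way.
    """
    order = list(table.stage_order)
    window = [s for s in order if stages is None or s in set(stages)]
    if len(window) < 2 and stages is None:
        raise ValueError("need at least two stages")
    traj = table.mean_trajectories()[window].to_numpy()
    rev = traj[:, ::-1]
    peak_in_window = traj.shape[1] - 1 - np.argmax(rev, axis=1)
    full_index = np.array([order.index(s) for s in window])
    ranks = [idx[0] for idx in table.mean_trajectories().index]
    cats = [idx[1] for idx in table.mean_trajectories().index]
    return pd.DataFrame(
        {
            "category": cats,
            "rank": ranks,
            "peak_stage": full_index[peak_in_window],
            "peak_stage_name": [order[i] for i in full_index[peak_in_window]],
        }
    ).sort_values("rank", ignore_index=True)


_EXACT_LIMIT = 8


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.kendalltau(x, y, variant="b").statistic)


def _tau_b_many(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorized Kendall tau-b of one x against many candidate y rows."""
    n = x.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    sx = np.sign(x[jj] - x[ii])
    dy = ys[:, jj] - ys[:, ii]
    sy = np.sign(dy)
    conc = (sx[None, :] * sy).sum(axis=1)
    n0 = n * (n - 1) / 2
    tx = n0 - np.count_nonzero(sx)  # pairs tied in x
    ty = n0 - np.count_nonzero(sy, axis=1)
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, conc / denom, np.nan)


def _permutation_pvalue(
    youngness: np.ndarray, peaks: np.ndarray, n_perm: int, seed: int
) -> tuple[float, float, str]:
    """Two-sided p for |tau-b| under permutation of the peak-stage vector.

    Exact enumeration up to 8 categories, seeded sampling otherwise.
    """
    obs = _tau_b(youngness, peaks)
    n = len(peaks)
    if n <= _EXACT_LIMIT:
        perms = np.array(list(itertools.permutations(peaks)))
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(peaks) for _ in range(n_perm)])
        method = "permutation"
    taus = _tau_b_many(youngness.astype(float), perms.astype(float))
    taus = taus[~np.isnan(taus)]
    if np.isnan(obs) or len(taus) == 0:
        return obs, float("nan"), method
    p = float(np.mean(np.abs(taus) >= abs(obs) - 1e-12))
    return obs, p, method


@dataclass
class RecapResult:
    """Concordance between category age order and peak-stage order."""

    tau: float
    p_value: float
    method: str  # 'exact' or 'permutation'
    window_start_stage: str
    peaks: pd.DataFrame  # category, rank, peak_stage, peak_stage_name, in_window
    n_categories: int


def recap_concordance(
    table: RelativeTable,
    window_start_stage: str | int = 0,
    n_perm: int = 10_000,
    seed: int = 0,
) -> RecapResult:
    """Kendall tau-b between category youngness and in-window peak stage.

    The stage window starts at the (configured) phylotypic stage.  Categories
    whose full-trajectory peak falls before the window are excluded so that
    pre-window behaviour cannot disturb the in-window concordance.  tau = 1
    means younger categories peak at strictly later stages.
    """
    order = list(table.stage_order)
    if isinstance(window_start_stage, int):
        w0 = window_start_stage
    else:
        w0 = order.index(window_start_stage)
    window = order[w0:]
    full_peaks = peak_stage(table)
    in_window = full_peaks["peak_stage"] >= w0
    win_peaks = peak_stage(table, stages=window)
    merged = full_peaks[["category", "rank"]].copy()
    merged["in_window"] = in_window.to_numpy()
    merged = merged.merge(win_peaks[["category", "peak_stage", "peak_stage_name"]],
                          on="category")
    use = merged[merged["in_window"]]
    if len(use) < 3:
        raise ValueError("need at least three categories peaking inside the window")
    youngness = -use["rank"].to_numpy(dtype=float)  # larger = younger
    peaks = use["peak_stage"].to_numpy(dtype=float)
    tau, p, method = _permutation_pvalue(youngness, peaks, n_perm=n_perm, seed=seed)
    return RecapResult(
        tau=tau, p_value=p, method=method, window_start_stage=order[w0],
        peaks=merged, n_categories=int(len(use)),
    )


def kw_test(table: RelativeTable, fdr_q: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis test of a stage effect per category, BH-adjusted.

    Groups are the replicate percentage values at each stage.  Degenerate
    categories (all values identical) get H = 0, p = 1.
    """
    rows = []
    for (rank, cat), grp in table.data.groupby(["rank", "category"], sort=True):
        groups = [g["percent"].to_numpy() for _, g in grp.groupby("stage", sort=True)]
        if len(groups) < 2:
            raise ValueError("need at least two stages")
        values = np.concatenate(groups)
        if np.allclose(values, values[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append({"category": cat, "rank": rank, "H": float(h), "p": float(p)})
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p"], alpha=fdr_q, method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out


def plot_trajectories(table: RelativeTable, path: str, peaks: pd.DataFrame | None = None):
    """Stacked per-category trajectory panels (replicate mean +- SD)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = table.mean_trajectories()
    sd = (
        table.data.groupby(["rank", "category", "stage"])["percent"].std()
        .reset_index()
        .pivot(index=["rank", "category"], columns="stage", values="percent")
    )[list(table.stage_order)]
    n = len(traj)
    fig, axes = plt.subplots(n, 1, figsize=(6, 1.4 * n), sharex=True, squeeze=False)
    x = np.arange(len(table.stage_order))
    for ax, (idx, row) in zip(axes[:, 0], traj.iterrows()):
        ax.errorbar(x, row.to_numpy(), yerr=sd.loc[idx].to_numpy(), fmt="-o", ms=3)
        ax.set_ylabel(f"rank {idx[0]}", fontsize=8)
        if peaks is not None:
            pk = peaks.loc[peaks["category"] == idx[1], "peak_stage"]
            if len(pk):
                ax.axvline(int(pk.iloc[0]), color="red", lw=0.8, alpha=0.6)
    axes[-1, 0].set_xticks(x)
    axes[-1, 0].set_xticklabels(table.stage_order, rotation=45, fontsize=7)
    fig.suptitle(f"relative {table.mode} by age category")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
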