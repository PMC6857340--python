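"""Species-sharing profile of a reference genome from pairwise-alignment coverage.

Each query species contributes a set of reference intervals in which it has a
similar (alignable) sequence.  Overlaying all species partitions every
chromosome into maximal segments, each labelled with the exact set of species
sharing it; uncovered stretches carry the empty set and are interpreted
downstream as reference-specific sequence.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import merge_intervals, read_bed


@dataclass
class CoverageSet:
    """Sorted, merged, non-overlapping coverage intervals of one query species."""

    species: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    # chrom -> (n, 2) int64 array of [start, end)

    @classmethod
    def from_records(cls, species: str, records: Iterable[tuple[str, int, int]]) -> "CoverageSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {chrom}:[{start}, {end})")
            by_chrom.setdefault(chrom, []).append((start, end))
        intervals = {}
        for chrom, ivs in by_chrom.items():
            s, e = merge_intervals([i[0] for i in ivs], [i[1] for i in ivs])
            intervals[chrom] = np.column_stack([s, e])
        return cls(species, intervals)

    def total_bases(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values()))

    def n_intervals(self) -> int:
        return int(sum(len(iv) for iv in self.intervals.values()))


def read_coverage_beds(paths_by_species: Mapping[str, str]) -> list[CoverageSet]:
    """Read one BED3+ file per query species; intervals are sorted and merged."""
    out = []
    for species, path in paths_by_species.items():
        df = read_bed(path, min_cols=3)
        records = list(zip(df["chrom"], df["start"], df["end"])) if len(df) else []
        out.append(CoverageSet.from_records(species, records))
    return out


@dataclass
class SharingProfile:
    """Maximal segments tiling each chromosome with their species-sharing sets.

    Per chromosome: ``starts``/``ends`` (sorted, disjoint, tiling [0, length))
    and one frozenset of species names per segment.  Adjacent segments always
    differ in sharing set.
    """

    chrom_sizes: dict[str, int]
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    sets: dict[str, list[frozenset[str]]]

    def query(self, chrom: str, start: int, end: int) -> list[tuple[int, int, frozenset[str]]]:
        """Sub-segments (clipped to [start, end)) tiling the query interval."""
        if chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        if not (0 <= start <= end <= size):
            raise ValueError(f"interval [{start}, {end}) outside {chrom} bounds [0, {size})")
        if start == end:
            return []
        starts = self.starts[chrom]
        ends = self.ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        out = []
        for i in range(lo, len(starts)):
            if starts[i] >= end:
                break
            out.append((max(int(starts[i]), start), min(int(ends[i]), end), self.sets[chrom][i]))
        return out

    def to_bed(self) -> pd.DataFrame:
        """BED with the sharing set comma-joined in the name column ('.' = empty)."""
        rows = []
        for chrom in self.chrom_sizes:
            for s, e, ss in zip(self.starts[chrom], self.ends[chrom], self.sets[chrom]):
                rows.append((chrom, int(s), int(e), ",".join(sorted(ss)) if ss else "."))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def build_sharing_profile(
    coverages: Iterable[CoverageSet], chrom_sizes: Mapping[str, int]
) -> SharingProfile:
    """Partition every chromosome into maximal segments by exact sharing set.

    Uncovered space yields empty-set segments, so per chromosome the segments
    tile exactly [0, chrom length).  The result is invariant under permutation
    of the input species order.
    """
    coverages = list(coverages)
    for cov in coverages:
        for chrom, iv in cov.intervals.items():
            if chrom not in chrom_sizes:
                raise ValueError(f"{cov.species}: unknown chromosome {chrom!r}")
            if len(iv) and iv[:, 1].max() > chrom_sizes[chrom]:
                raise ValueError(
                    f"{cov.species}: interval beyond {chrom} length {chrom_sizes[chrom]}"
                )
    starts_out: dict[str, np.ndarray] = {}
    ends_out: dict[str, np.ndarray] = {}
    sets_out: dict[str, list[frozenset[str]]] = {}
    species_sorted = sorted(c.species for c in coverages)
    cov_by_species = {c.species: c for c in coverages}
    for chrom, size in chrom_sizes.items():
        bounds = {0, size}
        for cov in coverages:
            iv = cov.intervals.get(chrom)
            if iv is not None and len(iv):
                bounds.update(int(x) for x in iv[:, 0])
                bounds.update(int(x) for x in iv[:, 1])
        bpts = np.array(sorted(bounds), dtype=np.int64)
        n_seg = len(bpts) - 1
        seg_sets: list[set[str]] = [set() for _ in range(n_seg)]
        for sp in species_sorted:
            iv = cov_by_species[sp].intervals.get(chrom)
            if iv is None or not len(iv):
                continue
            # every interval boundary is a breakpoint, so coverage is constant
            # on each elementary segment
            idx = np.searchsorted(iv[:, 0], bpts[:-1], side="right") - 1
            covered = (idx >= 0) & (iv[np.clip(idx, 0, None), 1] > bpts[:-1])
            for i in np.nonzero(covered)[0]:
                seg_sets[i].add(sp)
        # merge adjacent segments with identical sets
        m_starts, m_ends, m_sets = [], [], []
        for i in range(n_seg):
            fs = frozenset(seg_sets[i])
            if m_sets and m_sets[-1] == fs:
                m_ends[-1] = int(bpts[i + 1])
            else:
                m_starts.append(int(bpts[i]))
                m_ends.append(int(bpts[i + 1]))
                m_sets.append(fs)
        starts_out[chrom] = np.array(m_starts, dtype=np.int64)
        ends_out[chrom] = np.array(m_ends, dtype=np.int64)
        sets_out[chrom] = m_sets
    return SharingProfile(dict(chrom_sizes), starts_out, ends_out, sets_out)


def profile_query(
    profile: SharingProfile, chrom: str, start: int, end: int
) -> list[tuple[int, int, frozenset[str]]]:
    """Functional alias for :meth:`SharingProfile.query`."""
    return profile.query(chrom, start, end)
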