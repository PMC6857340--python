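"""Evolutionary age assignment for accessible chromatin regions (methods I-IV).

An ACR's age is the time back to the most recent common ancestor of all
analyzed species sharing a similar sequence.  Four variants are supported:

* **I**   - subdivide each ACR by evolutionary origin; keep only strictly
            conserved segments (shared by every species of one monophyletic
            clade and no outgroup).
* **II**  - subdivide, but keep segments whose sharing pattern implies
            secondary loss in some clade members.
* **III** - one age per whole ACR: the oldest category whose sequence makes
            up at least one-third of the ACR; secondary-loss ACRs excluded.
* **IV**  - as III, secondary-loss ACRs retained.

Uncovered (empty sharing set) bases are reference-specific strict sequence,
not missing data: absence of pairwise coverage is the only signal the
youngest category has.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .coverage import SharingProfile
from .phylo import STRICT, SECONDARY_LOSS, AgeCategory, PhyloTree

METHODS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class AgedSegment:
    """A (sub)interval of an ACR with an age category and conservation status."""

    chrom: str
    start: int
    end: int
    acr_id: str
    category: AgeCategory
    status: str  # STRICT or SECONDARY_LOSS
    method: str

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_conservation(sharing_set: Iterable[str], tree: PhyloTree) -> str:
    """Strict iff the sharing set is exactly the clade of its implied MRCA.

    Any species missing from the clade implies the sequence was lost
    secondarily after its origin.  The empty set (reference-specific) is
    strict by definition.
    """
    sharing = frozenset(sharing_set)
    cat = tree.mrca_category(sharing)
    return STRICT if sharing == tree.clade_species(cat.node_id) else SECONDARY_LOSS


def subdivide_acr(
    acr: tuple[str, int, int, str],
    profile: SharingProfile,
    tree: PhyloTree,
    include_secondary_loss: bool,
    min_segment_len: int = 1,
    method_tag: str | None = None,
) -> list[AgedSegment]:
    """Split an ACR into segments of distinct evolutionary origin (methods I/II).

    Adjacent sub-segments with identical (category, status) are merged.  With
    ``include_secondary_loss`` False (method I) loss-implying segments are
    dropped; segments shorter than ``min_segment_len`` are dropped either way.
    """
    chrom, start, end, acr_id = acr
    tag = method_tag or ("II" if include_secondary_loss else "I")
    pieces: list[list] = []  # [start, end, category, status]
    for s, e, sharing in profile.query(chrom, start, end):
        cat = tree.mrca_category(sharing)
        status = classify_conservation(sharing, tree)
        if pieces and pieces[-1][2] == cat and pieces[-1][3] == status and pieces[-1][1] == s:
            pieces[-1][1] = e
        else:
            pieces.append([s, e, cat, status])
    out = []
    for s, e, cat, status in pieces:
        if status == SECONDARY_LOSS and not include_secondary_loss:
            continue
        if e - s < min_segment_len:
            continue
        out.append(AgedSegment(chrom, s, e, acr_id, cat, status, tag))
    return out


def whole_acr_age(
    acr: tuple[str, int, int, str],
    profile: SharingProfile,
    tree: PhyloTree,
    include_secondary_loss: bool,
    min_frac: float = 1.0 / 3.0,
    strict_threshold: bool = False,
    tie_break: str = "oldest",
    method_tag: str | None = None,
) -> AgedSegment | None:
    """Assign one age to a whole ACR by the one-third coverage rule (III/IV).

    Per candidate category, the covered lengths within the ACR are summed;
    categories reaching ``min_frac`` of the ACR length (``>=`` by default,
    ``>`` with ``strict_threshold``) are eligible and the oldest eligible one
    is assigned (``tie_break='coverage'`` picks the largest coverage instead).
    The ACR is strict only if every base supporting the assigned category is
    strict; a secondary-loss ACR is excluded under method III.  Returns None
    when no category is eligible or the ACR is excluded.
    """
    if tie_break not in ("oldest", "coverage"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    chrom, start, end, acr_id = acr
    tag = method_tag or ("IV" if include_secondary_loss else "III")
    length: dict[AgeCategory, int] = {}
    all_strict: dict[AgeCategory, bool] = {}
    for s, e, sharing in profile.query(chrom, start, end):
        cat = tree.mrca_category(sharing)
        status = classify_conservation(sharing, tree)
        length[cat] = length.get(cat, 0) + (e - s)
        all_strict[cat] = all_strict.get(cat, True) and (status == STRICT)
    acr_len = end - start
    threshold = min_frac * acr_len
    if strict_threshold:
        eligible = [c for c, ln in length.items() if ln > threshold]
    else:
        eligible = [c for c, ln in length.items() if ln >= threshold]
    if not eligible:
        return None
    if tie_break == "oldest":
        chosen = max(eligible, key=lambda c: c.rank)
    else:
        chosen = max(eligible, key=lambda c: (length[c], c.rank))
    status = STRICT if all_strict[chosen] else SECONDARY_LOSS
    if status == SECONDARY_LOSS and not include_secondary_loss:
        return None
    return AgedSegment(chrom, start, end, acr_id, chosen, status, tag)


def run_method(
    acrs: Iterable[tuple[str, int, int, str]],
    profile: SharingProfile,
    tree: PhyloTree,
    method: str,
    min_segment_len: int = 1,
    min_frac: float = 1.0 / 3.0,
    strict_threshold: bool = False,
    tie_break: str = "oldest",
) -> list[AgedSegment]:
    """Age every ACR under one of the four methods; stable coordinate order."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    out: list[AgedSegment] = []
    for acr in acrs:
        if method in ("I", "II"):
            out.extend(
                subdivide_acr(
                    acr, profile, tree,
                    include_secondary_loss=(method == "II"),
                    min_segment_len=min_segment_len, method_tag=method,
                )
            )
        else:
            seg = whole_acr_age(
                acr, profile, tree,
                include_secondary_loss=(method == "IV"),
                min_frac=min_frac, strict_threshold=strict_threshold,
                tie_break=tie_break, method_tag=method,
            )
            if seg is not None:
                out.append(seg)
    out.sort(key=lambda g: (g.chrom, g.start, g.end, g.acr_id))
    return out


def segments_to_bed(segments: Sequence[AgedSegment]) -> pd.DataFrame:
    """BED6+3 export: name=parent ACR id, extra columns category/status/method."""
    rows = [
        (
            g.chrom, g.start, g.end, g.acr_id, 0, ".",
            g.category.node_id, g.status, g.method,
        )
        for g in segments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "category", "status", "method",
        ],
    )


def category_status_counts(segments: Sequence[AgedSegment]) -> pd.DataFrame:
    """Structured log of counts per (category, status)."""
    df = segments_to_bed(segments)
    if df.empty:
        return pd.DataFrame(columns=["category", "status", "n"])
    return df.groupby(["category", "status"], sort=True).size().reset_index(name="n")
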