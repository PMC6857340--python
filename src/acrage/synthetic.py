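"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* a dated ladder species tree (reference + outgroups at increasing split
  times), giving one age category per reference-path node;
* a reference genome partitioned into segments with planted age categories;
  each segment is covered by exactly the species of its planted clade, minus
  independent Bernoulli secondary losses.  Losses never hit the clade's most
  distant species: losing it would change the observable MRCA itself, making
  the planted age unidentifiable rather than merely loss-affected;
* ACRs (single- or multi-origin) whose per-stage expected read counts follow
  a planted age-to-peak-stage schedule (discretized Gaussian bumps), with
  multiplicative lognormal replicate noise and Poisson counting noise; read
  5' ends are emitted pre-correction (minus the Tn5 +4/-5 shift) so the
  read-level operations are exercised;
* cross-species expression tables with an hourglass structure (species
  divergence minimal at a planted mid stage), per-gene age categories with a
  homolog presence/absence matrix, and a configurable "reuse" rate by which
  evolutionarily old genes acquire additional late expression - the
  mechanism that obscures recapitulation at the gene level.

Everything is reproducible from (config, seed), and a manifest records the
planted truth needed to score recovery exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import merge_intervals, write_bed, write_chrom_sizes
from .phylo import parse_tree


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a 7-leaf ladder tree (reference + 6 outgroups, hence 7
    age categories including reference-specific), 2 chromosomes of 500 kb,
    8 developmental stages with 3 biological replicates and 50k reads per
    replicate, and a 3-species hourglass expression panel of 6 stages with 2
    replicates.
    """

    # species tree (ladder): reference plus one species per split time
    reference: str = "ref"
    split_times: tuple[float, ...] = (90.0, 160.0, 320.0, 430.0, 530.0, 600.0)

    # genome and coverage
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    segment_min_len: int = 500
    segment_max_len: int = 2000
    # genomic proportion per category rank (0 = reference-specific, youngest);
    # young categories dominate, mirroring the scarcity of deeply conserved
    # non-coding sequence
    category_proportions: tuple[float, ...] = (0.30, 0.22, 0.16, 0.12, 0.10, 0.06, 0.04)
    loss_rate: float = 0.08  # per losable clade species per segment

    # ACRs and reads
    n_acrs: int = 210
    acr_length: int = 400
    multi_origin_rate: float = 0.4  # share of ACRs spanning two origins
    stages: tuple[str, ...] = ("st1", "st2", "st3", "st4", "st5", "st6", "st7", "st8")
    n_replicates: int = 3
    reads_per_replicate: int = 50_000
    background_frac: float = 0.2  # reads outside ACRs (FRiP ~ 0.8)
    noise_sd: float = 0.1  # lognormal sigma of the replicate factor; 0 = deterministic
    signal_base: float = 1.0
    signal_amplitude: float = 8.0  # peak/baseline per-bp rate ratio
    bump_sd: float = 0.75  # stage-index width of the accessibility bump
    peak_schedule: tuple[int, ...] | None = None  # stage index per rank; None = monotone
    replicate_peak_jitter_frac: float = 0.1

    # toy annotation and promoter placement preference
    n_annotation_genes: int = 40
    promoter_placement_prob: float = 0.0

    # expression / hourglass
    expression_species: tuple[str, ...] = ("ref", "s1", "s2")
    expression_stages: tuple[str, ...] = ("e1", "e2", "e3", "e4", "e5", "e6")
    expression_replicates: int = 2
    n_genes: int = 400
    hourglass_mid: int = 2  # stage index of maximal cross-species similarity
    hourglass_depth: float = 1.6
    divergence_min: float = 0.15
    reuse_rate: float = 0.5  # chance an old gene gains extra late expression
    gene_loss_rate: float = 0.12
    expr_noise_sd: float = 0.1
    expr_mu_sd: float = 0.6
    expr_stage_sd: float = 0.6
    expr_ar_phi: float = 0.9
    expr_bump_amp: float = 1.5
    expr_reuse_amp: float = 2.0
    ortho_missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.category_proportions) - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")
        if len(self.category_proportions) != len(self.split_times) + 1:
            raise ValueError("need one proportion per category (splits + reference)")
        for r in (self.loss_rate, self.multi_origin_rate, self.background_frac,
                  self.reuse_rate, self.gene_loss_rate, self.ortho_missing_rate,
                  self.promoter_placement_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        schedule = self.effective_schedule()
        if any(not 0 <= p < len(self.stages) for p in schedule):
            raise ValueError("peak stages must lie within the stage range")
        if not 0 <= self.hourglass_mid < len(self.expression_stages):
            raise ValueError("hourglass mid stage outside the expression stage range")

    # ------------------------------------------------------------------
    @property
    def species(self) -> tuple[str, ...]:
        """Non-reference species, youngest split first."""
        return tuple(f"s{i + 1}" for i in range(len(self.split_times)))

    @property
    def n_categories(self) -> int:
        return len(self.split_times) + 1

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "SimulationConfig":
        """Parse a plain ``key = value`` config file (python literals allowed)."""
        import ast

        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (x.strip() for x in line.split("=", 1))
                try:
                    values[key] = ast.literal_eval(raw)
                except (SyntaxError, ValueError):
                    values[key] = raw
        values.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**values)

    def effective_schedule(self) -> tuple[int, ...]:
        """Planted peak stage per rank; default: younger peaks strictly later."""
        if self.peak_schedule is not None:
            return tuple(self.peak_schedule)
        last = len(self.stages) - 1
        return tuple(max(last - rank, 0) for rank in range(self.n_categories))

    def newick(self) -> str:
        s = self.reference
        prev = 0.0
        for sp, t in zip(self.species, self.split_times):
            s = f"({s}:{t - prev},{sp}:{t})"
            prev = t
        return s + ";"

    def clade(self, rank: int) -> tuple[str, ...]:
        """Non-reference species sharing a region of category ``rank``."""
        return self.species[:rank]

    def trajectory(self, rank: int, stage_index: int) -> float:
        """Per-bp expected read rate (unnormalized) of a category at a stage."""
        peak = self.effective_schedule()[rank]
        return self.signal_base + self.signal_amplitude * math.exp(
            -((stage_index - peak) ** 2) / (2.0 * self.bump_sd**2)
        )


# ----------------------------------------------------------------------


@dataclass
class PlantedSegment:
    chrom: str
    start: int
    end: int
    rank: int
    lost: tuple[str, ...]  # clade species without coverage (secondary losses)


@dataclass
class PlantedACR:
    acr_id: str
    chrom: str
    start: int
    end: int
    parts: list[PlantedSegment]  # clipped to the ACR, in coordinate order


@dataclass
class TruthManifest:
    """Planted truth sufficient to score parameter recovery exactly."""

    seed: int
    config: dict
    tree_newick: str
    chrom_sizes: dict[str, int]
    segments: list[PlantedSegment]
    coverage_interval_counts: dict[str, int]
    acrs: list[PlantedACR]
    expected_methods: dict  # per acr_id: expected outcome per method I-IV
    expected_percent: dict  # stage -> {rank: analytic relative-signal %}
    schedule: dict  # rank -> planted peak stage index
    expression_truth: dict
    checksums: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1, sort_keys=True)


# ----------------------------------------------------------------------
# genome and coverage


def simulate_genome_and_coverage(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, int], list[PlantedSegment], dict[str, list[tuple[str, int, int]]]]:
    """Partition the genome into aged segments and derive species coverage.

    Adjacent segments always differ in category, so the sharing profile
    recovers the planted segmentation exactly.  Secondary losses are drawn
    Bernoulli(loss_rate) per clade species per segment, excluding the clade's
    most distant species (see module docstring).
    """
    props = np.asarray(config.category_proportions)
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    segments: list[PlantedSegment] = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        prev_rank = -1
        while pos < size:
            ln = int(rng.integers(config.segment_min_len, config.segment_max_len + 1))
            end = min(pos + ln, size)
            while True:
                rank = int(rng.choice(config.n_categories, p=props))
                if rank != prev_rank:
                    break
            clade = config.clade(rank)
            losable = clade[:-1]  # most distant species always retained
            lost = tuple(sp for sp in losable if rng.random() < config.loss_rate)
            segments.append(PlantedSegment(chrom, pos, end, rank, lost))
            prev_rank = rank
            pos = end
    coverage: dict[str, list[tuple[str, int, int]]] = {sp: [] for sp in config.species}
    for seg in segments:
        present = set(config.clade(seg.rank)) - set(seg.lost)
        for sp in present:
            coverage[sp].append((seg.chrom, seg.start, seg.end))
    return chrom_sizes, segments, coverage


def _sharing_set(config: SimulationConfig, seg: PlantedSegment) -> frozenset[str]:
    return frozenset(set(config.clade(seg.rank)) - set(seg.lost))


# ----------------------------------------------------------------------
# annotation


def simulate_annotation(
    config: SimulationConfig, chrom_sizes: dict[str, int], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy non-overlapping gene models (body + 2-4 exons) for context tests."""
    chroms = list(chrom_sizes)
    genes, exons = [], []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for i in range(config.n_annotation_genes):
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(2000, 8001))
            lo, hi = 6000, chrom_sizes[chrom] - length - 6000
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length
            if all(end + 5000 <= s or start - 5000 >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"gene{i:03d}"
                genes.append((gid, chrom, strand, start, end))
                n_ex = int(rng.integers(2, 5))
                cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_ex,
                                          replace=False))
                for j in range(n_ex):
                    exons.append((gid, chrom, int(cuts[2 * j]), int(cuts[2 * j + 1])))
                break
    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "start", "end"])
    exons_df = pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"])
    return genes_df, exons_df


# ----------------------------------------------------------------------
# ACRs and reads


def _clip_to_segments(
    chrom: str, start: int, end: int, segs_by_chrom: dict[str, list[PlantedSegment]]
) -> list[PlantedSegment]:
    parts = []
    for seg in segs_by_chrom[chrom]:
        if seg.end <= start or seg.start >= end:
            continue
        parts.append(
            PlantedSegment(chrom, max(seg.start, start), min(seg.end, end), seg.rank, seg.lost)
        )
    parts.sort(key=lambda p: p.start)
    return parts


def _expected_method_outcomes(
    config: SimulationConfig, acr: PlantedACR, min_frac: float = 1.0 / 3.0
) -> dict:
    """Expected age assignment per method, derived from the planted parts."""
    out: dict = {}
    kept_i, kept_ii = [], []
    for p in acr.parts:
        status = "strict" if not p.lost else "secondary_loss"
        rec = {"start": p.start, "end": p.end, "rank": p.rank, "status": status}
        kept_ii.append(rec)
        if status == "strict":
            kept_i.append(rec)
    out["I"] = kept_i
    out["II"] = kept_ii
    length: dict[int, int] = {}
    clean: dict[int, bool] = {}
    for p in acr.parts:
        length[p.rank] = length.get(p.rank, 0) + (p.end - p.start)
        clean[p.rank] = clean.get(p.rank, True) and not p.lost
    acr_len = acr.end - acr.start
    eligible = [r for r, ln in length.items() if ln >= min_frac * acr_len]
    if not eligible:
        out["III"] = None
        out["IV"] = None
    else:
        chosen = max(eligible)  # oldest planted origin
        status = "strict" if clean[chosen] else "secondary_loss"
        out["IV"] = {"rank": chosen, "status": status}
        out["III"] = {"rank": chosen, "status": status} if status == "strict" else None
    return out


def simulate_acrs(
    config: SimulationConfig,
    segments: list[PlantedSegment],
    annotation: pd.DataFrame,
    rng: np.random.Generator,
) -> list[PlantedACR]:
    """Place single- and multi-origin ACRs on the planted segments.

    Single-origin ACRs sit inside one segment (optionally biased into
    promoter windows of the toy annotation); multi-origin ACRs straddle a
    boundary between two segments with a 35-65% split, so that both origins
    clear the one-third rule and the expected whole-ACR age is the older one.
    """
    margin = 20
    acr_len = config.acr_length
    segs_by_chrom: dict[str, list[PlantedSegment]] = {}
    for seg in segments:
        segs_by_chrom.setdefault(seg.chrom, []).append(seg)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in segs_by_chrom}

    def free(chrom: str, start: int, end: int) -> bool:
        # keep a >= 1 bp gap so distinct ACRs never merge on consolidation
        return all(end < s or start > e for s, e in placed[chrom])

    n_multi = int(round(config.n_acrs * config.multi_origin_rate))
    n_single = config.n_acrs - n_multi
    per_cat = [n_single // config.n_categories] * config.n_categories
    for i in range(n_single - sum(per_cat)):
        per_cat[i % config.n_categories] += 1

    # promoter windows (for placement preference)
    prom_windows: list[tuple[str, int, int]] = []
    for row in annotation.itertuples(index=False):
        if row.strand == "+":
            prom_windows.append((row.chrom, max(row.start - 2000, 0), row.start + 1001))
        else:
            prom_windows.append((row.chrom, max(row.end - 1 - 1000, 0), row.end + 2000))

    acrs: list[PlantedACR] = []
    idx = 0

    def add(chrom: str, start: int, end: int) -> None:
        nonlocal idx
        parts = _clip_to_segments(chrom, start, end, segs_by_chrom)
        acrs.append(PlantedACR(f"ACR{idx:05d}", chrom, start, end, parts))
        placed[chrom].append((start, end))
        idx += 1

    # single-origin
    singles_by_cat: dict[int, list[PlantedSegment]] = {}
    for seg in segments:
        if seg.end - seg.start >= acr_len + 2 * margin:
            singles_by_cat.setdefault(seg.rank, []).append(seg)
    for rank, n_needed in enumerate(per_cat):
        candidates = list(singles_by_cat.get(rank, []))
        rng.shuffle(candidates)
        placed_n = 0
        for seg in candidates:
            if placed_n >= n_needed:
                break
            if config.promoter_placement_prob > 0 and rng.random() < config.promoter_placement_prob and prom_windows:
                # relocate into a random promoter window (composition then
                # derived from whatever segments underlie the new location)
                w = prom_windows[int(rng.integers(len(prom_windows)))]
                start = int(rng.integers(max(w[1] - acr_len + 1, margin),
                                         min(w[2], config.chrom_length - acr_len - margin)))
                chrom = w[0]
            else:
                chrom = seg.chrom
                start = int(rng.integers(seg.start + margin, seg.end - acr_len - margin + 1))
            if free(chrom, start, start + acr_len):
                add(chrom, start, start + acr_len)
                placed_n += 1
        if placed_n < n_needed:
            raise RuntimeError(
                f"could not place {n_needed} single-origin ACRs for rank {rank}; "
                "enlarge the genome or shorten the ACRs"
            )

    # multi-origin: straddle boundaries between adjacent segments
    boundaries = []
    for chrom, segs in segs_by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            boundaries.append((a, b))
    rng.shuffle(boundaries)
    placed_m = 0
    for a, b in boundaries:
        if placed_m >= n_multi:
            break
        u = rng.uniform(0.35, 0.65)
        left = int(round(u * acr_len))
        start, end = a.end - left, a.end + (acr_len - left)
        if start < a.start + margin or end > b.end - margin:
            continue
        if free(a.chrom, start, end):
            add(a.chrom, start, end)
            placed_m += 1
    if placed_m < n_multi:
        raise RuntimeError("could not place the requested multi-origin ACRs")
    acrs.sort(key=lambda a: (a.chrom, a.start))
    return acrs


def _expected_part_weights(
    config: SimulationConfig, acrs: list[PlantedACR]
) -> tuple[np.ndarray, list[tuple[int, PlantedSegment]]]:
    """Unnormalized expected counts per (part, stage): trajectory x length."""
    parts = []
    for ai, acr in enumerate(acrs):
        for p in acr.parts:
            parts.append((ai, p))
    n_stages = len(config.stages)
    w = np.empty((len(parts), n_stages))
    for i, (_, p) in enumerate(parts):
        for s in range(n_stages):
            w[i, s] = config.trajectory(p.rank, s) * (p.end - p.start)
    return w, parts


def simulate_reads(
    config: SimulationConfig,
    acrs: list[PlantedACR],
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], pd.DataFrame], dict]:
    """Per-(stage, replicate) raw read-end tables plus analytic expectations.

    Expected in-ACR reads per stage are normalized to
    ``(1 - background_frac) * reads_per_replicate`` (emulating read-depth
    control), distributed over ACR parts proportionally to trajectory x
    length, then perturbed by a lognormal replicate factor per (ACR, stage,
    replicate) and Poisson counting noise.  With ``noise_sd`` = 0 the counts
    are deterministic (rounded expectations, no Poisson draw).  Read
    positions are uniform within their part; emitted positions are the raw
    (pre-Tn5-correction) 5' ends.
    """
    w, parts = _expected_part_weights(config, acrs)
    n_stages = len(config.stages)
    target_in = (1.0 - config.background_frac) * config.reads_per_replicate
    n_bg = config.reads_per_replicate - int(round(target_in))
    expected = w * (target_in / w.sum(axis=0))  # parts x stages
    if config.noise_sd == 0:
        det_counts = np.round(expected).astype(np.int64)
        basis = det_counts.astype(float)  # percentages exact w.r.t. emitted reads
    else:
        det_counts = None
        basis = expected

    # analytic relative-signal expectation per rank and stage
    ranks = np.array([p.rank for _, p in parts])
    expected_percent: dict[str, dict[int, float]] = {}
    for s, stage in enumerate(config.stages):
        per_rank: dict[int, float] = {}
        for r in range(config.n_categories):
            per_rank[r] = float(basis[ranks == r, s].sum())
        total = sum(per_rank.values())
        expected_percent[stage] = {r: 100.0 * v / total for r, v in per_rank.items()
                                   if v > 0}

    chroms = list(chrom_sizes)
    chrom_w = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    acr_index = np.array([ai for ai, _ in parts])
    samples: dict[tuple[str, str], pd.DataFrame] = {}
    for s, stage in enumerate(config.stages):
        for r in range(config.n_replicates):
            rep = f"rep{r + 1}"
            if config.noise_sd > 0:
                factor = rng.lognormal(
                    -config.noise_sd**2 / 2.0, config.noise_sd, size=len(acrs)
                )
                lam = expected[:, s] * factor[acr_index]
                counts = rng.poisson(lam)
            else:
                counts = det_counts[:, s]
            rec_chrom, rec_pos, rec_strand = [], [], []
            for i, (_, p) in enumerate(parts):
                c = int(counts[i])
                if c == 0:
                    continue
                pos = rng.integers(p.start, p.end, size=c)
                strand = np.where(rng.random(c) < 0.5, "+", "-")
                raw = np.where(strand == "+", pos - 4, pos + 5)
                rec_chrom.append(np.full(c, p.chrom))
                rec_pos.append(raw)
                rec_strand.append(strand)
            # background reads, uniform over the genome
            if n_bg > 0:
                n_bg_draw = n_bg if config.noise_sd == 0 else int(rng.poisson(n_bg))
                bg_chrom = rng.choice(chroms, size=n_bg_draw, p=chrom_w)
                bg_pos = np.array(
                    [rng.integers(16, chrom_sizes[c] - 16) for c in bg_chrom],
                    dtype=np.int64,
                )
                bg_strand = np.where(rng.random(n_bg_draw) < 0.5, "+", "-")
                bg_raw = np.where(bg_strand == "+", bg_pos - 4, bg_pos + 5)
                rec_chrom.append(bg_chrom)
                rec_pos.append(bg_raw)
                rec_strand.append(bg_strand)
            df = pd.DataFrame(
                {
                    "chrom": np.concatenate(rec_chrom),
                    "pos": np.concatenate(rec_pos).astype(np.int64),
                    "strand": np.concatenate(rec_strand),
                }
            ).sort_values(["chrom", "pos", "strand"], ignore_index=True)
            samples[(stage, rep)] = df
    truth = {"expected_percent": expected_percent}
    return samples, truth


def simulate_peak_sets(
    config: SimulationConfig, acrs: list[PlantedACR], rng: np.random.Generator
) -> dict[str, dict[str, pd.DataFrame]]:
    """Pooled and replicate peak BED frames per stage.

    Replicate peaks are the true ACR intervals shifted by up to
    ``replicate_peak_jitter_frac`` of their length, preserving well over 50%
    overlap so the consensus filter retains every true ACR.
    """
    out: dict[str, dict[str, pd.DataFrame]] = {}
    base = pd.DataFrame(
        [(a.chrom, a.start, a.end, a.acr_id) for a in acrs],
        columns=["chrom", "start", "end", "name"],
    )
    jit = config.replicate_peak_jitter_frac
    for stage in config.stages:
        stage_sets = {"pooled": base.copy()}
        for r in range(config.n_replicates):
            shift = np.round(
                rng.uniform(-jit, jit, size=len(base)) * (base["end"] - base["start"])
            ).astype(np.int64)
            rep = base.copy()
            rep["start"] = np.maximum(rep["start"] + shift, 0)
            rep["end"] = rep["end"] + shift
            stage_sets[f"rep{r + 1}"] = rep
        out[stage] = stage_sets
    return out


def simulate_acrs_and_reads(
    config: SimulationConfig,
    segments: list[PlantedSegment],
    annotation: pd.DataFrame,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[list[PlantedACR], dict[tuple[str, str], pd.DataFrame], dict[str, dict[str, pd.DataFrame]], dict]:
    """Place ACRs, draw per-sample read ends and emit peak sets in one step.

    Convenience wrapper around :func:`simulate_acrs`, :func:`simulate_reads`
    and :func:`simulate_peak_sets` sharing one generator stream.
    """
    acrs = simulate_acrs(config, segments, annotation, rng)
    samples, truth = simulate_reads(config, acrs, chrom_sizes, rng)
    peaks = simulate_peak_sets(config, acrs, rng)
    return acrs, samples, peaks, truth


# ----------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, pd.DataFrame], dict[tuple[str, str], pd.DataFrame], pd.DataFrame, dict]:
    """Per-species expression tables, orthology maps, presence matrix, truth.

    Log-expression of gene g in species sp at stage s is
    ``mu_g + t_g(s) + bump_g(s) + d(s) * delta_{sp,g} + noise`` with t an
    AR(1) stage profile shared across species, bump the gene's age-linked
    activation (peaking per the planted schedule, plus a late reuse bump for
    a ``reuse_rate`` share of old genes), and d(s) the hourglass divergence
    profile, minimal at the planted mid stage.
    """
    n_stages = len(config.expression_stages)
    n_genes = config.n_genes
    props = np.asarray(config.category_proportions)
    gene_ranks = rng.choice(config.n_categories, size=n_genes, p=props)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]

    mid = config.hourglass_mid
    dist = np.abs(np.arange(n_stages) - mid)
    d_profile = config.divergence_min + config.hourglass_depth * (
        dist / max(dist.max(), 1)
    )

    mu = rng.normal(2.0, config.expr_mu_sd, size=n_genes)
    t = np.empty((n_genes, n_stages))
    t[:, 0] = rng.normal(0.0, config.expr_stage_sd, size=n_genes)
    phi = config.expr_ar_phi
    for s in range(1, n_stages):
        t[:, s] = phi * t[:, s - 1] + math.sqrt(1 - phi**2) * rng.normal(
            0.0, config.expr_stage_sd, size=n_genes
        )

    last = n_stages - 1
    peak_by_rank = np.array([max(last - r, 0) for r in range(config.n_categories)])
    stage_idx = np.arange(n_stages)
    bump = np.zeros((n_genes, n_stages))
    reused = np.zeros(n_genes, dtype=bool)
    reuse_peak = np.full(n_genes, -1)
    for g in range(n_genes):
        pk = peak_by_rank[gene_ranks[g]]
        bump[g] = config.expr_bump_amp * np.exp(-((stage_idx - pk) ** 2) / (2 * 0.75**2))
        if gene_ranks[g] >= 2 and rng.random() < config.reuse_rate:
            reused[g] = True
            rp = int(rng.integers(mid + 1, n_stages))
            reuse_peak[g] = rp
            bump[g] += config.expr_reuse_amp * np.exp(
                -((stage_idx - rp) ** 2) / (2 * 0.75**2)
            )

    species = list(config.expression_species)
    delta = {sp: rng.normal(0.0, 1.0, size=n_genes) for sp in species}
    tables: dict[str, pd.DataFrame] = {}
    for sp in species:
        rows = []
        for s, stage in enumerate(config.expression_stages):
            for r in range(config.expression_replicates):
                noise = rng.normal(0.0, config.expr_noise_sd, size=n_genes)
                log_expr = mu + t[:, s] + bump[:, s] + d_profile[s] * delta[sp] + noise
                fpkm = np.exp(log_expr)
                rep = f"rep{r + 1}"
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": [f"{sp}_{g}" for g in gene_ids],
                            "stage": stage,
                            "replicate": rep,
                            "fpkm": fpkm,
                        }
                    )
                )
        tables[sp] = pd.concat(rows, ignore_index=True)

    orthology: dict[tuple[str, str], pd.DataFrame] = {}
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1:]:
            keep = rng.random(n_genes) >= config.ortho_missing_rate
            orthology[(sp_a, sp_b)] = pd.DataFrame(
                {
                    sp_a: [f"{sp_a}_{g}" for g, k in zip(gene_ids, keep) if k],
                    sp_b: [f"{sp_b}_{g}" for g, k in zip(gene_ids, keep) if k],
                }
            )

    # homolog presence matrix over all tree species (reference gene ids)
    presence = pd.DataFrame(False, index=[f"{config.reference}_{g}" for g in gene_ids],
                            columns=list(config.species))
    gene_lost: dict[str, list[str]] = {}
    for g in range(n_genes):
        clade = config.clade(int(gene_ranks[g]))
        losable = clade[:-1]
        lost = [sp for sp in losable if rng.random() < config.gene_loss_rate]
        gid = f"{config.reference}_{gene_ids[g]}"
        gene_lost[gid] = lost
        for sp in clade:
            if sp not in lost:
                presence.loc[gid, sp] = True
    presence.index.name = "gene_id"

    truth = {
        "mid_stage_index": mid,
        "gene_ranks": {f"{config.reference}_{g}": int(r)
                       for g, r in zip(gene_ids, gene_ranks)},
        "gene_lost": gene_lost,
        "reused": [f"{config.reference}_{g}" for g, f in zip(gene_ids, reused) if f],
        "expression_peak_by_rank": {int(r): int(p) for r, p in enumerate(peak_by_rank)},
    }
    return tables, orthology, presence, truth


# ----------------------------------------------------------------------
# top-level driver


@dataclass
class SimulatedData:
    config: SimulationConfig
    seed: int
    outdir: Path
    manifest: TruthManifest
    paths: dict[str, str]


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate(config: SimulationConfig, outdir: str | os.PathLike, seed: int) -> SimulatedData:
    """Generate and write every pipeline input plus the truth manifest.

    Deterministic: the same (config, seed) produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    rng_genome, rng_annot, rng_acr, rng_reads, rng_peaks, rng_expr = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    chrom_sizes, segments, coverage = simulate_genome_and_coverage(config, rng_genome)
    genes_df, exons_df = simulate_annotation(config, chrom_sizes, rng_annot)
    acrs = simulate_acrs(config, segments, genes_df, rng_acr)
    samples, signal_truth = simulate_reads(config, acrs, chrom_sizes, rng_reads)
    peak_sets = simulate_peak_sets(config, acrs, rng_peaks)
    expr_tables, orthology, presence, expr_truth = simulate_expression(config, rng_expr)

    paths: dict[str, str] = {}

    def emit(rel: str) -> Path:
        p = outdir / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        paths[rel] = str(p)
        return p

    with open(emit("tree.nwk"), "w") as fh:
        fh.write(config.newick() + "\n")
    write_chrom_sizes(chrom_sizes, emit("chrom.sizes"))

    cov_counts: dict[str, int] = {}
    for sp in config.species:
        rows = coverage[sp]
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in rows:
            by_chrom.setdefault(chrom, []).append((s, e))
        recs = []
        for chrom in sorted(by_chrom):
            ms, me = merge_intervals([x[0] for x in by_chrom[chrom]],
                                     [x[1] for x in by_chrom[chrom]])
            recs.extend((chrom, int(a), int(b)) for a, b in zip(ms, me))
        cov_counts[sp] = len(recs)
        write_bed(pd.DataFrame(recs, columns=["chrom", "start", "end"]),
                  emit(f"coverage/{sp}.bed"))

    genes_df.to_csv(emit("annotation/genes.tsv"), sep="\t", index=False)
    exons_df.to_csv(emit("annotation/exons.tsv"), sep="\t", index=False)

    for stage, sets in peak_sets.items():
        for label, df in sets.items():
            write_bed(df, emit(f"peaks/{stage}_{label}.bed"))

    for (stage, rep), df in samples.items():
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "name": ".",
                "score": 0,
                "strand": df["strand"],
            }
        )
        write_bed(bed, emit(f"reads/{stage}_{rep}.bed"))

    for sp, tab in expr_tables.items():
        tab.to_csv(emit(f"expression/{sp}.tsv"), sep="\t", index=False,
                   float_format="%.6f")
    for (sp_a, sp_b), tab in orthology.items():
        tab.to_csv(emit(f"orthology/{sp_a}__{sp_b}.tsv"), sep="\t", index=False)
    presence.astype(int).to_csv(emit("presence.tsv"), sep="\t")

    expected_methods = {a.acr_id: _expected_method_outcomes(config, a) for a in acrs}
    manifest = TruthManifest(
        seed=seed,
        config=dataclasses.asdict(config),
        tree_newick=config.newick(),
        chrom_sizes=chrom_sizes,
        segments=segments,
        coverage_interval_counts=cov_counts,
        acrs=acrs,
        expected_methods=expected_methods,
        expected_percent=signal_truth["expected_percent"],
        schedule={int(r): int(p) for r, p in enumerate(config.effective_schedule())},
        expression_truth=expr_truth,
    )
    manifest.checksums = {rel: _md5(Path(p)) for rel, p in sorted(paths.items())}
    with open(emit("manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return SimulatedData(config=config, seed=seed, outdir=outdir, manifest=manifest,
                         paths=paths)
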