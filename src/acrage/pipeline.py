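"""End-to-end orchestration: files in, aged segments and statistics out.

`run_pipeline` wires the stages in dependency order - coverage profile ->
age assignment -> signal quantification -> relative tables -> recapitulation
statistics - with the independent gene-age and phylotypic branches run on
demand.  All knobs live in :class:`RunConfig` (loadable from a plain
``key = value`` config file); every output directory gets a ``summary.json``
stamped with the config hash and seed, and rerunning with the same config
and seed reproduces the tables byte for byte.

This package is library-first: the functions here (plus the scripts under
``examples/``) are the command surface.
"""

from __future__ import annotations

import ast
import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acr_qc, coverage, evo_age, gene_age, phylo, phylotypic, recap
from .io import read_bed, read_chrom_sizes


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RunConfig:
    """All paths, thresholds and seeds of one pipeline run."""

    data_dir: str
    out_dir: str
    reference: str = "ref"
    stages: tuple[str, ...] = ()
    replicates: tuple[str, ...] = ()
    method: str = "I"
    min_segment_len: int = 1
    min_frac: float = 1.0 / 3.0
    consensus_min_frac: float = 0.5
    tn5_plus_shift: int = 4
    tn5_minus_shift: int = -5
    window_start_stage: int = 1  # stage index of the phylotypic period
    fdr_q: float = 0.05
    top_frac: float = 0.01
    n_resamples: int = 100
    fpkm_threshold: float = 1.0
    run_gene_age: bool = False
    run_phylotypic: bool = False
    expression_species: tuple[str, ...] = ()
    expression_stages: tuple[str, ...] = ()
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.method not in evo_age.METHODS:
            raise ConfigError(f"unknown method {self.method!r}")
        for name in ("min_frac", "consensus_min_frac", "top_frac", "fdr_q"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if not self.stages:
            raise ConfigError("stage order must be supplied explicitly")

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Parse a plain ``key = value`` config file (python literals allowed)."""
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, raw = (x.strip() for x in line.split("=", 1))
                try:
                    values[key] = ast.literal_eval(raw)
                except (SyntaxError, ValueError):
                    values[key] = raw
        values.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**values)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    tree: phylo.PhyloTree
    profile: coverage.SharingProfile
    acrs: pd.DataFrame
    membership: dict[str, set[str]]
    aged_segments: list[evo_age.AgedSegment]
    signal_table: RelativeSignal = None  # type: ignore[name-defined]
    relative_signal: recap.RelativeTable | None = None
    relative_length: recap.RelativeTable | None = None
    peaks: pd.DataFrame | None = None
    concordance: recap.RecapResult | None = None
    kw: pd.DataFrame | None = None
    gene_ages: pd.DataFrame | None = None
    relative_expression: recap.RelativeTable | None = None
    gene_concordance: recap.RecapResult | None = None
    ptop: phylotypic.PTopResult | None = None
    frip_by_sample: dict = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)


RelativeSignal = pd.DataFrame  # long (segment_index, stage, replicate, count)


def _consensus_by_stage(cfg: RunConfig, data: Path):
    """Per-stage consensus ACRs, consolidated into one disjoint ACR list."""
    per_stage: dict[str, pd.DataFrame] = {}
    for stage in cfg.stages:
        pooled = read_bed(data / f"peaks/{stage}_pooled.bed", min_cols=3)
        reps = []
        for rep in cfg.replicates:
            p = data / f"peaks/{stage}_{rep}.bed"
            if not p.exists():
                raise DataError(f"missing replicate peak file {p}")
            reps.append(read_bed(p, min_cols=3))
        per_stage[stage] = acr_qc.consensus_acrs(pooled, reps, cfg.consensus_min_frac)
    # consolidate across stages: merge overlapping retained peaks
    frames = [df for df in per_stage.values() if len(df)]
    if not frames:
        raise DataError("no consensus ACRs at any stage")
    union = pd.concat(frames, ignore_index=True)
    rows = []
    from .io import merge_intervals

    for chrom, grp in union.groupby("chrom", sort=True):
        s, e = merge_intervals(grp["start"], grp["end"])
        rows.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
    acrs = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    acrs["name"] = [f"ACR{i:05d}" for i in range(len(acrs))]
    # per-stage membership of consolidated ids
    membership: dict[str, set[str]] = {}
    for stage, df in per_stage.items():
        members = set()
        for row in df.itertuples(index=False):
            sub = acrs[
                (acrs["chrom"] == row.chrom)
                & (acrs["start"] < row.end)
                & (acrs["end"] > row.start)
            ]
            members.update(sub["name"])
        membership[stage] = members
    return acrs, membership


def _segment_counts(
    segments: list[evo_age.AgedSegment],
    samples: dict[tuple[str, str], pd.DataFrame],
) -> pd.DataFrame:
    """Recounted 5'-end reads within every aged segment per sample."""
    seg_df = pd.DataFrame(
        [(i, g.chrom, g.start, g.end) for i, g in enumerate(segments)],
        columns=["segment_index", "chrom", "start", "end"],
    )
    rows = []
    for (stage, rep), reads in samples.items():
        pos_by_chrom = {
            chrom: np.sort(grp["pos"].to_numpy())
            for chrom, grp in reads.groupby("chrom", sort=True)
        }
        for row in seg_df.itertuples(index=False):
            pos = pos_by_chrom.get(row.chrom)
            if pos is None:
                n = 0
            else:
                n = int(
                    np.searchsorted(pos, row.end, "left")
                    - np.searchsorted(pos, row.start, "left")
                )
            rows.append((row.segment_index, stage, rep, n))
    return pd.DataFrame(rows, columns=["segment_index", "stage", "replicate", "count"])


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis in dependency order; abort naming the stage."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save(df: pd.DataFrame, rel: str) -> None:
        p = out / rel
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        outputs[rel] = str(p)

    stage_name = "tree"
    try:
        tree = phylo.read_tree(str(data / "tree.nwk"), config.reference)
        chrom_sizes = read_chrom_sizes(data / "chrom.sizes")

        stage_name = "coverage"
        cov_paths = {
            sp: str(data / f"coverage/{sp}.bed") for sp in sorted(tree.nonreference_leaves)
        }
        missing = [p for p in cov_paths.values() if not os.path.exists(p)]
        if missing:
            raise DataError(f"missing coverage files: {missing}")
        coverages = coverage.read_coverage_beds(cov_paths)
        profile = coverage.build_sharing_profile(coverages, chrom_sizes)

        stage_name = "consensus"
        acrs, membership = _consensus_by_stage(config, data)

        stage_name = "ages"
        acr_tuples = [
            (r.chrom, int(r.start), int(r.end), r.name) for r in acrs.itertuples(index=False)
        ]
        aged = evo_age.run_method(
            acr_tuples, profile, tree, config.method,
            min_segment_len=config.min_segment_len, min_frac=config.min_frac,
        )
        if not aged:
            raise DataError("no aged segments produced; check coverage inputs")
        save(evo_age.segments_to_bed(aged), "aged_segments.tsv")

        stage_name = "signal"
        samples: dict[tuple[str, str], pd.DataFrame] = {}
        frip_by_sample = {}
        for stage in config.stages:
            for rep in config.replicates:
                p = data / f"reads/{stage}_{rep}.bed"
                if not p.exists():
                    raise DataError(f"missing read file {p}")
                raw = acr_qc.reads_from_bed6(read_bed(p, min_cols=6))
                corrected = acr_qc.tn5_correct(
                    raw, chrom_sizes,
                    plus_shift=config.tn5_plus_shift,
                    minus_shift=config.tn5_minus_shift,
                )
                samples[(stage, rep)] = corrected
                frip_by_sample[f"{stage}/{rep}"] = acr_qc.frip(corrected, acrs)
        seg_counts = _segment_counts(aged, samples)

        stage_name = "recap"
        rel_signal = recap.relative_signal_table(
            aged, None, config.stages, segment_counts=seg_counts
        )
        rel_signal.check_normalization()
        rel_length = recap.relative_length_table(aged, membership, config.stages)
        peaks = recap.peak_stage(rel_signal)
        conc = recap.recap_concordance(
            rel_signal, window_start_stage=config.window_start_stage, seed=config.seed
        )
        kw = recap.kw_test(rel_signal, fdr_q=config.fdr_q)
        save(rel_signal.data, "relative_signal.tsv")
        save(rel_length.data, "relative_length.tsv")
        stats = peaks.merge(kw, on=["category", "rank"])
        save(stats, "recap_stats.tsv")
        if config.make_plots:
            recap.plot_trajectories(rel_signal, str(out / "trajectories.png"), peaks)
            outputs["trajectories.png"] = str(out / "trajectories.png")

        result = PipelineResult(
            config=config, tree=tree, profile=profile, acrs=acrs,
            membership=membership, aged_segments=aged, signal_table=seg_counts,
            relative_signal=rel_signal, relative_length=rel_length, peaks=peaks,
            concordance=conc, kw=kw, frip_by_sample=frip_by_sample, outputs=outputs,
        )

        if config.run_gene_age:
            stage_name = "gene_age"
            presence = pd.read_csv(data / "presence.tsv", sep="\t", index_col=0)
            ages = gene_age.gene_ages(presence, tree, exclude_secondary_loss=True)
            expr = pd.read_csv(
                data / f"expression/{config.reference}.tsv", sep="\t",
                dtype={"stage": str, "replicate": str},
            )
            expr_stages = tuple(config.expression_stages) or tuple(
                sorted(expr["stage"].unique())
            )
            rel_expr = gene_age.relative_expression_table(expr, ages, expr_stages)
            gene_conc = recap.recap_concordance(rel_expr, window_start_stage=0,
                                                seed=config.seed)
            result.gene_ages = ages
            result.relative_expression = rel_expr
            result.gene_concordance = gene_conc
            save(ages, "gene_ages.tsv")
            save(rel_expr.data, "relative_expression.tsv")

        if config.run_phylotypic:
            stage_name = "phylotypic"
            species = tuple(config.expression_species) or (config.reference,)
            expr_stages = tuple(config.expression_stages)
            matrices = {
                sp: phylotypic.ExpressionMatrix.from_tsv(
                    sp, str(data / f"expression/{sp}.tsv"), expr_stages
                )
                for sp in species
            }
            pair_tables = {}
            for i, a in enumerate(species):
                for b in species[i + 1:]:
                    for cand in (data / f"orthology/{a}__{b}.tsv",
                                 data / f"orthology/{b}__{a}.tsv"):
                        if cand.exists():
                            pair_tables[(a, b)] = pd.read_csv(cand, sep="\t")
                            break
            orth = phylotypic.OrthologyMap(pair_tables)
            pair_selection = [
                (a, b) for i, a in enumerate(species) for b in species[i + 1:]
            ]
            result.ptop = phylotypic.p_top(
                matrices, orth, pair_selection, top_frac=config.top_frac,
                n_resamples=config.n_resamples, seed=config.seed,
            )
            save(result.ptop.summary, "p_top.tsv")

        summary = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "method": config.method,
            "n_acrs": int(len(acrs)),
            "n_aged_segments": int(len(aged)),
            "tau": conc.tau,
            "tau_p": conc.p_value,
            "frip": frip_by_sample,
            "outputs": sorted(outputs),
            "parameters": {
                "tn5_shift": [config.tn5_plus_shift, config.tn5_minus_shift],
                "consensus_min_frac": config.consensus_min_frac,
                "consensus_denominator": "pooled_peak_length",
                "min_frac": config.min_frac,
                "whole_acr_tie_break": "oldest",
                "peak_stage_tie_break": "later",
            },
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        outputs["summary.json"] = str(out / "summary.json")
        return result
    except (ConfigError, DataError):
        raise
    except Exception as exc:
        raise DataError(f"pipeline failed at stage '{stage_name}': {exc}") from exc
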