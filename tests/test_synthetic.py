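"""Generator determinism, file validity, loss statistics, noiseless identity."""

import hashlib
import json

import numpy as np
import pandas as pd
import pytest

from acrage import SimulationConfig, parse_tree, simulate
from acrage.io import read_bed, read_chrom_sizes
from acrage.phylotypic import ExpressionMatrix

SMALL = dict(
    n_acrs=70, chrom_length=150_000, reads_per_replicate=5_000, n_genes=80,
    stages=("st1", "st2", "st3", "st4", "st5", "st6"),
)


def test_config_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(category_proportions=(0.5, 0.6))
    with pytest.raises(ValueError, match="one proportion per category"):
        SimulationConfig(category_proportions=(0.5, 0.5))
    with pytest.raises(ValueError, match="rates"):
        SimulationConfig(loss_rate=1.5)
    with pytest.raises(ValueError, match="peak stages"):
        SimulationConfig(peak_schedule=(9,) * 7)


def test_config_from_file(tmp_path):
    p = tmp_path / "sim.cfg"
    p.write_text("n_acrs = 50\nloss_rate = 0.0  # no secondary losses\n")
    cfg = SimulationConfig.from_file(p)
    assert cfg.n_acrs == 50 and cfg.loss_rate == 0.0
    p.write_text("bogus = 1\n")
    with pytest.raises(ValueError, match="bogus"):
        SimulationConfig.from_file(p)


def test_same_seed_byte_identical(tmp_path):
    cfg = SimulationConfig(**SMALL)
    a = simulate(cfg, tmp_path / "a", seed=11)
    b = simulate(cfg, tmp_path / "b", seed=11)
    assert a.manifest.checksums == b.manifest.checksums
    c = simulate(cfg, tmp_path / "c", seed=12)
    assert a.manifest.checksums != c.manifest.checksums


def test_emitted_files_parse_and_checksums_match(sim_default):
    sim = sim_default
    # tree parses with the configured reference and category count
    tree = parse_tree(sim.manifest.tree_newick, sim.config.reference)
    assert len(tree.categories) == sim.config.n_categories
    sizes = read_chrom_sizes(sim.paths["chrom.sizes"])
    assert sizes == sim.manifest.chrom_sizes
    # every file's checksum matches a fresh digest
    for rel, digest in sim.manifest.checksums.items():
        h = hashlib.md5(open(sim.paths[rel], "rb").read()).hexdigest()
        assert h == digest, rel
    # a read file parses as BED6 with single-base records
    stage, rep = sim.config.stages[0], "rep1"
    bed = read_bed(sim.paths[f"reads/{stage}_{rep}.bed"], min_cols=6)
    assert ((bed["end"] - bed["start"]) == 1).all()
    assert set(bed["strand"]) <= {"+", "-"}
    # expression tables load into ExpressionMatrix
    for sp in sim.config.expression_species:
        ExpressionMatrix.from_tsv(sp, sim.paths[f"expression/{sp}.tsv"],
                                  sim.config.expression_stages)
    # manifest JSON round-trips
    manifest = json.loads(open(sim.paths["manifest.json"]).read())
    assert manifest["seed"] == sim.seed


def test_segments_tile_genome_and_alternate_categories(sim_default):
    segs = sim_default.manifest.segments
    by_chrom = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, ss in by_chrom.items():
        assert ss[0].start == 0
        assert ss[-1].end == sim_default.manifest.chrom_sizes[chrom]
        for a, b in zip(ss, ss[1:]):
            assert a.end == b.start
            assert a.rank != b.rank


def test_loss_fraction_matches_bernoulli_expectation(sim_loss02):
    """Share of loss-affected segments tracks 1-(1-r)^k per category."""
    r = sim_loss02.config.loss_rate
    segs = sim_loss02.manifest.segments
    for rank in range(2, sim_loss02.config.n_categories):
        sub = [s for s in segs if s.rank == rank]
        if len(sub) < 30:
            continue
        k = rank - 1  # losable species (most distant one protected)
        expected = 1.0 - (1.0 - r) ** k
        observed = np.mean([bool(s.lost) for s in sub])
        se = (expected * (1 - expected) / len(sub)) ** 0.5
        assert abs(observed - expected) < 3.3 * se + 0.02, (rank, observed, expected)


def test_lost_species_never_include_clade_outermost(sim_loss02):
    for s in sim_loss02.manifest.segments:
        clade = sim_loss02.config.clade(s.rank)
        if clade:
            assert clade[-1] not in s.lost


def test_noiseless_counts_reproduce_analytic_percentages(tmp_path):
    """noise_sd = 0: recounted reads give exactly the manifest percentages."""
    from acrage import build_sharing_profile, read_coverage_beds, run_method
    from acrage.acr_qc import reads_from_bed6, tn5_correct
    from acrage.pipeline import _segment_counts
    from acrage.recap import relative_signal_table

    cfg = SimulationConfig(noise_sd=0.0, background_frac=0.0, loss_rate=0.0, **SMALL)
    sim = simulate(cfg, tmp_path / "sim", seed=9)
    tree = parse_tree(sim.manifest.tree_newick, cfg.reference)
    covs = read_coverage_beds({sp: sim.paths[f"coverage/{sp}.bed"] for sp in cfg.species})
    profile = build_sharing_profile(covs, sim.manifest.chrom_sizes)
    acrs = [(a.chrom, a.start, a.end, a.acr_id) for a in sim.manifest.acrs]
    aged = run_method(acrs, profile, tree, "I")
    samples = {}
    for stage in cfg.stages:
        for rep in (f"rep{i+1}" for i in range(cfg.n_replicates)):
            raw = reads_from_bed6(read_bed(sim.paths[f"reads/{stage}_{rep}.bed"], min_cols=6))
            samples[(stage, rep)] = tn5_correct(raw, sim.manifest.chrom_sizes)
    seg_counts = _segment_counts(aged, samples)
    tab = relative_signal_table(aged, None, cfg.stages, segment_counts=seg_counts)
    tab.check_normalization()
    # every replicate at a stage carries identical, deterministic counts;
    # compare against the manifest's analytic expectation
    expected = sim.manifest.expected_percent
    got = tab.data.groupby(["stage", "rank"])["percent"].mean()
    for stage, per_rank in expected.items():
        total_round = sum(per_rank.values())
        for rank, pct in per_rank.items():
            # analytic percentages are pre-rounding; integer read counts shift
            # each cell by well under 0.1 percentage points at these depths
            assert got[(stage, int(rank))] == pytest.approx(pct, abs=0.1)


def test_nonmonotone_schedule_breaks_perfect_concordance(tmp_path):
    """Planting the oldest category to peak last yields tau < 1 analytically."""
    from acrage.recap import RelativeTable, recap_concordance

    cfg = SimulationConfig(peak_schedule=(5, 4, 3, 2, 1, 0, 5), **SMALL)
    sim = simulate(cfg, tmp_path / "sim", seed=13)
    rows = []
    for stage, per_rank in sim.manifest.expected_percent.items():
        for rank, pct in per_rank.items():
            rows.append((stage, f"c{rank}", int(rank), "exp", pct))
    tab = RelativeTable(
        pd.DataFrame(rows, columns=["stage", "category", "rank", "replicate", "percent"]),
        "signal", tuple(cfg.stages),
    )
    res = recap_concordance(tab, window_start_stage=0)
    assert res.tau < 1.0


def test_monotone_schedule_has_perfect_analytic_concordance(sim_default):
    from acrage.recap import RelativeTable, recap_concordance

    rows = []
    for stage, per_rank in sim_default.manifest.expected_percent.items():
        for rank, pct in per_rank.items():
            rows.append((stage, f"c{rank}", int(rank), "exp", pct))
    tab = RelativeTable(
        pd.DataFrame(rows, columns=["stage", "category", "rank", "replicate", "percent"]),
        "signal", tuple(sim_default.config.stages),
    )
    res = recap_concordance(tab, window_start_stage=1)
    assert res.tau == pytest.approx(1.0)
    peaks = res.peaks.set_index("rank")["peak_stage"].to_dict()
    assert peaks == {int(r): p for r, p in sim_default.manifest.schedule.items()}
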