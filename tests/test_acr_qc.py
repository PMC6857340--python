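"""Read-level conventions, consensus filtering, signal, FRiP and context."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from acrage import (
    GeneAnnotation,
    classify_genomic_context,
    consensus_acrs,
    downsample_reads,
    frip,
    promoter_enrichment,
    quantify_signal,
    replicate_correlation,
    tn5_correct,
)
from acrage.acr_qc import build_signal_table, place_random_controls, reads_from_bed6


def reads(*entries):
    return pd.DataFrame(entries, columns=["chrom", "pos", "strand"])


def bed(*rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestTn5Correction:
    def test_standard_shift(self):
        out = tn5_correct(reads(("chr1", 100, "+"), ("chr1", 200, "-")))
        assert out["pos"].tolist() == [104, 195]

    def test_zero_shift_is_identity(self):
        out = tn5_correct(reads(("chr1", 100, "+")), plus_shift=0, minus_shift=0)
        assert out["pos"].tolist() == [100]

    def test_out_of_bounds_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = tn5_correct(reads(("chr1", 2, "-")), chrom_sizes={"chr1": 1000})
        assert out["pos"].tolist() == [0]

    def test_bed6_five_prime_extraction(self):
        df = bed(
            ("chr1", 10, 11, ".", 0, "+"),
            ("chr1", 20, 21, ".", 0, "-"),
            cols=("chrom", "start", "end", "name", "score", "strand"),
        )
        assert reads_from_bed6(df)["pos"].tolist() == [10, 20]


class TestDownsample:
    def test_identity_and_determinism(self):
        r = reads(*((f"chr1", i, "+") for i in range(50)))
        assert downsample_reads(r, 50, seed=1)["pos"].tolist() == r["pos"].tolist()
        a = downsample_reads(r, 10, seed=3)
        b = downsample_reads(r, 10, seed=3)
        assert a["pos"].tolist() == b["pos"].tolist()
        assert len(a) == 10

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="downsample"):
            downsample_reads(reads(("chr1", 1, "+")), 2, seed=0)


class TestConsensus:
    def _replicate(self, frac):
        # replicate peak overlapping [100, 200) by the given fraction
        return bed(("chr1", 100, 100 + int(100 * frac)))

    def test_fifty_percent_rule(self):
        pooled = bed(("chr1", 100, 200))
        kept = consensus_acrs(pooled, [self._replicate(f) for f in (0.6, 0.8, 1.0)])
        assert len(kept) == 1
        dropped = consensus_acrs(pooled, [self._replicate(f) for f in (0.6, 0.4, 1.0)])
        assert len(dropped) == 0

    def test_overlap_summed_across_replicate_peaks(self):
        pooled = bed(("chr1", 100, 200))
        rep = bed(("chr1", 100, 130), ("chr1", 150, 180))  # 30 + 30 = 60%
        assert len(consensus_acrs(pooled, [rep])) == 1

    def test_no_replicate_peaks_drops_everything(self):
        pooled = bed(("chr1", 100, 200), ("chr1", 300, 400))
        assert len(consensus_acrs(pooled, [bed()])) == 0

    def test_monotone_in_min_frac(self):
        rng = np.random.default_rng(0)
        pooled = bed(*[("chr1", int(s), int(s) + 100) for s in range(0, 5000, 200)])
        rep1 = bed(*[("chr1", int(s) + int(rng.integers(0, 80)), int(s) + 120)
                     for s in range(0, 5000, 200)])
        prev = None
        for f in (0.2, 0.4, 0.6, 0.8):
            n = len(consensus_acrs(pooled, [rep1], min_frac=f))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_requires_a_replicate(self):
        with pytest.raises(ValueError, match="replicate"):
            consensus_acrs(bed(("chr1", 0, 10)), [])


class TestSignal:
    def test_counts_rpm_and_boundaries(self):
        acrs = bed(("chr1", 100, 200))
        r = reads(*[("chr1", p, "+") for p in [100, 150, 199, 200, 99, 500, 600, 700, 800, 900]])
        tab = quantify_signal(r, acrs)
        assert tab["count"].tolist() == [3]  # start inclusive, end exclusive
        assert tab["rpm"].iloc[0] == pytest.approx(3e5)

    def test_no_reads_all_zero(self):
        tab = quantify_signal(reads(), bed(("chr1", 0, 100)), total_reads=10)
        assert tab["count"].tolist() == [0]
        # zero counts are logged with the pseudocount read
        assert tab["log10_rpm"].iloc[0] == pytest.approx(np.log10(1e6 / 10))

    def test_overlapping_acrs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            quantify_signal(reads(), bed(("chr1", 0, 100), ("chr1", 50, 150)))

    def test_read_conservation_when_acrs_tile_genome(self):
        rng = np.random.default_rng(1)
        r = reads(*[("chr1", int(p), "+") for p in rng.integers(0, 1000, 500)])
        acrs = bed(*[("chr1", i, i + 100) for i in range(0, 1000, 100)])
        assert quantify_signal(r, acrs)["count"].sum() == 500


class TestFrip:
    def test_extremes_and_fraction(self):
        acrs = bed(("chr1", 0, 100))
        inside = reads(*[("chr1", i, "+") for i in range(30)])
        outside = reads(*[("chr1", 500 + i, "+") for i in range(70)])
        assert frip(inside, acrs) == 1.0
        assert frip(outside, acrs) == 0.0
        combined = pd.concat([inside, outside], ignore_index=True)
        score = frip(combined, acrs)
        assert score == pytest.approx(0.3)
        assert score > 0.2  # clears the ATAC-seq acceptability bound

    def test_zero_reads_error(self):
        with pytest.raises(ValueError, match="zero reads"):
            frip(reads(), bed(("chr1", 0, 10)))


class TestReplicateCorrelation:
    def _table(self, values_by_rep):
        rows = []
        for rep, vals in values_by_rep.items():
            for i, v in enumerate(vals):
                rows.append((f"acr{i}", "st1", rep, v, v, np.log10(max(v, 1) * 1e5)))
        return pd.DataFrame(
            rows, columns=["acr_id", "stage", "replicate", "count", "rpm", "log10_rpm"]
        )

    def test_duplicated_replicate_r_one(self):
        tab = self._table({"r1": [1, 5, 9], "r2": [1, 5, 9]})
        assert replicate_correlation(tab).loc["r1", "r2"] == pytest.approx(1.0)

    def test_uniform_scaling_invariance_on_log_scale(self):
        rows = []
        for rep, scale in (("r1", 1.0), ("r2", 10.0)):
            for i, v in enumerate([2.0, 8.0, 32.0]):
                rows.append((f"acr{i}", "st1", rep, v, v * scale, np.log10(v * scale)))
        tab = pd.DataFrame(rows, columns=["acr_id", "stage", "replicate", "count", "rpm", "log10_rpm"])
        assert replicate_correlation(tab).loc["r1", "r2"] == pytest.approx(1.0)

    def test_three_point_pearson_closed_form(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([2.0, 1.0, 5.0])
        rows = [(f"a{i}", "s", "r1", 0, 0.0, xv) for i, xv in enumerate(x)]
        rows += [(f"a{i}", "s", "r2", 0, 0.0, yv) for i, yv in enumerate(y)]
        tab = pd.DataFrame(rows, columns=["acr_id", "stage", "replicate", "count", "rpm", "log10_rpm"])
        expected = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        got = replicate_correlation(tab).loc["r1", "r2"]
        assert abs(got - expected) < 1e-12

    def test_zero_variance_flagged(self):
        tab = self._table({"r1": [3, 3, 3], "r2": [1, 5, 9]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = replicate_correlation(tab)
        assert np.isnan(corr.loc["r1", "r2"])
        assert corr.loc["r1", "r1"] == 1.0


@pytest.fixture
def annotation():
    genes = pd.DataFrame(
        {
            "gene_id": ["gP", "gM"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "start": [10_000, 50_000],
            "end": [20_000, 60_000],
        }
    )
    exons = pd.DataFrame(
        {
            "gene_id": ["gP", "gP", "gM"],
            "chrom": ["chr1"] * 3,
            "start": [10_000, 15_000, 59_000],
            "end": [10_500, 15_500, 60_000],
        }
    )
    return GeneAnnotation.from_tables(genes, exons)


class TestGenomicContext:
    def test_precedence_and_strand_awareness(self, annotation):
        acrs = bed(
            ("chr1", 9_900, 10_050),   # overlaps TSS window AND first exon -> promoter
            ("chr1", 12_000, 12_100),  # inside body, no exon -> intron
            ("chr1", 15_100, 15_300),  # inside exon -> exon
            ("chr1", 14_200, 14_400),  # 5kb-upstream window? inside body -> intron
            ("chr1", 6_000, 6_100),    # 4-5kb upstream of plus-strand TSS -> proximal
            ("chr1", 100_000, 100_200),  # far from everything -> distal
            ("chr1", 62_000, 62_100),  # 2-3kb upstream of minus-strand gene -> proximal
            ("chr1", 60_500, 60_600),  # within 2kb upstream of minus-strand TSS -> promoter
        )
        labels = classify_genomic_context(acrs, annotation)
        assert labels.tolist() == [
            "promoter", "intron", "exon", "intron",
            "proximal", "distal", "proximal", "promoter",
        ]

    def test_labels_partition(self, annotation):
        rng = np.random.default_rng(2)
        starts = rng.integers(0, 190_000, size=100)
        acrs = bed(*[("chr1", int(s), int(s) + 150) for s in starts])
        labels = classify_genomic_context(acrs, annotation)
        assert len(labels) == 100
        assert set(labels) <= {"promoter", "exon", "intron", "proximal", "distal"}

    def test_strandless_gene_rejected(self):
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chr1"], "strand": ["."],
             "start": [0], "end": [100]}
        )
        with pytest.raises(ValueError, match="strand"):
            GeneAnnotation.from_tables(genes, pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))


class TestPromoterEnrichment:
    def test_forced_identical_controls_give_odds_one(self, annotation):
        # two promoter-overlapping ACRs, three distal ones; controls forced
        # identical to the observed set give an odds ratio of exactly 1
        acrs = bed(
            ("chr1", 9_000, 9_200), ("chr1", 9_500, 9_700),
            ("chr1", 150_000, 150_200), ("chr1", 151_000, 151_200),
            ("chr1", 152_000, 152_200),
        )
        res = promoter_enrichment(acrs, annotation, {"chr1": 200_000}, seed=0,
                                  controls=acrs)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric(self, annotation):
        n = 5
        in_prom = bed(*[("chr1", 9_000 + 50 * i, 9_040 + 50 * i) for i in range(n)])
        far = bed(*[("chr1", 150_000 + 500 * i, 150_040 + 500 * i) for i in range(n)])
        res = promoter_enrichment(in_prom, annotation, {"chr1": 200_000}, seed=0,
                                  controls=far)
        assert res.table.tolist() == [[n, 0], [0, n]]
        assert res.p_value == pytest.approx(2.0 / comb(2 * n, n, exact=True))

    def test_controls_are_length_matched_and_disjoint(self, annotation):
        rng = np.random.default_rng(3)
        acrs = bed(*[("chr1", int(s), int(s) + int(l)) for s, l in
                     zip(rng.integers(0, 190_000, 40), rng.integers(100, 500, 40))])
        ctl = place_random_controls(acrs, {"chr1": 200_000}, seed=4)
        assert sorted(ctl["end"] - ctl["start"]) == sorted(acrs["end"] - acrs["start"])
        ctl_sorted = ctl.sort_values("start")
        assert (ctl_sorted["start"].to_numpy()[1:] >= ctl_sorted["end"].to_numpy()[:-1]).all()

    def test_planted_promoter_preference_detected(self):
        """ACRs placed into promoters 35% of the time: Fisher detects it."""
        from acrage.synthetic import SimulationConfig, simulate_annotation

        rng = np.random.default_rng(10)
        sizes = {"chr1": 500_000, "chr2": 500_000}
        genes, exons = simulate_annotation(SimulationConfig(), sizes, rng)
        ann = GeneAnnotation.from_tables(genes, exons)
        prom = []
        for g in genes.itertuples(index=False):
            tsspos = g.start if g.strand == "+" else g.end - 1
            prom.append((g.chrom, max(tsspos - 2000, 0), tsspos + 1001))
        hits = 0
        for trial in range(100):
            trng = np.random.default_rng(1000 + trial)
            rows = []
            for i in range(120):
                if trng.random() < 0.35:
                    c, a, b = prom[int(trng.integers(len(prom)))]
                    s = int(trng.integers(a, b - 150))
                else:
                    c = "chr1" if trng.random() < 0.5 else "chr2"
                    s = int(trng.integers(0, sizes[c] - 150))
                rows.append((c, s, s + 150))
            acrs = bed(*rows)
            res = promoter_enrichment(acrs, ann, sizes, seed=trial)
            hits += res.p_value < 0.05
        assert hits >= 95


def test_build_signal_table_long_format():
    acrs = bed(("chr1", 0, 100), ("chr1", 200, 300))
    samples = {
        ("st1", "r1"): reads(("chr1", 10, "+"), ("chr1", 250, "+")),
        ("st1", "r2"): reads(("chr1", 20, "+")),
    }
    tab = build_signal_table(samples, acrs)
    assert len(tab) == 4
    assert tab.groupby("replicate")["count"].sum().tolist() == [2, 1]
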