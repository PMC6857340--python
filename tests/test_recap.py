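"""Relative tables, peak stages, concordance and Kruskal-Wallis statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from acrage import (
    AgedSegment,
    kw_test,
    parse_tree,
    peak_stage,
    recap_concordance,
    relative_length_table,
    relative_signal_table,
    restrict_to_conserved,
)
from acrage.recap import RelativeTable

from conftest import TREE3


@pytest.fixture(scope="module")
def cats():
    tree = parse_tree(TREE3, "R")
    return {c.rank: c for c in tree.categories}


def seg(cats, rank, start, end, acr_id, chrom="chr"):
    return AgedSegment(chrom, start, end, acr_id, cats[rank], "strict", "I")


def signal(rows):
    return pd.DataFrame(rows, columns=["acr_id", "stage", "replicate", "count"])


class TestRelativeSignal:
    def test_single_category_is_100_everywhere(self, cats):
        segs = [seg(cats, 0, 0, 100, "a")]
        tab = relative_signal_table(
            segs, signal([("a", "s1", "r1", 5), ("a", "s2", "r1", 9)]), ["s1", "s2"]
        )
        assert (tab.data["percent"] == 100.0).all()
        tab.check_normalization()

    def test_two_categories_30_70(self, cats):
        segs = [seg(cats, 0, 0, 100, "a"), seg(cats, 1, 200, 300, "b")]
        tab = relative_signal_table(
            segs,
            signal([("a", "s1", "r1", 30), ("b", "s1", "r1", 70)]),
            ["s1"],
        )
        by_rank = tab.data.set_index("rank")["percent"]
        assert by_rank[0] == pytest.approx(30.0)
        assert by_rank[1] == pytest.approx(70.0)

    def test_length_apportioning_of_parent_signal(self, cats):
        # one ACR subdivided 25/75: parent signal splits by length
        segs = [seg(cats, 0, 0, 25, "a"), seg(cats, 1, 25, 100, "a")]
        tab = relative_signal_table(segs, signal([("a", "s1", "r1", 40)]), ["s1"])
        by_rank = tab.data.set_index("rank")["percent"]
        assert by_rank[0] == pytest.approx(25.0)
        assert by_rank[1] == pytest.approx(75.0)

    def test_zero_total_stage_errors(self, cats):
        segs = [seg(cats, 0, 0, 100, "a")]
        with pytest.raises(ValueError, match="zero total"):
            relative_signal_table(segs, signal([("a", "s1", "r1", 0)]), ["s1"])

    def test_scaling_invariance_per_stage(self, cats):
        segs = [seg(cats, 0, 0, 100, "a"), seg(cats, 1, 200, 300, "b")]
        t1 = relative_signal_table(
            segs, signal([("a", "s1", "r1", 3), ("b", "s1", "r1", 7)]), ["s1"]
        )
        t2 = relative_signal_table(
            segs, signal([("a", "s1", "r1", 300), ("b", "s1", "r1", 700)]), ["s1"]
        )
        pd.testing.assert_frame_equal(t1.data, t2.data)


class TestRelativeLength:
    def test_25_75_and_signal_length_agreement(self, cats):
        segs = [seg(cats, 0, 0, 100, "a"), seg(cats, 1, 200, 500, "b")]
        tab = relative_length_table(segs, {"s1": {"a", "b"}}, ["s1"])
        by_rank = tab.data.set_index("rank")["percent"]
        assert by_rank[0] == pytest.approx(25.0)
        assert by_rank[1] == pytest.approx(75.0)
        # signal proportional to length gives the same table values
        sig = relative_signal_table(
            segs, signal([("a", "s1", "r1", 100), ("b", "s1", "r1", 300)]), ["s1"]
        )
        assert sig.data["percent"].tolist() == tab.data["percent"].tolist()

    def test_equal_lengths_split_evenly(self, cats):
        segs = [seg(cats, 0, 0, 100, "a"), seg(cats, 2, 200, 300, "b")]
        tab = relative_length_table(segs, {"s1": {"a", "b"}}, ["s1"])
        assert (tab.data["percent"] == 50.0).all()


class TestConservedRestriction:
    def test_identity_empty_and_clipping(self, cats):
        segs = [seg(cats, 0, 100, 200, "a"), seg(cats, 1, 300, 400, "b")]
        everything = pd.DataFrame([("chr", 0, 1000)], columns=["chrom", "start", "end"])
        out = restrict_to_conserved(segs, everything)
        assert [(g.start, g.end) for g in out] == [(100, 200), (300, 400)]
        nothing = pd.DataFrame([("chr", 500, 600)], columns=["chrom", "start", "end"])
        assert restrict_to_conserved(segs, nothing) == []
        half = pd.DataFrame([("chr", 150, 350)], columns=["chrom", "start", "end"])
        clipped = restrict_to_conserved(segs, half)
        assert [(g.start, g.end, g.category.rank) for g in clipped] == [
            (150, 200, 0), (300, 350, 1)
        ]


def _table_from_trajectories(traj_by_rank, n_reps=1, noise=0.0, rng=None):
    """Build a valid RelativeTable whose category means follow given curves."""
    ranks = sorted(traj_by_rank)
    n_stages = len(next(iter(traj_by_rank.values())))
    stages = [f"s{i}" for i in range(n_stages)]
    rows = []
    for si, st in enumerate(stages):
        for r in range(n_reps):
            vals = np.array([traj_by_rank[k][si] for k in ranks], dtype=float)
            if noise and rng is not None:
                vals = np.maximum(vals + rng.normal(0, noise, len(vals)), 1e-6)
            vals = 100.0 * vals / vals.sum()
            for k, v in zip(ranks, vals):
                rows.append((st, f"c{k}", k, f"r{r}", v))
    return RelativeTable(
        pd.DataFrame(rows, columns=["stage", "category", "rank", "replicate", "percent"]),
        "signal", tuple(stages),
    )


class TestPeakStage:
    def test_monotone_flat_and_tied(self):
        # two complementary categories keep the normalized trajectories shaped
        # as written: increasing -> last stage
        inc = _table_from_trajectories({0: [1, 2, 3], 1: [3, 2, 1]})
        assert peak_stage(inc).set_index("rank")["peak_stage"][0] == 2
        # flat trajectory: every stage ties, resolved toward the later stage
        flat = _table_from_trajectories({0: [1, 1, 1], 1: [1, 1, 1]})
        assert peak_stage(flat).set_index("rank")["peak_stage"][0] == 2
        # bimodal tie at stages 0 and 2 resolves to stage 2
        tied = _table_from_trajectories({0: [5, 1, 5], 1: [5, 9, 5]})
        assert peak_stage(tied).set_index("rank")["peak_stage"][0] == 2

    def test_planted_peak_recovered_under_noise(self):
        """A mid-trajectory bump at stage 3 of 6 survives noise at 10% of effect."""
        x = np.arange(6)
        bump = 1.0 + np.exp(-((x - 2) ** 2) / (2 * 0.75**2))  # peak at index 2
        flat = np.ones(6) * 2.0
        hits = 0
        for trial in range(200):
            rng = np.random.default_rng(trial)
            tab = _table_from_trajectories({0: bump, 1: flat}, n_reps=3, noise=0.1, rng=rng)
            hits += int(peak_stage(tab).set_index("rank")["peak_stage"][0] == 2)
        assert hits >= 198


class TestConcordance:
    def test_perfect_and_reversed_order(self):
        # younger (higher rank 0 = youngest) peaking strictly later
        tab = _table_from_trajectories(
            {
                0: [1, 1, 1, 10],
                1: [1, 1, 10, 1],
                2: [1, 10, 1, 1],
                3: [10, 1, 1, 1],
            }
        )
        res = recap_concordance(tab, window_start_stage=0)
        assert res.tau == pytest.approx(1.0)
        assert res.method == "exact"
        rev = _table_from_trajectories(
            {
                0: [10, 1, 1, 1],
                1: [1, 10, 1, 1],
                2: [1, 1, 10, 1],
                3: [1, 1, 1, 10],
            }
        )
        assert recap_concordance(rev, window_start_stage=0).tau == pytest.approx(-1.0)

    def test_window_excludes_pre_window_peaks(self):
        # category 3 peaks pre-window; in-window order of the rest is perfect
        tab = _table_from_trajectories(
            {
                0: [1, 1, 1, 1, 10],
                1: [1, 1, 1, 10, 1],
                2: [1, 1, 10, 1, 1],
                3: [10, 1, 1, 1, 1.5],
            }
        )
        res = recap_concordance(tab, window_start_stage=2)
        assert res.n_categories == 3
        assert res.tau == pytest.approx(1.0)
        excluded = res.peaks[~res.peaks["in_window"]]
        assert excluded["rank"].tolist() == [3]

    def test_needs_three_categories(self):
        tab = _table_from_trajectories({0: [1, 5], 1: [5, 1]})
        with pytest.raises(ValueError, match="three categories"):
            recap_concordance(tab, window_start_stage=0)

    def test_exact_p_small_for_perfect_order_of_seven(self):
        traj = {k: np.eye(7)[6 - k] * 9 + 1 for k in range(7)}
        res = recap_concordance(_table_from_trajectories(traj), window_start_stage=0)
        # 2/7! permutations reach |tau| = 1
        assert res.p_value == pytest.approx(2 / 5040)


class TestKruskalWallis:
    def test_hand_computed_two_stage_table(self):
        # category 0 percents: stage s0 -> (1,2,3), stage s1 -> (4,5,6)
        rows = []
        for st, vals in (("s0", [1, 2, 3]), ("s1", [4, 5, 6])):
            for r, v in enumerate(vals):
                rows.append((st, "c0", 0, f"r{r}", float(v)))
                rows.append((st, "c1", 1, f"r{r}", 100.0 - v))
        tab = RelativeTable(
            pd.DataFrame(rows, columns=["stage", "category", "rank", "replicate", "percent"]),
            "signal", ("s0", "s1"),
        )
        out = kw_test(tab).set_index("rank")
        # textbook H = 12/(N(N+1)) * sum(R_j^2/n_j) - 3(N+1) with no ties
        assert out.loc[0, "H"] == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21)
        assert out.loc[0, "p"] == pytest.approx(sps.chi2.sf(out.loc[0, "H"], 1))
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_degenerate_identical_values(self):
        tab = _table_from_trajectories({0: [1, 1, 1], 1: [1, 1, 1]}, n_reps=3)
        out = kw_test(tab)
        assert (out["H"] == 0.0).all()
        assert (out["p"] == 1.0).all()

    def test_null_fdr_control_small_batch(self):
        """All-null categories: BH at q=0.05 rarely rejects anything."""
        false_disc = 0
        n_sims = 200
        for i in range(n_sims):
            rng = np.random.default_rng(i)
            traj = {k: np.ones(8) for k in range(5)}
            tab = _table_from_trajectories(traj, n_reps=3, noise=0.3, rng=rng)
            false_disc += kw_test(tab)["significant"].any()
        assert false_disc / n_sims <= 0.08


def test_plot_trajectories_writes_file(tmp_path):
    tab = _table_from_trajectories({0: [1, 2, 3], 1: [3, 2, 1]}, n_reps=2)
    out = tmp_path / "traj.png"
    from acrage.recap import plot_trajectories

    plot_trajectories(tab, str(out), peak_stage(tab))
    assert out.exists() and out.stat().st_size > 0
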