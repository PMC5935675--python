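"""Diversity, comparisons, regression and topology maps."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from trialcorr.heterogeneity import (
    EMPTY_BIN,
    SlideSummary,
    compare_fractions,
    compare_pooled_counts,
    compare_shannon,
    diversity_cd8_regression,
    shannon_entropy,
    summaries_frame,
    summarize_slide,
    topology_map,
)
from trialcorr.records import POPULATIONS
from trialcorr.synthetic import SlideSpec, generate_cell_table


def _cells(labels, xy=None, cd8=None, gzmb=None):
    n = len(labels)
    rng = np.random.default_rng(0)
    xy = xy if xy is not None else rng.uniform(0, 500, (n, 2))
    return pd.DataFrame({
        "cell_id": range(n), "x": xy[:, 0], "y": xy[:, 1],
        "jak2_spots": 2, "cep9_spots": 2, "pstat3_intensity": 50.0,
        "pstat3_pos": False, "jak2_amp": False,
        "cd8": cd8 if cd8 is not None else np.zeros(n, bool),
        "gzmb": gzmb if gzmb is not None else np.zeros(n, bool),
        "population": labels,
    })


def _summary(fractions, shannon=None, cd8=0.0, slide_id="s",
             timepoint="baseline", n=100):
    h = shannon if shannon is not None else shannon_entropy(fractions)
    return SlideSummary(slide_id=slide_id, n_cells=n,
                        fractions=tuple(fractions), shannon=h,
                        cd8_per_montage=cd8, gzmb_fraction=float("nan"),
                        timepoint=timepoint)


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(math.log(4))

    def test_single_population_zero(self):
        assert shannon_entropy([1, 0, 0, 0]) == 0.0

    def test_two_equal_populations(self):
        assert shannon_entropy([0.5, 0.5, 0, 0]) == pytest.approx(math.log(2))

    def test_base_two_option(self):
        assert shannon_entropy([0.25] * 4, base=2) == pytest.approx(2.0)

    def test_label_permutation_invariance(self, rng):
        p = rng.dirichlet(np.ones(4))
        assert shannon_entropy(p) == pytest.approx(
            shannon_entropy(p[::-1]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_formula(self, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(4))
        brute = -sum(pi * math.log(pi) for pi in p if pi > 0)
        assert shannon_entropy(p) == pytest.approx(brute, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(50):
            h = shannon_entropy(rng.dirichlet(np.ones(4)))
            assert -1e-12 <= h <= math.log(4) + 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0, 0, 0, 0])


class TestSummarize:
    def test_fractions_conserve_counts(self):
        labels = [POPULATIONS[0]] * 6 + [POPULATIONS[1]] * 3 + \
            [POPULATIONS[3]] * 1
        s = summarize_slide(_cells(labels))
        counts = np.array(s.fractions) * s.n_cells
        assert np.allclose(counts, [6, 3, 0, 1])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_slide(_cells([]))

    def test_cd8_per_montage_averaging(self):
        labels = [POPULATIONS[0]] * 12
        cd8 = np.array([True] * 6 + [False] * 6)
        montages = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1])
        s = summarize_slide(_cells(labels, cd8=cd8), montages=montages)
        assert s.cd8_per_montage == pytest.approx(3.0)

    def test_gzmb_fraction(self):
        labels = [POPULATIONS[0]] * 8
        cd8 = np.array([True] * 4 + [False] * 4)
        gzmb = np.array([True, True, False, False] + [False] * 4)
        s = summarize_slide(_cells(labels, cd8=cd8, gzmb=gzmb))
        assert s.gzmb_fraction == pytest.approx(0.5)

    def test_gzmb_nan_without_cd8(self):
        s = summarize_slide(_cells([POPULATIONS[0]] * 5))
        assert math.isnan(s.gzmb_fraction)

    def test_frame_round_trip(self):
        s = _summary([0.5, 0.5, 0, 0])
        frame = summaries_frame([s])
        assert frame.loc[0, "shannon"] == pytest.approx(math.log(2))


class TestCompare:
    def test_identical_groups_p_one(self):
        g = [_summary([0.4, 0.6, 0, 0], slide_id=f"a{i}") for i in range(3)]
        res = compare_fractions(g, list(g), population=1)
        assert res.p_value == 1.0

    def test_paired_three_same_sign(self):
        a = [_summary([0.6, 0.4, 0, 0]), _summary([0.7, 0.3, 0, 0]),
             _summary([0.8, 0.2, 0, 0])]
        b = [_summary([0.4, 0.6, 0, 0]), _summary([0.3, 0.7, 0, 0]),
             _summary([0.5, 0.5, 0, 0])]
        res = compare_fractions(a, b, population=0, paired=True)
        assert res.p_value == pytest.approx(0.25)

    def test_paired_t_alternative(self):
        a = [_summary([0.6, 0.4, 0, 0]), _summary([0.7, 0.3, 0, 0]),
             _summary([0.8, 0.2, 0, 0])]
        b = [_summary([0.4, 0.6, 0, 0]), _summary([0.3, 0.7, 0, 0]),
             _summary([0.5, 0.5, 0, 0])]
        res = compare_fractions(a, b, population=0, paired=True, method="t")
        assert res.test_name == "paired_t"
        assert res.p_value < 0.05  # consistent one-directional shift

    def test_paired_unequal_lengths_rejected(self):
        a = [_summary([1, 0, 0, 0])] * 3
        b = [_summary([1, 0, 0, 0])] * 2
        with pytest.raises(ValueError):
            compare_fractions(a, b, population=0, paired=True)

    def test_shannon_comparison(self):
        a = [_summary([0.97, 0.01, 0.01, 0.01], slide_id=f"a{i}")
             for i in range(3)]
        b = [_summary([0.25, 0.25, 0.25, 0.25], slide_id=f"b{i}")
             for i in range(3)]
        res = compare_shannon(a, b)
        assert res.test_name == "wilcoxon_rank_sum"
        assert 0 < res.p_value <= 1

    def test_bad_population_index(self):
        a = [_summary([1, 0, 0, 0])] * 2
        with pytest.raises(ValueError):
            compare_fractions(a, a, population=7)


class TestPooledCounts:
    def test_identical_vectors(self):
        res = compare_pooled_counts([10, 20, 30, 40], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_separation(self):
        with pytest.warns(UserWarning):  # two all-zero populations collapse
            res = compare_pooled_counts([100, 0, 0, 0], [0, 100, 0, 0])
        assert res.p_value < 1e-10

    def test_hand_computed_table(self):
        a = np.array([10, 20, 30, 40])
        b = np.array([20, 20, 20, 40])
        # independent textbook computation: sum (O-E)^2 / E over all cells
        col = a + b
        expected_a = col * a.sum() / (a.sum() + b.sum())
        expected_b = col * b.sum() / (a.sum() + b.sum())
        stat = (((a - expected_a) ** 2 / expected_a).sum()
                + ((b - expected_b) ** 2 / expected_b).sum())
        res = compare_pooled_counts(a, b)
        assert res.statistic == pytest.approx(stat, abs=1e-10)
        assert res.extra["df"] == 3
        assert res.p_value == pytest.approx(float(sps.chi2.sf(stat, 3)))

    def test_zero_margin_collapsed_with_warning(self):
        with pytest.warns(UserWarning):
            res = compare_pooled_counts([10, 20, 0, 0], [15, 15, 0, 0])
        assert res.extra["df"] == 1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compare_pooled_counts([0, 0, 0, 0], [1, 1, 1, 1])


class TestRegression:
    def test_exact_line(self):
        xs = [0.1, 0.5, 0.9, 1.3]
        summaries = [_summary([0.25] * 4, shannon=x, cd8=2 * x + 1,
                              slide_id=f"s{i}")
                     for i, x in enumerate(xs)]
        fit = diversity_cd8_regression(summaries)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_constant_x_undefined(self):
        summaries = [_summary([0.25] * 4, shannon=0.5, cd8=float(i),
                              slide_id=f"s{i}") for i in range(4)]
        fit = diversity_cd8_regression(summaries)
        assert not fit.defined

    def test_too_few_slides_rejected(self):
        with pytest.raises(ValueError):
            diversity_cd8_regression([_summary([0.25] * 4)] * 2)

    def test_stratum_filter(self):
        prim = [_summary([0.25] * 4, shannon=x, cd8=5 - 3 * x,
                         slide_id=f"p{i}", timepoint="primary")
                for i, x in enumerate([0.2, 0.6, 1.0, 1.2])]
        met = [_summary([0.25] * 4, shannon=x, cd8=1.0, slide_id=f"m{i}",
                        timepoint="metastasis")
               for i, x in enumerate([0.3, 0.7, 1.1])]
        fit = diversity_cd8_regression(prim + met, stratum="primary")
        assert fit.n == 4
        assert fit.slope == pytest.approx(-3.0, abs=1e-9)

    def test_negative_association_power(self):
        """Planted correlation -0.7 at n=30 detected (negative slope,
        p < 0.05) in >= 80% of replicates."""
        hits = 0
        n_reps = 200
        rho = -0.7
        for rep in range(n_reps):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=30)
            y = rho * x + math.sqrt(1 - rho ** 2) * rng.normal(size=30)
            summaries = [
                _summary([0.25] * 4,
                         shannon=float(0.7 + 0.3 * np.tanh(xi)),
                         cd8=float(yi), slide_id=f"s{i}")
                for i, (xi, yi) in enumerate(zip(x, y))]
            fit = diversity_cd8_regression(summaries)
            hits += fit.slope < 0 and fit.p_value < 0.05
        assert hits / n_reps >= 0.80

    def test_permutation_null_uniform_p(self):
        """Shuffling y: regression p-values are uniform (KS at alpha=0.01)."""
        rng = np.random.default_rng(42)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        ps = []
        for _ in range(500):
            yy = rng.permutation(y)
            summaries = [
                _summary([0.25] * 4, shannon=float(0.7 + 0.3 * np.tanh(xi)),
                         cd8=float(yi), slide_id=f"s{i}")
                for i, (xi, yi) in enumerate(zip(x, yy))]
            ps.append(diversity_cd8_regression(summaries).p_value)
        _, ks_p = sps.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_band_brackets_fit(self):
        xs = np.linspace(0.1, 1.3, 10)
        rng = np.random.default_rng(3)
        summaries = [_summary([0.25] * 4, shannon=float(x),
                              cd8=float(2 * x + rng.normal(0, 0.2)),
                              slide_id=f"s{i}") for i, x in enumerate(xs)]
        fit = diversity_cd8_regression(summaries)
        assert (fit.band["ci_low"] <= fit.band["fit"]).all()
        assert (fit.band["fit"] <= fit.band["ci_high"]).all()


class TestTopology:
    def test_empty_bins_marked(self):
        labels = [POPULATIONS[0]] * 4
        xy = np.array([[10.0, 10.0]] * 4)
        cells = _cells(labels, xy=xy)
        tmap = topology_map(cells, bin_size=32, width=128, height=128)
        assert tmap.dominant[0, 0] == 0
        assert (tmap.dominant == EMPTY_BIN).sum() == tmap.dominant.size - 1

    def test_counts_conserved(self):
        table = generate_cell_table(SlideSpec(n_cells=150, seed=12))
        tmap = topology_map(table, bin_size=64, width=512, height=512)
        assert tmap.counts.sum() == 150

    def test_clustered_bins_reproduce_planted_assignment(self):
        """With strong (but noisy, 90%) label inheritance, the per-bin
        dominant label matches the planted cluster assignment (majority
        parent label) for >= 90% of occupied bins."""
        spec = SlideSpec(width=900, height=900, n_cells=500, clustering=0.9,
                         nucleus_radius=5.0, placement_gap=2.0,
                         cluster_sigma=25.0, cells_per_cluster=50, seed=44)
        table = generate_cell_table(spec)
        planted = table.attrs["planted_cluster_labels"]
        tmap = topology_map(table, bin_size=60, width=900, height=900)
        ix = np.clip(np.digitize(table["x"], tmap.x_edges) - 1, 0,
                     len(tmap.x_edges) - 2)
        iy = np.clip(np.digitize(table["y"], tmap.y_edges) - 1, 0,
                     len(tmap.y_edges) - 2)
        ok = tot = 0
        for by in range(len(tmap.y_edges) - 1):
            for bx in range(len(tmap.x_edges) - 1):
                sel = (ix == bx) & (iy == by)
                if not sel.any():
                    continue
                mode = np.bincount(planted[sel], minlength=4).argmax()
                tot += 1
                ok += tmap.dominant[by, bx] == mode
        assert ok / tot >= 0.9

    def test_uniform_slide_within_multinomial_bounds(self):
        """No bin's dominant-label count exceeds its Bonferroni-adjusted
        99% binomial bound under the balanced mixture."""
        spec = SlideSpec(width=900, height=900, n_cells=600, seed=45)
        table = generate_cell_table(spec)
        tmap = topology_map(table, bin_size=90, width=900, height=900)
        totals = tmap.counts.sum(axis=2)
        occupied = totals > 0
        n_occ = int(occupied.sum())
        for iy, ix in zip(*np.nonzero(occupied)):
            n_bin = totals[iy, ix]
            crit = sps.binom.ppf(1 - 0.01 / (4 * n_occ), n_bin, 0.25)
            assert tmap.counts[iy, ix].max() <= crit

    def test_points_by_population_layers(self):
        table = generate_cell_table(SlideSpec(n_cells=80, seed=13))
        tmap = topology_map(table, bin_size=64, width=512, height=512)
        layers = tmap.points_by_population(table)
        assert sum(len(v) for v in layers.values()) == 80

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValueError):
            topology_map(_cells([POPULATIONS[0]]), bin_size=0)
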