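"""Association machinery: Wilson intervals, 2x2 tests, trend tests, screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfbsc.association_stats import (
    epistasis_pair_test,
    equal_population_bins,
    per_tf_screen,
    permutation_p_value,
    trend_test,
    two_level_association,
    wilson_interval,
)


def _wilson_by_hand(k, n, z=1.959963984540054):
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestWilson:
    def test_zero_successes_lower_bound_is_zero(self):
        lo, hi = wilson_interval(0, 20)
        assert lo == 0.0 and hi > 0

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = wilson_interval(20, 20)
        assert hi == pytest.approx(1.0) and lo < 1

    def test_closed_form_example(self):
        assert wilson_interval(5, 10) == pytest.approx((0.2366, 0.7634), abs=5e-4)

    @pytest.mark.parametrize("k,n", [(1, 7), (5, 10), (29, 30), (13, 200)])
    def test_matches_independent_closed_form(self, k, n):
        assert wilson_interval(k, n) == pytest.approx(_wilson_by_hand(k, n), abs=1e-9)

    def test_interval_contains_point_estimate(self):
        for k, n in [(0, 5), (3, 9), (9, 9)]:
            lo, hi = wilson_interval(k, n)
            assert lo <= k / n <= hi

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(0, 0)


class TestEqualPopulationBins:
    def test_twelve_distinct_values_into_six_pairs(self):
        values = np.arange(12, dtype=float)
        bins, edges = equal_population_bins(values, 6)
        counts = np.bincount(bins)
        assert list(counts) == [2] * 6
        assert len(edges) == 6

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            equal_population_bins(np.ones(20), 4)

    def test_fewer_than_two_bins_rejected(self):
        with pytest.raises(ValueError):
            equal_population_bins(np.arange(10.0), 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ties_never_straddle_a_bin_edge(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 8, 200).astype(float)  # heavy ties
        bins, _ = equal_population_bins(values, 6)
        # brute-force check: equal values share a bin
        for v in np.unique(values):
            assert len(set(bins[values == v])) == 1

    def test_bins_ordered_by_value(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=300)
        bins, edges = equal_population_bins(values, 6)
        means = [values[bins == b].mean() for b in range(6)]
        assert all(means[i] < means[i + 1] for i in range(5))


class TestTwoLevel:
    def test_cross_product_odds_ratio(self):
        odds, p, test = two_level_association([[20, 10], [10, 20]])
        assert odds == pytest.approx(4.0)
        assert test == "chi2"

    def test_homogeneous_table(self):
        odds, p, _ = two_level_association([[10, 10], [10, 10]])
        assert odds == pytest.approx(1.0)
        assert p > 0.9

    def test_small_expected_counts_use_fisher(self):
        _odds, _p, test = two_level_association([[3, 1], [1, 3]])
        assert test == "fisher"

    def test_zero_cell_gets_haldane_correction(self):
        odds, _p, _ = two_level_association([[10, 0], [5, 5]])
        assert odds == pytest.approx((10.5 * 5.5) / (0.5 * 5.5))

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            two_level_association([[0, 0], [5, 5]])

    def test_or_invariances(self):
        t = np.array([[20, 10], [5, 25]])
        odds, _, _ = two_level_association(t)
        both_swapped, _, _ = two_level_association(t[::-1, ::-1])
        assert both_swapped == pytest.approx(odds)
        one_swapped, _, _ = two_level_association(t[::-1, :])
        assert one_swapped == pytest.approx(1 / odds)


class TestTrendTest:
    def test_deviance_drop_is_twice_the_loglik_difference(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, 400).astype(float)
        y = rng.random(400) < 1 / (1 + np.exp(-(x - 1.5)))
        res = trend_test(y.astype(float), x)

        def loglik(xcols):
            from tfbsc.integrated_model import fit_binomial_glm
            fit = fit_binomial_glm(np.column_stack(xcols), y.astype(float))
            mu = fit.mu
            return (y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum()

        ll_full = loglik([np.ones(400), x])
        ll_red = loglik([np.ones(400)])
        assert res["deviance_drop"] == pytest.approx(2 * (ll_full - ll_red), abs=1e-6)
        assert res["direction"] == 1.0

    def test_saturated_two_level_matches_g_test(self):
        rng = np.random.default_rng(1)
        x = (rng.random(500) < 0.5).astype(float)
        y = rng.random(500) < np.where(x > 0, 0.7, 0.4)
        res = trend_test(y.astype(float), x)
        table = np.array(
            [[((x == 0) & ~y).sum(), ((x == 0) & y).sum()],
             [((x == 1) & ~y).sum(), ((x == 1) & y).sum()]]
        )
        g = stats.chi2_contingency(table, correction=False,
                                   lambda_="log-likelihood")
        assert res["p_value"] == pytest.approx(g.pvalue, abs=1e-8)

    def test_separation_flagged_not_raised(self):
        x = np.array([0.0, 0, 0, 1, 1, 1] * 5)
        y = x.copy()
        res = trend_test(y, x)
        assert res["ok"] is False

    def test_single_level_predictor_rejected(self):
        with pytest.raises(ValueError):
            trend_test(np.array([0.0, 1, 0, 1]), np.ones(4))


class TestPerTfScreen:
    def _data(self, rng, n_tf=6, n=80, effect=1.5):
        rows = []
        for t in range(n_tf):
            x = rng.integers(1, 5, n).astype(float)
            p = 1 / (1 + np.exp(-(effect * (x - 2.5))))
            y = (rng.random(n) < p).astype(int)
            rows.append(pd.DataFrame(
                {"tf_id": f"TF{t}", "copy_number": x, "between": y}
            ))
        return pd.concat(rows, ignore_index=True)

    def test_concordance_with_planted_global_effect(self):
        data = self._data(np.random.default_rng(0))
        table, summary = per_tf_screen("copy_number", data)
        assert summary["n_eligible"] == 6
        assert summary["fraction_concordant"] > 0.5

    def test_distance_requires_four_distinct_values(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"tf_id": ["a"] * 12 + ["b"] * 12,
             "distance": [10.0, 20, 30] * 4 + list(np.arange(12.0) * 50),
             "between": rng.integers(0, 2, 24)}
        )
        _table, summary = per_tf_screen("distance", data)
        assert "a" in summary["ineligible"]

    def test_categorical_requires_every_category(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {"tf_id": ["a"] * 30 + ["b"] * 30,
             "subtelomeric": [True] * 30 + list(rng.random(30) < 0.5),
             "between": rng.integers(0, 2, 60)}
        )
        _table, summary = per_tf_screen("subtelomeric", data)
        assert "a" in summary["ineligible"]


class TestEpistasis:
    def test_planted_negative_pairs_reduce_conservation(self, small_sim, small_calls):
        res = epistasis_pair_test(
            small_sim.features.copy(), small_calls[["site_id", "between"]]
        )
        assert res.odds_ratio < 1.0

    def test_missing_flag_column_is_an_error(self, small_calls):
        with pytest.raises(ValueError, match="emap_partner"):
            epistasis_pair_test(pd.DataFrame({"site_id": ["s1"]}), small_calls)

    def test_single_group_is_degenerate(self, small_calls):
        feats = pd.DataFrame(
            {"site_id": small_calls["site_id"], "emap_partner": False}
        )
        with pytest.raises(ValueError, match="single"):
            epistasis_pair_test(feats, small_calls)


def test_permutation_p_value_is_calibrated_under_the_null():
    rng = np.random.default_rng(4)
    y = rng.integers(0, 2, 60)
    x = rng.random(60)

    def stat(perm_y):
        return float(x[perm_y == 1].mean() - x[perm_y == 0].mean())

    p = permutation_p_value(stat, y, n_permutations=500, seed=1)
    assert 0.01 < p <= 1.0
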