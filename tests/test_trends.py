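import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from hspcflow import trends


def _grid_trend(values, gene="g", grid=None):
    values = np.asarray(values, dtype=float)
    grid = np.linspace(0, 1, values.size) if grid is None else grid
    return trends.GeneTrend(gene=gene, branch="b", grid=grid, values=values)


class TestFitTrend:
    def test_constant_expression_gives_constant_trend(self):
        rng = np.random.default_rng(0)
        t = rng.random(200)
        tr = trends.fit_trend(np.full(200, 3.25), t, None)
        assert np.abs(tr.values - 3.25).max() < 1e-6

    def test_noiseless_linear_recovered_on_interior(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.random(400))
        tr = trends.fit_trend(t.copy(), t, None)
        inner = slice(10, -10)
        assert np.abs(tr.values[inner] - tr.grid[inner]).max() < 0.01

    def test_zero_weight_cells_cannot_influence_fit(self):
        rng = np.random.default_rng(2)
        t = rng.random(300)
        w = (np.arange(300) % 2 == 0).astype(float)
        y = np.sin(2 * np.pi * t)
        corrupted = y.copy()
        corrupted[w == 0] = 1e6
        a = trends.fit_trend(y, t, w)
        b = trends.fit_trend(corrupted, t, w)
        assert np.array_equal(a.values, b.values)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        t = rng.random(250)
        y = np.cos(3 * t) + rng.normal(0, 0.2, 250)
        w = rng.random(250)
        base = trends.fit_trend(y, t, w)
        shifted = trends.fit_trend(y + 7.5, t, w)
        assert np.abs(shifted.values - (base.values + 7.5)).max() < 1e-8

    def test_degenerate_inputs_rejected(self):
        t = np.linspace(0, 1, 50)
        y = np.sin(t)
        with pytest.raises(trends.TrendError):
            trends.fit_trend(y, t, np.zeros(50))
        with pytest.raises(trends.TrendError):
            trends.fit_trend(y, np.full(50, 0.5), None)
        with pytest.raises(trends.TrendError):
            trends.fit_trend(y[:10], t[:10], None)  # below min_cells


class TestClusterTrends:
    def test_identical_trends_share_a_cluster(self):
        rng = np.random.default_rng(0)
        curve = np.sin(np.linspace(0, 6, 100))
        other = np.cos(np.linspace(0, 6, 100))
        ts = {
            "a": _grid_trend(curve),
            "b": _grid_trend(curve.copy()),
            "c": _grid_trend(other),
        }
        labels = trends.cluster_trends(ts, 2)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_k_equal_to_gene_count_gives_singletons(self):
        rng = np.random.default_rng(1)
        ts = {
            f"g{i}": _grid_trend(rng.normal(size=50)) for i in range(4)
        }
        labels = trends.cluster_trends(ts, 4)
        assert labels.nunique() == 4

    def test_anticorrelated_families_separate_cleanly(self):
        grid = np.linspace(0, 1, 200)
        rng = np.random.default_rng(2)
        ts, truth = {}, []
        for i in range(6):
            up = grid**2 + rng.normal(0, 0.01, 200)
            down = -(grid**2) + rng.normal(0, 0.01, 200)
            ts[f"up{i}"] = _grid_trend(up)
            ts[f"down{i}"] = _grid_trend(down)
            truth += [0, 1]
        labels = trends.cluster_trends(ts, 2)
        pred = [labels[g] for g in ts]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_constant_trend_goes_to_flat_group(self):
        ts = {
            "flat": _grid_trend(np.full(60, 2.0)),
            "a": _grid_trend(np.sin(np.linspace(0, 5, 60))),
            "b": _grid_trend(np.cos(np.linspace(0, 5, 60))),
        }
        with pytest.warns(UserWarning, match="flat"):
            labels = trends.cluster_trends(ts, 2)
        assert labels["flat"] == trends.FLAT_CLUSTER


def enumeration_oracle(a, b):
    """Independent exact two-sided rank-sum p by explicit enumeration."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum()
    sums = [
        sum(ranks[i] for i in comb)
        for comb in itertools.combinations(range(len(pooled)), n)
    ]
    sums = np.asarray(sums)
    p_le = (sums <= u_obs + 1e-9).mean()
    p_ge = (sums >= u_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestTrendWilcoxon:
    def test_worked_small_sample_case(self):
        assert trends.trend_wilcoxon([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_trends_not_significant(self):
        v = np.arange(8.0)
        assert trends.trend_wilcoxon(v, v) == 1.0

    def test_symmetric_in_arguments(self):
        a = [1.0, 5.0, 2.0, 8.0]
        b = [3.0, 3.0, 9.0]
        assert trends.trend_wilcoxon(a, b) == trends.trend_wilcoxon(b, a)

    @given(
        st.lists(st.integers(0, 6), min_size=2, max_size=8),
        st.lists(st.integers(0, 6), min_size=2, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        assert trends.trend_wilcoxon(a, b) == pytest.approx(
            enumeration_oracle(a, b)
        )

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.5, 1, 100)
        ours = trends.trend_wilcoxon(a, b)
        ref = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        )[1]
        assert ours == ref


class TestCompareTrends:
    def test_identical_sets_are_ns(self):
        grid = np.linspace(0, 1, 120)
        ts = {f"g{i}": _grid_trend(np.sin(grid * (i + 1)), grid=grid)
              for i in range(5)}
        res = trends.compare_trends(ts, {k: _grid_trend(v.values, grid=grid)
                                         for k, v in ts.items()})
        assert (res["tier"] == "NS").all()
        assert (res["p_raw"] == 1.0).all()

    def test_grid_length_mismatch_rejected(self):
        a = {"g": _grid_trend(np.zeros(10))}
        b = {"g": _grid_trend(np.zeros(12))}
        with pytest.raises(trends.TrendError):
            trends.compare_trends(a, b)

    def test_tier_thresholds(self):
        assert trends.significance_tier(0.2) == "NS"
        assert trends.significance_tier(0.03) == "*"
        assert trends.significance_tier(0.005) == "**"
        assert trends.significance_tier(0.0005) == "***"
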