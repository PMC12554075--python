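"""Paired t-test, percentile bootstrap and mean/SEM summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bretropy.stats import (
    DegenerateComparisonError,
    bootstrap_ci,
    compare_with_ci,
    holm_adjust,
    paired_t,
    summarize,
)


class TestPairedT:
    def test_hand_computed_example(self):
        """Differences (1,2,3): mean 2, SD 1 -> t = 2*sqrt(3), df = 2."""
        res = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.t_stat == pytest.approx(2.0 * math.sqrt(3.0), rel=1e-10)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(1.0)

    def test_antisymmetric_under_condition_swap(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.t_stat == pytest.approx(-b.t_stat, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_identical_pairs_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateComparisonError):
            paired_t(x, x)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_scipy_ttest_rel(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 30)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert res.t_stat == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_many_random_sets_match_scipy(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            ref = sps.ttest_rel(x, y)
            res = paired_t(x, y)
            assert abs(res.t_stat - ref.statistic) < 1e-10
            assert abs(res.p_value - ref.pvalue) < 1e-8

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            paired_t(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestBootstrap:
    def test_constant_differences_collapse_to_point(self):
        lo, hi = bootstrap_ci(np.full(10, 0.5), seed=0)
        assert (lo, hi) == (0.5, 0.5)

    def test_fixed_seed_deterministic(self, rng):
        d = rng.normal(size=15)
        assert bootstrap_ci(d, seed=123) == bootstrap_ci(d, seed=123)
        assert bootstrap_ci(d, seed=123) != bootstrap_ci(d, seed=124)

    def test_interval_brackets_mean_and_orders(self, rng):
        d = rng.normal(0.5, 1.0, size=40)
        lo, hi = bootstrap_ci(d, n_boot=2000, seed=1)
        assert lo <= d.mean() <= hi

    def test_width_shrinks_with_sample_size(self):
        """Bootstrap CI width scales roughly as 1/sqrt(n)."""
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            d20 = rng.normal(0.3, 1.0, 20)
            d80 = rng.normal(0.3, 1.0, 80)
            lo20, hi20 = bootstrap_ci(d20, seed=s)
            lo80, hi80 = bootstrap_ci(d80, seed=s)
            wins += (hi80 - lo80) < (hi20 - lo20)
        assert wins >= 8

    def test_rejects_tiny_inputs(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]))
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0, 2.0]), n_boot=10)

    def test_compare_with_ci_brackets_mean_diff(self, rng):
        x, y = rng.normal(1.0, 0.3, 12), rng.normal(0.5, 0.3, 12)
        res = compare_with_ci(x, y, n_boot=500, seed=7)
        assert res.ci_low <= res.mean_diff <= res.ci_high
        assert res.n_boot == 500 and res.seed == 7


class TestSummarize:
    def _table(self):
        return pd.DataFrame(
            {
                "condition": ["c"] * 6,
                "metric": ["sampen"] * 6,
                "alpha": [np.nan] * 6,
                "tau": [1] * 6,
                "experiment_id": ["E1", "E1", "E2", "E2", "E3", "E3"],
                "value": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
            }
        )

    def test_wells_averaged_before_sem(self):
        out = summarize(self._table())
        assert len(out) == 1
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "sem"] == pytest.approx(1.0 / math.sqrt(3.0))
        assert out.loc[0, "n_experiments"] == 3

    def test_single_experiment_sem_missing(self):
        df = self._table().iloc[:2]
        out = summarize(df)
        assert math.isnan(out.loc[0, "sem"])

    def test_row_order_invariance(self):
        df = self._table()
        a = summarize(df)
        b = summarize(df.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(
            a.sort_values("condition").reset_index(drop=True),
            b.sort_values("condition").reset_index(drop=True),
            check_like=True,
        )

    def test_nan_values_dropped_with_warning(self):
        df = self._table()
        df.loc[0, "value"] = np.nan
        with pytest.warns(RuntimeWarning, match="dropped"):
            out = summarize(df)
        assert out.loc[0, "n_experiments"] == 3


class TestHolm:
    def test_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.2])
        adj = holm_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        assert adj[np.argsort(p)].tolist() == sorted(adj[np.argsort(p)].tolist())
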