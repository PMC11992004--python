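import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dendritemp.core import AsvTable, LoggerSeries, ValidationError
from dendritemp.preprocess import (
    RarefactionSpec,
    percentile_depth,
    rarefaction_curve,
    rarefy,
    remove_singletons,
    suva,
    to_relative_abundance,
    window_mean,
    zscore,
)


def _table(rows, samples=None, asvs=None):
    rows = np.atleast_2d(rows)
    return AsvTable(pd.DataFrame(
        rows,
        index=samples or [f"s{i}" for i in range(rows.shape[0])],
        columns=asvs or [f"a{j}" for j in range(rows.shape[1])],
    ))


class TestRemoveSingletons:
    def test_total_one_dropped_total_two_retained(self):
        t = _table([[1, 1, 0], [0, 1, 5]])  # a0 total 1, a1 total 2, a2 total 5
        out = remove_singletons(t)
        assert out.asv_ids == ["a1", "a2"]

    def test_identity_without_singletons(self):
        t = _table([[2, 3], [4, 5]])
        assert remove_singletons(t) == t

    def test_exclusion_list(self):
        t = _table([[2, 3], [4, 5]])
        assert remove_singletons(t, exclude=["a0"]).asv_ids == ["a1"]


class TestPercentileDepth:
    def test_zero_percentile_is_minimum(self):
        t = _table(np.diag([10, 20, 30, 40]))
        assert percentile_depth(t, 0) == 10

    def test_constant_totals(self):
        t = _table([[7, 0], [3, 4], [0, 7]])
        for q in (0, 5, 50, 100):
            assert percentile_depth(t, q) == 7

    def test_linear_interpolation_matches_order_statistic_oracle(self):
        totals = np.arange(1, 101)
        t = _table(np.diag(totals))
        # brute-force oracle: linear interpolation between sorted order stats
        srt = np.sort(totals)
        pos = 5 / 100 * (len(srt) - 1)
        lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
        expected = int(np.floor(srt[lo] + frac * (srt[lo + 1] - srt[lo])))
        assert percentile_depth(t, 5) == expected == 5


class TestRarefy:
    def test_boundary_identity_at_exact_depth(self):
        t = _table([[2000, 1352]])
        out = rarefy(t, RarefactionSpec(3352, seed=1))
        assert out == t

    def test_passthrough_below_depth(self):
        t = _table([[2000, 239], [3000, 352]])  # totals 2239, 3352
        out = rarefy(t, RarefactionSpec(3352, passthrough_below_depth=True, seed=1))
        assert out.sample_totals().tolist() == [2239, 3352]
        assert out.counts.loc["s0"].tolist() == [2000, 239]

    def test_drop_below_depth(self):
        t = _table([[2000, 239], [3000, 352]])
        out = rarefy(t, RarefactionSpec(3352, passthrough_below_depth=False, seed=1))
        assert out.sample_ids == ["s1"]
        with pytest.raises(ValidationError):
            rarefy(_table([[1, 1]]), RarefactionSpec(10, passthrough_below_depth=False))

    def test_totals_and_bounds_invariants(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 50, size=(6, 20)))
        depth = 200
        out = rarefy(t, RarefactionSpec(depth, seed=3))
        for sid in out.sample_ids:
            assert out.sample_totals()[sid] == min(depth, t.sample_totals()[sid])
            assert (out.counts.loc[sid] <= t.counts.loc[sid]).all()

    def test_deterministic_given_seed(self):
        t = _table([[500, 300, 200]])
        a = rarefy(t, RarefactionSpec(100, seed=9))
        b = rarefy(t, RarefactionSpec(100, seed=9))
        assert a == b

    def test_hypergeometric_expectation(self):
        # (1000, 1000) rarefied to 1000: marginal is hypergeometric with
        # mean 500, var 1000*0.25*(1000/1999) ≈ 125.1
        t = _table([[1000, 1000]])
        n = 2000
        vals = np.array([
            rarefy(t, RarefactionSpec(1000, seed=s)).counts.iloc[0, 0]
            for s in range(n)
        ])
        sd_mean = np.sqrt(1000 * 0.25 * (1000 / 1999) / n)
        assert abs(vals.mean() - 500) < 3 * sd_mean

    def test_exchangeable_over_asv_order(self):
        # permuting ASV order leaves per-ASV mean rarefied counts unchanged
        t = _table([[400, 300, 200, 100]])
        perm = ["a2", "a0", "a3", "a1"]
        tp = AsvTable(t.counts[perm])
        n = 400
        means = np.mean([rarefy(t, RarefactionSpec(100, seed=s)).counts.to_numpy()[0]
                         for s in range(n)], axis=0)
        means_p = np.mean([rarefy(tp, RarefactionSpec(100, seed=s)).counts.to_numpy()[0]
                           for s in range(n)], axis=0)
        back = pd.Series(means_p, index=perm).loc[t.counts.columns].to_numpy()
        # both estimate the same hypergeometric means (40, 30, 20, 10)
        sd = np.sqrt(100 * 0.4 * 0.6 * (900 / 999) / n) * 3
        assert np.all(np.abs(means - back) < 2 * sd)


class TestRelativeAbundance:
    def test_examples_and_row_sums(self):
        p = to_relative_abundance(_table([[2, 2, 0], [3352, 0, 0]]))
        assert p.iloc[0].tolist() == [0.5, 0.5, 0.0]
        assert p.iloc[1].tolist() == [1.0, 0.0, 0.0]
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named(self):
        with pytest.raises(ValidationError, match="s1"):
            to_relative_abundance(_table([[1, 2], [0, 0]]))


class TestZscore:
    def _env(self, values):
        return pd.DataFrame(
            {"site_id": [f"S{i}" for i in range(len(values))],
             "occasion": [1] * len(values), "pH": values}
        ).set_index(["site_id", "occasion"])

    def test_mean_zero_sd_one(self):
        out = zscore(self._env([5.0, 6.0, 7.5, 8.0]), ["pH"])
        assert abs(out["pH"].mean()) < 1e-12
        assert abs(out["pH"].std(ddof=1) - 1) < 1e-12

    def test_two_value_column(self):
        out = zscore(self._env([1.0, 3.0]), ["pH"])
        assert np.allclose(sorted(out["pH"]), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_missing_stays_missing(self):
        out = zscore(self._env([1.0, np.nan, 3.0]), ["pH"])
        assert np.isnan(out["pH"].iloc[1])
        assert abs(out["pH"].dropna().mean()) < 1e-12

    def test_zero_variance_named(self):
        with pytest.raises(ValidationError, match="pH"):
            zscore(self._env([2.0, 2.0, 2.0]), ["pH"])


class TestSuva:
    def test_ratio(self):
        assert suva(0.5, 10.0) == pytest.approx(0.05)
        assert suva(0.0, 3.0) == 0.0
        assert suva(0.5, 10.0, scale=100) == pytest.approx(5.0)

    def test_nonpositive_doc_rejected(self):
        with pytest.raises(ValueError):
            suva(0.5, 0.0)


class TestWindowMean:
    def _series(self, stamps, values):
        return LoggerSeries("H1", "temperature", tuple(stamps), tuple(values))

    def test_constant_series(self):
        s = self._series(pd.date_range("2018-07-01", periods=48, freq="30min"), [4.0] * 48)
        mean, n = window_mean(s, pd.Timestamp("2018-07-03").date(), 7)
        assert mean == 4.0 and n == 48

    def test_two_point_mean_and_half_open_window(self):
        s = self._series(["2018-06-30 06:00", "2018-06-30 18:00", "2018-07-01 00:00"],
                         [1.0, 3.0, 99.0])
        mean, n = window_mean(s, pd.Timestamp("2018-07-01").date(), 7)
        assert mean == 2.0 and n == 2  # the sample-date point is excluded

    def test_empty_window_warns_and_returns_nan(self):
        s = self._series(["2018-01-01"], [1.0])
        with pytest.warns(UserWarning):
            mean, n = window_mean(s, pd.Timestamp("2018-07-01").date(), 7)
        assert np.isnan(mean) and n == 0


class TestRarefactionCurve:
    def test_full_depth_gives_observed_richness(self):
        counts = pd.Series([5, 3, 0, 2])
        assert rarefaction_curve(counts, [10])[0] == pytest.approx(3.0)

    def test_depth_one_gives_one(self):
        assert rarefaction_curve(pd.Series([5, 5]), [1])[0] == pytest.approx(1.0)

    def test_hand_value_and_monte_carlo(self):
        # (5, 5) at depth 2: E[S] = 2 - 2*C(5,2)/C(10,2) = 2 - 20/45
        expected = 2 - 20 / 45
        got = rarefaction_curve(pd.Series([5, 5]), [2])[0]
        assert got == pytest.approx(expected, abs=1e-12)
        rng = np.random.default_rng(0)
        draws = 2000
        rich = [np.count_nonzero(rng.multivariate_hypergeometric([5, 5], 2))
                for _ in range(draws)]
        mc = np.mean(rich)
        assert abs(got - mc) < 3 * np.std(rich, ddof=1) / np.sqrt(draws)

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction_curve(pd.Series([2, 2]), [5])

    @given(st.lists(st.integers(1, 20), min_size=2, max_size=6))
    def test_monotone_in_depth(self, counts):
        total = sum(counts)
        curve = rarefaction_curve(pd.Series(counts), list(range(1, total + 1)))
        assert np.all(np.diff(curve) >= -1e-9)
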