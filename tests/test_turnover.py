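"""Gap-filler turnover counts, rates, rarefaction and aggregation."""

import math
import random

import numpy as np
import pytest

from paleodiv.binning import bin_per_unit
from paleodiv.synthetic import SimulationConfig, simulate_dataset
from paleodiv.turnover import (
    RateSeries,
    TurnoverCounts,
    aggregate_replicates,
    extinction_rate_series,
    gap_filler_rate,
    origination_rate_series,
    rarefied_rates,
    turnover_counts,
)

from conftest import make_table


def _presence_from_patterns(patterns, n_bins):
    P = np.zeros((len(patterns), n_bins), dtype=bool)
    for t, bins in enumerate(patterns):
        P[t, list(bins)] = True
    return P


class TestWindowCounts:
    def test_four_range_patterns(self):
        # X in {i,i+1}, Y in {i,i+1,i+2}, Z in {i,i+2}, V in {i-2,i+1,i+2}
        i = 2
        P = _presence_from_patterns(
            [(i, i + 1), (i, i + 1, i + 2), (i, i + 2), (i - 2, i + 1, i + 2)], 7
        )
        c = turnover_counts(P, i)
        assert (c.t2, c.t3, c.p, c.g) == (2, 1, 1, 1)
        assert gap_filler_rate(c) == pytest.approx(0.0)  # log(3/3)

    def test_perfect_sampling_no_gaps(self):
        # every taxon sampled through its whole range -> p = g = 0
        P = _presence_from_patterns([(0, 1, 2, 3), (1, 2, 3), (0, 1, 2)], 4)
        c = turnover_counts(P, 1)
        assert c.p == 0 and c.g == 0

    def test_out_of_range_window_flagged(self):
        P = _presence_from_patterns([(0, 1)], 3)
        c = turnover_counts(P, 1)
        assert not c.defined
        assert math.isnan(gap_filler_rate(c))

    def test_empty_window_all_zero_flagged(self):
        P = np.zeros((3, 5), dtype=bool)
        P[:, 4] = True
        c = turnover_counts(P, 0)
        assert (c.t2, c.t3, c.p, c.g) == (0, 0, 0, 0)
        assert math.isnan(gap_filler_rate(c))

    def test_three_timers_are_two_timers(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            P = rng.random((8, 6)) < 0.4
            for i in range(4):
                c = turnover_counts(P, i)
                assert c.t3 <= c.t2


class TestGapFillerRate:
    def test_classical_three_timer_limit(self):
        c = TurnoverCounts(i=0, t2=10, t3=8, p=0, g=0)
        assert gap_filler_rate(c) == pytest.approx(math.log(10 / 8))

    def test_no_extinction_when_counts_equal(self):
        c = TurnoverCounts(i=0, t2=5, t3=5, p=0, g=0)
        assert gap_filler_rate(c) == 0.0

    def test_zero_denominator_undefined(self):
        assert math.isnan(gap_filler_rate(TurnoverCounts(0, t2=3, t3=0, p=0, g=0)))
        assert math.isnan(gap_filler_rate(TurnoverCounts(0, t2=0, t3=0, p=0, g=0)))


class TestRangeThroughRefinement:
    def test_identical_under_perfect_sampling(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            # contiguous ranges sampled everywhere = perfect sampling
            n_taxa, n_bins = 10, 8
            P = np.zeros((n_taxa, n_bins), dtype=bool)
            for t in range(n_taxa):
                a, b = sorted(rng.integers(0, n_bins, 2))
                P[t, a : b + 1] = True
            for i in range(n_bins - 2):
                exact = turnover_counts(P, i)
                relaxed = turnover_counts(P, i, third_bin_test="range_through")
                assert (exact.t2, exact.t3, exact.p, exact.g) == (
                    relaxed.t2, relaxed.t3, relaxed.p, relaxed.g,
                )

    def test_denominator_never_smaller(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            P = rng.random((12, 9)) < 0.3
            for i in range(7):
                exact = turnover_counts(P, i)
                relaxed = turnover_counts(P, i, third_bin_test="range_through")
                assert (
                    relaxed.t3 + relaxed.p + relaxed.g
                    >= exact.t3 + exact.p + exact.g
                )


class TestTimeReversal:
    def test_origination_equals_extinction_on_reversed_exactly(self):
        rng = np.random.default_rng(7)
        P = rng.random((30, 10)) < 0.35
        orig = origination_rate_series(P)
        rev_ext = extinction_rate_series(P[:, ::-1])
        np.testing.assert_array_equal(orig.values, rev_ext.values[::-1])

    def test_no_origination_after_initial_cohort(self):
        # all taxa present from bin 0 onward, perfectly sampled
        P = np.ones((20, 8), dtype=bool)
        lam = origination_rate_series(P)
        interior = lam.values[~np.isnan(lam.values)]
        assert np.allclose(interior, 0.0)


class TestRarefiedRates:
    def test_bin_at_quota_uses_full_bin(self):
        counts = np.array([[3, 3, 3, 3], [2, 2, 2, 2]])
        t = make_table(counts)
        rr = rarefied_rates(bin_per_unit(t), quota=5, iterations=20, seed=0)
        # both taxa always present in every bin: constant ranges, mu = 0
        defined = rr.values[~np.isnan(rr.values)]
        assert np.allclose(defined, 0.0)

    def test_below_quota_bins_undefined_not_zero(self):
        counts = np.array([[3, 3, 1, 3, 3], [3, 3, 1, 3, 3]])
        t = make_table(counts)
        rr = rarefied_rates(bin_per_unit(t), quota=4, iterations=10, seed=0)
        # windows touching the starved middle bin are undefined
        assert np.isnan(rr.values[1]) and np.isnan(rr.values[2]) and np.isnan(rr.values[3])

    def test_against_bruteforce_resampling_oracle(self):
        """Independent subsampling oracle with python's RNG."""
        counts = np.array(
            [
                [6, 5, 4, 3],
                [4, 5, 6, 1],
                [5, 2, 0, 4],
                [0, 3, 5, 4],
            ]
        )
        quota, iters = 5, 4000
        t = make_table(counts)
        rr = rarefied_rates(bin_per_unit(t), quota=quota, iterations=iters, seed=21)

        rng = random.Random(77)
        pools = [
            [tx for tx in range(counts.shape[0]) for _ in range(counts[tx, b])]
            for b in range(4)
        ]
        sums = np.zeros(4)
        ns = np.zeros(4)
        for _ in range(iters):
            P = np.zeros((4, 4), dtype=bool)
            for b in range(4):
                for tx in set(rng.sample(pools[b], quota)):
                    P[tx, b] = True
            c = turnover_counts(P, 0)
            r = gap_filler_rate(c)
            if not math.isnan(r):
                sums[1] += r
                ns[1] += 1
            c = turnover_counts(P, 1)
            r = gap_filler_rate(c)
            if not math.isnan(r):
                sums[2] += r
                ns[2] += 1
        oracle = sums / np.maximum(ns, 1)
        # Monte-Carlo agreement within 2 standard errors (rates are O(1),
        # per-iteration sd < 1)
        for b in (1, 2):
            assert rr.values[b] == pytest.approx(oracle[b], abs=2 / math.sqrt(iters) * 25)

    def test_perfect_sampling_calibration(self):
        """With constant true extinction probability q, exp(-mu) estimates
        1-q within binomial noise in the perfect-sampling limit."""
        cfg = SimulationConfig(
            n_bins=14, initial_richness=1500, extinction=0.05, origination=0.05,
            abundance_log_mean=3.0, abundance_log_sd=0.3, sampling_intensity=20.0,
        )
        table, _ = simulate_dataset(cfg, seed=42)
        series = extinction_rate_series(table.presence().to_numpy())
        interior = series.values[2:-2]
        survival = np.exp(-interior[~np.isnan(interior)])
        assert np.abs(survival.mean() - 0.95) < 0.01
        assert np.all(np.abs(survival - 0.95) < 0.03)


class TestAggregation:
    def _series(self, values_list):
        return [
            RateSeries(bins=["a"], values=np.array([v]), metric="extinction", replicate_id=i)
            for i, v in enumerate(values_list)
        ]

    def test_median_of_three(self):
        agg = aggregate_replicates(self._series([0.1, 0.2, 0.9]), seed=0)
        assert agg.median[0] == pytest.approx(0.2)

    def test_equal_replicates_zero_spread(self):
        agg = aggregate_replicates(self._series([0.3, 0.3, 0.3, 0.3]), seed=0)
        assert agg.spread[0] == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_se_close_to_analytic(self):
        """SE of the median of n=100 normals: 1.2533 * sigma / sqrt(n)."""
        rng = np.random.default_rng(123)
        vals = rng.normal(0.0, 1.0, 100)
        agg = aggregate_replicates(self._series(list(vals)), n_boot=4000, seed=1)
        analytic = 1.2533 / math.sqrt(100)
        assert abs(agg.spread[0] - analytic) / analytic < 0.15

    def test_undefined_bins_flagged(self):
        series = self._series([0.5, float("nan"), float("nan")])
        agg = aggregate_replicates(series, seed=0)
        assert agg.n_replicates_defined[0] == 1
        assert math.isnan(agg.spread[0])

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            aggregate_replicates(self._series([0.1]), seed=0)
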