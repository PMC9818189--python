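"""Log-rank, Kaplan-Meier and the exhaustive cut-point search.

The log-rank implementation is checked against a hand-rolled risk-set
tabulation (O/E/V over distinct event times, hypergeometric variance), and
the cut search against a literal loop over every cut.
"""

import numpy as np
import pytest
from scipy.stats import chi2

from tmedeconv import (
    CohortSpec,
    DataError,
    SurvivalRecord,
    km_curve,
    logrank_test,
    make_cohort,
    optimal_split,
    to_months,
)


def recs(times, events, prefix="s"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def brute_force_logrank(ta, ea, tb, eb):
    """Independent O/E/V tabulation over distinct event times (with ties)."""
    ta, ea = np.asarray(ta, float), np.asarray(ea, bool)
    tb, eb = np.asarray(tb, float), np.asarray(eb, bool)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    O = E = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & group_a).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & group_a).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat = (O - E) ** 2 / V if V > 0 else 0.0
    return stat, chi2.sf(stat, 1)


class TestLogrank:
    def test_identical_groups_null(self):
        g = recs([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test(g, recs([1, 2, 3, 4], [1, 1, 0, 1], "t"))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_on_separated_groups(self):
        ta, ea = [1, 2, 3], [1, 1, 1]
        tb, eb = [4, 5, 6], [1, 1, 1]
        res = logrank_test(recs(ta, ea, "a"), recs(tb, eb, "b"))
        stat, p = brute_force_logrank(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(stat, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_data_with_ties(self, seed):
        r = np.random.default_rng(seed)
        ta = r.integers(1, 8, 12).astype(float)  # integer times force ties
        tb = r.integers(1, 8, 15).astype(float)
        ea = r.random(12) < 0.7
        eb = r.random(15) < 0.7
        if not (ea.any() or eb.any()):
            ea[0] = True
        res = logrank_test(recs(ta, ea, "a"), recs(tb, eb, "b"))
        stat, p = brute_force_logrank(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(stat, rel=1e-6, abs=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_symmetry(self):
        a, b = recs([1, 3, 5], [1, 0, 1], "a"), recs([2, 4], [1, 1], "b")
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_single_event_minimal_instance(self):
        res = logrank_test(recs([1], [1], "a"), recs([5, 6], [0, 0], "b"))
        assert np.isfinite(res.statistic)

    def test_errors(self):
        with pytest.raises(DataError, match="non-empty"):
            logrank_test([], recs([1], [1]))
        with pytest.raises(DataError, match="no observed events"):
            logrank_test(recs([1], [0], "a"), recs([2], [0], "b"))


class TestKMCurve:
    def test_three_uncensored_events(self):
        curve = km_curve(recs([1, 2, 3], [1, 1, 1]))
        assert curve(1) == pytest.approx(2 / 3)
        assert curve(2) == pytest.approx(1 / 3)
        assert curve(3) == pytest.approx(0.0)
        assert curve(0.5) == 1.0

    def test_censoring_shrinks_risk_set(self):
        curve = km_curve(recs([1, 2], [0, 1]))
        assert curve(1.5) == 1.0
        assert curve(2) == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        curve = km_curve(recs([1, 2, 3], [0, 0, 0]))
        for t in (0, 1, 2, 3, 10):
            assert curve(t) == 1.0

    def test_total_drops_equal_event_count(self):
        r = np.random.default_rng(3)
        times = r.exponential(10, 20)
        events = np.ones(20, bool)  # no censoring
        curve = km_curve(recs(times, events))
        drops = np.count_nonzero(np.diff(np.concatenate([[1.0], curve.survival])))
        assert drops == 20
        assert curve.survival[-1] == pytest.approx(0.0)


class TestToMonths:
    @pytest.mark.parametrize(
        "time,unit,expected",
        [(0, "days", 0.0), (365.25, "days", 12.0), (2, "years", 24.0), (7.5, "months", 7.5)],
    )
    def test_conversions(self, time, unit, expected):
        assert to_months(time, unit) == pytest.approx(expected)

    def test_negative_time(self):
        with pytest.raises(DataError, match="negative"):
            to_months(-1, "days")


class TestOptimalSplit:
    def cohort_with_fraction_effect(self, n, seed, log_hr=3.0):
        r = np.random.default_rng(seed)
        frac = r.uniform(0, 1, n)
        times = r.exponential(1.0 / (0.05 * np.exp(log_hr * frac)))
        events = r.random(n) < 0.85
        if not events.any():
            events[0] = True
        return frac, recs(times, events)

    def test_n4_counts_three_cuts(self):
        frac = np.array([0.9, 0.5, 0.3, 0.1])
        cohort = recs([1, 2, 3, 4], [1, 1, 1, 1])
        res = optimal_split(frac, cohort, min_group=1)
        assert res.all_p.shape == (3,)
        assert list(res.tested_cuts) == [1, 2, 3]

    def test_optimised_p_is_min_of_all_p(self):
        frac, cohort = self.cohort_with_fraction_effect(30, 0)
        res = optimal_split(frac, cohort, alpha=1.0)  # always optimised
        assert res.strategy == "optimised"
        assert res.p_value == res.all_p.min()
        assert res.cut_rank == res.tested_cuts[int(np.argmin(res.all_p))]

    def test_matches_exhaustive_oracle(self):
        """Chosen cut equals a literal loop over all 29 cuts, 20 cohorts."""
        for seed in range(20):
            frac, cohort = self.cohort_with_fraction_effect(30, seed)
            res = optimal_split(frac, cohort)
            order = np.lexsort((np.array([r.sample_id for r in cohort], dtype=object), -frac))
            srt = [cohort[i] for i in order]
            oracle_p = []
            for k in range(1, 30):
                try:
                    oracle_p.append(logrank_test(srt[:k], srt[k:]).p_value)
                except DataError:
                    oracle_p.append(1.0)
            oracle_p = np.array(oracle_p)
            np.testing.assert_allclose(res.all_p, oracle_p, rtol=1e-10)
            if res.strategy == "optimised":
                assert res.cut_rank == 1 + int(np.argmin(oracle_p))
            assert (res.strategy == "median") == (oracle_p.min() > 0.05)

    def test_median_fallback_group_sizes(self):
        """alpha below any attainable p forces the printed fallback rule."""
        frac, cohort = self.cohort_with_fraction_effect(21, 1)
        res = optimal_split(frac, cohort, alpha=1e-300)
        assert res.strategy == "median"
        sizes = sorted(
            [sum(1 for v in res.group_assignment.values() if v == g) for g in ("high", "low")]
        )
        assert sizes == [10, 11]

    def test_high_group_holds_largest_fractions(self):
        frac, cohort = self.cohort_with_fraction_effect(20, 2)
        res = optimal_split(frac, cohort, alpha=1.0)
        by_id = dict(zip([r.sample_id for r in cohort], frac))
        highs = [by_id[s] for s, g in res.group_assignment.items() if g == "high"]
        lows = [by_id[s] for s, g in res.group_assignment.items() if g == "low"]
        assert min(highs) >= max(lows)

    def test_identical_fractions_fall_back_to_median(self):
        _, cohort = self.cohort_with_fraction_effect(10, 3)
        res = optimal_split(np.full(10, 0.5), cohort)
        assert res.strategy == "median"
        assert res.tie_at_cut

    def test_length_mismatch(self):
        _, cohort = self.cohort_with_fraction_effect(10, 4)
        with pytest.raises(DataError, match="lengths do not match"):
            optimal_split(np.ones(9), cohort)

    def test_planted_hazard_jump_found(self, small_atlas):
        """A strong fraction-linked hazard yields a significant optimised split."""
        _, frac, cohort = make_cohort(
            CohortSpec(n_patients=60, effect_type="type_0",
                       log_hazard_ratio_per_unit_fraction=3.0,
                       censoring_rate=0.1, seed=11),
            small_atlas,
        )
        res = optimal_split(frac["type_0"].to_numpy(), cohort)
        assert res.strategy == "optimised"
        assert res.p_value < 0.05
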