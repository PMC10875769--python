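import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenosearch.outcomes_stats import (
    Make90Outcome,
    chi_square_2x2,
    cumulative_incidence,
    derive_make90,
    derive_make90_table,
    logrank_test,
    mann_whitney_u,
    risk_ratio,
    smd_profile,
)
from phenosearch.synthetic_cohort import SyntheticConfig, simulate_cohort


def record(**kwargs):
    base = {
        "death_day": None,
        "pre_aki_egfr": 80.0,
        "egfr_day90": None,
        "rrt_through_day28": False,
        "rrt_at_day90": False,
    }
    base.update(kwargs)
    return base


class TestDeriveMake90:
    def test_death_only(self):
        out = derive_make90(record(death_day=12))
        assert out == Make90Outcome(True, 12, frozenset({"death"}))

    def test_egfr_drop_over_25pct(self):
        out = derive_make90(record(egfr_day90=58.0, pre_aki_egfr=80.0))  # 27.5% drop
        assert out.event and out.event_day == 90 and out.components == {"egfr_drop"}

    def test_exact_25pct_drop_is_no_event(self):
        out = derive_make90(record(egfr_day90=60.0, pre_aki_egfr=80.0))
        assert not out.event
        assert out.event_day == 90

    def test_rrt_through_day28_timed_at_28(self):
        out = derive_make90(record(rrt_through_day28=True))
        assert out.event and out.event_day == 28 and out.components == {"rrt"}

    def test_earliest_component_wins(self):
        out = derive_make90(record(death_day=40, rrt_through_day28=True))
        assert out.event_day == 28 and out.components == {"death", "rrt"}

    def test_nonpositive_pre_aki_egfr_errors(self):
        with pytest.raises(ValueError, match="pre_aki_egfr"):
            derive_make90(record(egfr_day90=50.0, pre_aki_egfr=0.0))

    def test_table_matches_rowwise(self):
        cohort, _ = simulate_cohort(SyntheticConfig(n_patients=150, seed=9))
        table = derive_make90_table(cohort)
        for i, row in cohort.data.iterrows():
            single = derive_make90(row)
            assert single.event == table.loc[i, "event"]
            assert single.event_day == table.loc[i, "event_day"]

    def test_composite_equals_or_of_components(self):
        cohort, _ = simulate_cohort(SyntheticConfig(n_patients=400, seed=2))
        table = derive_make90_table(cohort)
        components_or = table[["death", "egfr_drop", "rrt"]].any(axis=1)
        assert (table["event"] == components_or).all()


class TestCumulativeIncidence:
    def test_no_censoring_identity(self):
        out = pd.DataFrame({"event": [True] * 4 + [False] * 6, "event_day": [10, 20, 30, 40] + [90] * 6})
        assert cumulative_incidence(out, 90) == pytest.approx(0.4)

    def test_zero_events(self):
        out = pd.DataFrame({"event": [False] * 5, "event_day": [90] * 5})
        assert cumulative_incidence(out, 90) == 0.0

    def test_staggered_censoring_hand_km(self):
        # deaths at 2, 5, 8; censorings at 4, 5, 9
        # S(90) = (5/6) * (3/4) * (1/2) = 5/16, so CI = 11/16
        out = pd.DataFrame(
            {
                "event": [True, False, True, False, True, False],
                "event_day": [2, 4, 5, 5, 8, 9],
            }
        )
        assert cumulative_incidence(out, 90) == pytest.approx(11 / 16)

    def test_non_decreasing_in_day(self):
        cohort, _ = simulate_cohort(SyntheticConfig(n_patients=200, seed=4))
        out = derive_make90_table(cohort)
        values = [cumulative_incidence(out, d) for d in range(1, 91, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cumulative_incidence(pd.DataFrame({"event": [], "event_day": []}), 90)


def _logrank_statistic_arrays(times, events, group):
    """Independent scalar-loop log-rank oracle (no shared code with the impl)."""
    o_minus_e, var = 0.0, 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        n1 = sum(1 for tt, g in zip(times, group) if g == 0 and tt >= t)
        n2 = sum(1 for tt, g in zip(times, group) if g == 1 and tt >= t)
        d1 = sum(1 for tt, e, g in zip(times, events, group) if g == 0 and e and tt == t)
        d2 = sum(1 for tt, e, g in zip(times, events, group) if g == 1 and e and tt == t)
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def _permutation_pvalue(times, events, n_a):
    """Exact permutation p for the log-rank statistic over all group assignments."""
    n = len(times)
    observed = _logrank_statistic_arrays(times, events, [0] * n_a + [1] * (n - n_a))
    count = total = 0
    for combo in itertools.combinations(range(n), n_a):
        group = [0 if i in combo else 1 for i in range(n)]
        stat = _logrank_statistic_arrays(times, events, group)
        count += stat >= observed - 1e-12
        total += 1
    return count / total, observed


def frame(times, events):
    return pd.DataFrame({"event": events, "event_day": times})


class TestLogrank:
    def test_identical_groups(self):
        a = frame([5, 10, 15], [True, True, False])
        res = logrank_test(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_vs_permutation_oracle(self):
        times = [5, 10, 15, 20, 25, 30]
        events = [True] * 6
        p_perm, stat = _permutation_pvalue(times, events, 3)
        res = logrank_test(frame(times[:3], events[:3]), frame(times[3:], events[3:]))
        assert res.statistic == pytest.approx(stat)
        assert p_perm == pytest.approx(2 / 20)
        assert abs(res.p_value - p_perm) < 0.1  # chi-square vs 20-point enumeration

    def test_single_event_closed_form(self):
        # one event in group A at t=5; both groups fully at risk there
        a = frame([5, 90], [True, False])
        b = frame([90, 90], [False, False])
        res = logrank_test(a, b)
        # o=1, e=2/4, var = 1*(2/4)*(2/4)*(3/3) = 0.25 -> stat = (0.5^2)/0.25 = 1
        assert res.statistic == pytest.approx(1.0)

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        a = frame(rng.integers(1, 91, 30), rng.random(30) < 0.6)
        b = frame(rng.integers(1, 91, 25), rng.random(25) < 0.4)
        r1 = logrank_test(a, b)
        r2 = logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(3)
        for _ in range(5):
            ta, tb = rng.integers(1, 91, 40), rng.integers(1, 91, 35)
            ea, eb = rng.random(40) < 0.5, rng.random(35) < 0.5
            if not (ea.any() or eb.any()):
                continue
            mine = logrank_test(frame(ta, ea), frame(tb, eb))
            ref = ll(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert mine.statistic == pytest.approx(ref.test_statistic)
            assert mine.p_value == pytest.approx(ref.p_value)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test(frame([], []), frame([5], [True]))

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test(frame([90], [False]), frame([90], [False]))


class TestSimpleStats:
    def test_risk_ratio_arithmetic(self):
        assert float(risk_ratio(4, 10, 5, 10)) == pytest.approx(0.8)

    def test_risk_ratio_undefined_flagged(self):
        rr = risk_ratio(3, 10, 0, 10)
        assert not rr.defined
        assert np.isnan(float(rr))

    def test_risk_ratio_identity(self):
        for a, n in [(1, 4), (3, 7), (5, 5)]:
            assert float(risk_ratio(a, n, a, n)) == pytest.approx(1.0)

    def test_risk_ratio_zero_group_errors(self):
        with pytest.raises(ValueError):
            risk_ratio(1, 0, 1, 10)

    def test_chi_square_table1_cell(self):
        # composite-event counts 66/122 (active) vs 80/118 (placebo)
        p = chi_square_2x2([[66, 122 - 66], [80, 118 - 80]])
        assert p < 0.05
        expected = stats.chi2_contingency([[66, 56], [80, 38]], correction=False).pvalue
        assert p == pytest.approx(expected)

    def test_chi_square_rejects_negative(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1, -2], [3, 4]])

    def test_mann_whitney_matches_scipy(self):
        x, y = [1.0, 2.0, 5.0, 7.0], [3.0, 4.0, 8.0, 9.0, 10.0]
        assert mann_whitney_u(x, y) == pytest.approx(
            stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        )


class TestSmd:
    def test_group_mean_equals_cohort_mean(self):
        m = pd.DataFrame({"v": [1.0, 2.0, 1.0, 2.0]})
        smd = smd_profile(m, [1, 1, 2, 2])
        assert smd.loc[1, "v"] == pytest.approx(0.0)
        assert smd.loc[2, "v"] == pytest.approx(0.0)

    def test_equal_groups_opposite_sign(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({"v": rng.normal(size=40), "w": rng.normal(size=40)})
        labels = [1] * 20 + [2] * 20
        smd = smd_profile(m, labels)
        assert smd.loc[1].to_numpy() == pytest.approx(-smd.loc[2].to_numpy())

    def test_hand_computed_example(self):
        # values 0, 2, 4, 6: mean 3, sd (ddof=1) = sqrt(20/3)
        m = pd.DataFrame({"v": [0.0, 2.0, 4.0, 6.0]})
        smd = smd_profile(m, [1, 1, 2, 2])
        sd = np.sqrt(20 / 3)
        assert smd.loc[1, "v"] == pytest.approx((1 - 3) / sd)
        assert smd.loc[2, "v"] == pytest.approx((5 - 3) / sd)

    def test_zero_sd_errors(self):
        m = pd.DataFrame({"v": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero cohort SD"):
            smd_profile(m, [1, 1, 2, 2])
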