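"""Failure estimators: hand-worked examples, invariants, and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nibench import (
    AllSubjectsDeadError,
    Dgp,
    EventType,
    build_risk_table,
    estimate_cif,
    estimate_km_failure,
    estimate_proportion,
    generate_cohort,
)

from .conftest import scenario
from .helpers import (
    CENSOR,
    DEATH,
    FAIL,
    all_cause_km_brute,
    cif_brute,
    km_failure_brute,
    make_cohort,
    random_cohort,
)

Z975 = stats.norm.ppf(0.975)


class TestProportion:
    def test_wald_interval_hand_example(self):
        cohort = make_cohort([(2.0, FAIL)] * 5 + [(10.0, CENSOR)] * 95)
        est = estimate_proportion(cohort)
        se = np.sqrt(0.05 * 0.95 / 100)
        assert est.point == pytest.approx(0.05)
        assert est.ci_lower == pytest.approx(0.05 - Z975 * se)
        assert est.ci_upper == pytest.approx(0.05 + Z975 * se)
        assert not est.degenerate

    def test_deaths_removed_from_denominator(self):
        cohort = make_cohort(
            [(1.0, FAIL)] * 10 + [(2.0, DEATH)] * 10 + [(10.0, CENSOR)] * 80
        )
        assert estimate_proportion(cohort).point == pytest.approx(10 / 90)

    def test_all_failures_gives_point_one_zero_width(self):
        est = estimate_proportion(make_cohort([(1.0, FAIL)] * 20))
        assert est.point == 1.0 and est.ci_lower == 1.0 and est.ci_upper == 1.0
        assert not est.degenerate

    def test_zero_failures_flagged_degenerate(self):
        est = estimate_proportion(make_cohort([(10.0, CENSOR)] * 30))
        assert est.point == 0.0 and est.degenerate

    def test_all_dead_is_undefined(self):
        with pytest.raises(AllSubjectsDeadError):
            estimate_proportion(make_cohort([(1.0, DEATH)] * 5))


class TestRiskTable:
    def test_hand_constructed_counts(self):
        cohort = make_cohort([(1.0, FAIL), (10.0, CENSOR), (2.0, FAIL), (10.0, CENSOR)])
        table = build_risk_table(cohort)
        np.testing.assert_array_equal(table.time, [1.0, 2.0, 10.0])
        np.testing.assert_array_equal(table.n_risk, [4, 3, 2])
        np.testing.assert_array_equal(table.n_failure, [1, 1, 0])
        np.testing.assert_array_equal(table.n_censor, [0, 0, 2])

    def test_counts_telescope_to_zero(self, rng):
        cohort = random_cohort(rng, 40)
        t = build_risk_table(cohort)
        np.testing.assert_array_equal(
            t.n_risk[1:], t.n_risk[:-1] - t.n_failure[:-1] - t.n_death[:-1] - t.n_censor[:-1]
        )
        assert t.n_risk[-1] - t.n_failure[-1] - t.n_death[-1] - t.n_censor[-1] == 0
        assert (t.n_failure + t.n_death + t.n_censor).sum() == len(cohort)

    def test_event_free_cohort_is_single_censoring_row(self):
        table = build_risk_table(make_cohort([(10.0, CENSOR)] * 6))
        assert table.time.tolist() == [10.0] and table.n_censor.tolist() == [6]

    def test_non_positive_times_rejected(self):
        with pytest.raises(ValueError):
            make_cohort([(0.0, FAIL)])


class TestKaplanMeier:
    def test_hand_product_with_interleaved_censoring(self):
        # S = (3/4) * (1/2) = 0.375 -> failure 0.625
        cohort = make_cohort([(1.0, FAIL), (1.5, CENSOR), (2.0, FAIL), (10.0, CENSOR)])
        est = estimate_km_failure(cohort)
        assert est.point == pytest.approx(0.625)
        assert 0.0 <= est.ci_lower <= est.point <= est.ci_upper <= 1.0

    def test_reduces_to_proportion_when_fully_observed(self, rng):
        events = np.where(rng.uniform(size=80) < 0.3, FAIL, CENSOR)
        pairs = [
            (rng.uniform(0.1, 9.9) if e == FAIL else 10.0, e) for e in events
        ]
        cohort = make_cohort(pairs)
        assert estimate_km_failure(cohort).point == pytest.approx(
            estimate_proportion(cohort).point
        )

    def test_zero_failures_degenerate(self):
        est = estimate_km_failure(make_cohort([(3.0, DEATH), (10.0, CENSOR)]))
        assert est.point == 0.0 and (est.ci_lower, est.ci_upper) == (0.0, 0.0)
        assert est.degenerate

    def test_all_failed_reaches_one(self):
        est = estimate_km_failure(make_cohort([(1.0, FAIL), (2.0, FAIL), (3.0, FAIL)]))
        assert est.point == 1.0 and est.ci_width == 0.0

    def test_invariant_to_moving_censoring_between_event_times(self):
        base = [(1.0, FAIL), (3.0, FAIL), (6.0, FAIL), (10.0, CENSOR)]
        a = estimate_km_failure(make_cohort(base + [(2.0, CENSOR)]))
        b = estimate_km_failure(make_cohort(base + [(2.9, CENSOR)]))
        assert a.point == pytest.approx(b.point)
        assert a.ci_upper == pytest.approx(b.ci_upper)

    def test_matches_lifelines_point_and_cloglog_interval(self):
        lifelines = pytest.importorskip("lifelines")
        cohort = generate_cohort(scenario(400, Dgp.CR, reps=1, seed=77))
        est = estimate_km_failure(cohort)
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit(cohort.time, event_observed=cohort.event == EventType.FAILURE)
        s = float(kmf.survival_function_at_times(cohort.horizon).iloc[0])
        assert est.point == pytest.approx(1.0 - s, abs=1e-12)
        ci = kmf.confidence_interval_.iloc[-1]
        assert est.ci_lower == pytest.approx(1.0 - float(ci.max()), abs=1e-9)
        assert est.ci_upper == pytest.approx(1.0 - float(ci.min()), abs=1e-9)


class TestCif:
    def test_hand_stepwise_sum(self):
        # 1*(1/4) at t=1, death at t=2, then S_all(2)=0.5 and 0.5*(1/2) at t=3
        cohort = make_cohort([(1.0, FAIL), (2.0, DEATH), (3.0, FAIL), (10.0, CENSOR)])
        est = estimate_cif(cohort)
        assert est.point == pytest.approx(0.50)

    def test_equals_km_without_deaths(self, rng):
        cohort = random_cohort(rng, 60)
        cohort.event[cohort.event == DEATH] = CENSOR
        km = estimate_km_failure(cohort)
        cif = estimate_cif(cohort)
        assert cif.point == pytest.approx(km.point, abs=1e-12)

    def test_zero_failures_degenerate(self):
        est = estimate_cif(make_cohort([(3.0, DEATH), (10.0, CENSOR)]))
        assert est.degenerate and est.point == 0.0

    def test_matches_lifelines_aalen_johansen_point(self):
        lifelines = pytest.importorskip("lifelines")
        cohort = generate_cohort(scenario(400, Dgp.CR, reps=1, seed=78))
        est = estimate_cif(cohort)
        ajf = lifelines.AalenJohansenFitter(calculate_variance=False, seed=1)
        ajf.fit(cohort.time, cohort.event, event_of_interest=int(EventType.FAILURE))
        point = float(ajf.cumulative_density_.iloc[-1, 0])
        # lifelines jitters tied times, so agreement is near-exact, not exact
        assert est.point == pytest.approx(point, abs=1e-6)


class TestCrossEstimatorInvariants:
    def test_all_three_identical_on_fully_observed_cohorts(self, rng):
        """With no deaths and no pre-horizon censoring the estimand collapses."""
        for _ in range(20):
            n = rng.integers(5, 40)
            events = np.where(rng.uniform(size=n) < 0.4, FAIL, CENSOR)
            pairs = [
                (float(rng.uniform(0.1, 9.9)) if e == FAIL else 10.0, int(e))
                for e in events
            ]
            cohort = make_cohort(pairs)
            p = estimate_proportion(cohort).point
            assert estimate_km_failure(cohort).point == pytest.approx(p, abs=1e-12)
            assert estimate_cif(cohort).point == pytest.approx(p, abs=1e-12)

    def test_cif_additivity_and_crude_below_net(self, rng):
        for _ in range(30):
            cohort = random_cohort(rng, int(rng.integers(8, 50)))
            if not (cohort.event == FAIL).any() or not (cohort.event == DEATH).any():
                continue
            cif_f = estimate_cif(cohort, EventType.FAILURE).point
            cif_d = estimate_cif(cohort, EventType.DEATH).point
            s_all = all_cause_km_brute(cohort)
            assert cif_f + cif_d == pytest.approx(1.0 - s_all, abs=1e-10)
            # crude failure cannot exceed net failure when deaths censor
            assert cif_f <= estimate_km_failure(cohort).point + 1e-10

    def test_brute_force_oracle_equivalence_on_random_small_cohorts(self):
        """KM and CIF match an independent raw-times reimplementation, 200 draws."""
        rng = np.random.default_rng(314)
        checked = 0
        while checked < 200:
            cohort = random_cohort(rng, int(rng.integers(3, 31)))
            if not (cohort.event == FAIL).any():
                continue
            km = estimate_km_failure(cohort).point
            cif = estimate_cif(cohort).point
            assert km == pytest.approx(km_failure_brute(cohort), abs=1e-10)
            assert cif == pytest.approx(cif_brute(cohort), abs=1e-10)
            checked += 1


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2 ** 20), n=st.integers(2, 60))
def test_interval_ordering_property(seed, n):
    """All estimators keep 0 <= lower <= point <= upper <= 1 on arbitrary cohorts."""
    cohort = random_cohort(np.random.default_rng(seed), n)
    estimates = [estimate_km_failure(cohort), estimate_cif(cohort)]
    if (cohort.event != DEATH).any():
        estimates.append(estimate_proportion(cohort))
    for est in estimates:
        assert 0.0 <= est.ci_lower <= est.point <= est.ci_upper <= 1.0
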