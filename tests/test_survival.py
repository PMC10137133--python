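import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nccborrow import (
    DegenerateCovariateError,
    brute_force_fit,
    brute_force_loglik,
    cox_fit,
    cox_loglik,
    cox_score_test,
    km_fit,
    logrank_test,
    risk_set,
    wald_summary,
)
from nccborrow.survival import Z95


class TestRiskSet:
    def test_all_present(self, km_records):
        assert risk_set(km_records, 2.0) == {0, 1, 2}

    def test_entry_boundary_strict(self, km_records):
        # r2 has entry 1: at t=1 the condition t > L fails
        assert risk_set(km_records, 1.0) == {0, 2}

    def test_not_yet_entered(self, km_records):
        assert risk_set(km_records, 0.5) == {0, 2}

    def test_exit_boundary_inclusive(self, km_records):
        assert 0 in risk_set(km_records, 2.0)
        assert 0 not in risk_set(km_records, 2.0 + 1e-9)

    def test_nonpositive_time(self, km_records):
        with pytest.raises(ValueError):
            risk_set(km_records, 0.0)


class TestKaplanMeier:
    def test_hand_example(self, km_records):
        est = km_fit(km_records)
        assert est.event_times.tolist() == [2.0, 3.0]
        assert est.survival == pytest.approx([2 / 3, 1 / 3])
        assert est.at_risk.tolist() == [3, 2]
        assert est.events.tolist() == [1, 1]

    def test_greenwood_variance(self, km_records):
        est = km_fit(km_records)
        assert est.variance[1] == pytest.approx(2 / 27)

    def test_all_censored(self, record_factory):
        recs = [record_factory(i, 0, 0.0, t, False) for i, t in enumerate([1.0, 2.0, 3.0])]
        est = km_fit(recs)
        assert len(est.event_times) == 0
        assert est.survival_at(2.5) == 1.0

    def test_survival_at_steps(self, km_records):
        est = km_fit(km_records)
        assert est.survival_at(1.9) == 1.0
        assert est.survival_at(2.0) == pytest.approx(2 / 3)
        assert est.survival_at(10.0) == pytest.approx(1 / 3)

    def test_reduces_to_textbook_km_without_truncation(self, record_factory):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        exit_ = rng.uniform(0.1, 5.0, 60)
        event = rng.random(60) < 0.6
        recs = [record_factory(i, 0, 0.0, exit_[i], bool(event[i])) for i in range(60)]
        est = km_fit(recs)
        ref = KaplanMeierFitter().fit(exit_, event)
        expected = ref.survival_function_at_times(est.event_times).to_numpy()
        np.testing.assert_allclose(est.survival, expected, atol=1e-12)

    def test_delayed_entry_matches_lifelines(self, record_factory):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        entry = np.where(rng.random(80) < 0.5, 0.0, rng.uniform(0, 2, 80))
        exit_ = entry + rng.uniform(0.1, 5.0, 80)
        event = rng.random(80) < 0.7
        recs = [
            record_factory(i, 0, entry[i], exit_[i], bool(event[i])) for i in range(80)
        ]
        est = km_fit(recs)
        ref = KaplanMeierFitter().fit(exit_, event, entry=entry)
        expected = ref.survival_function_at_times(est.event_times).to_numpy()
        np.testing.assert_allclose(est.survival, expected, atol=1e-12)

    def test_monotone_and_bounded(self, record_factory):
        rng = np.random.default_rng(4)
        recs = [
            record_factory(i, 0, e, e + d, bool(ev))
            for i, (e, d, ev) in enumerate(
                zip(rng.uniform(0, 1, 50), rng.uniform(0.1, 4, 50), rng.random(50) < 0.8)
            )
        ]
        est = km_fit(recs)
        assert np.all(np.diff(est.survival) <= 1e-15)
        assert np.all((est.survival >= 0) & (est.survival <= 1))
        assert np.all(est.at_risk >= est.events)
        assert np.all(est.events >= 1)
        assert np.all(est.ci_lower <= est.survival + 1e-12)
        assert np.all(est.ci_upper >= est.survival - 1e-12)

    def test_linear_ci_selectable(self, km_records):
        est = km_fit(km_records, ci_method="linear")
        assert est.ci_lower[0] == pytest.approx(max(0.0, 2 / 3 - Z95 * math.sqrt(est.variance[0])))

    def test_empty_input(self):
        with pytest.raises(ValueError):
            km_fit([])

    def test_accepts_dataframe(self, km_records):
        frame = pd.DataFrame(
            {
                "entry": [r.entry for r in km_records],
                "exit": [r.exit for r in km_records],
                "event": [r.event for r in km_records],
                "group": [r.group for r in km_records],
            }
        )
        assert km_fit(frame).survival == pytest.approx([2 / 3, 1 / 3])


class TestCoxLoglik:
    def test_beta_zero_value(self, cox4):
        assert cox_loglik(cox4, 0.0) == pytest.approx(-math.log(24), abs=1e-12)

    def test_single_record(self, record_factory):
        assert cox_loglik([record_factory("a", 1, 0.0, 1.0, True)], 0.0) == 0.0

    def test_matches_brute_force(self, random_instance):
        rng = np.random.default_rng(17)
        for _ in range(25):
            recs = random_instance(rng)
            for beta in (-1.0, 0.0, 0.7):
                assert cox_loglik(recs, beta) == pytest.approx(
                    brute_force_loglik(recs, beta), abs=1e-12
                )

    def test_breslow_matches_brute_force_with_ties(self, record_factory):
        recs = [
            record_factory("a", 1, 0.0, 1.0, True),
            record_factory("b", 0, 0.0, 1.0, True),  # tied event times
            record_factory("c", 1, 0.0, 2.0, True),
            record_factory("d", 0, 0.0, 3.0, False),
        ]
        for ties in ("breslow", "efron"):
            assert cox_loglik(recs, 0.4, ties=ties) == pytest.approx(
                brute_force_loglik(recs, 0.4, ties=ties), abs=1e-12
            )


class TestCoxFit:
    def test_closed_form_solution(self, cox4):
        # score equation reduces to u^2 - u - 4 = 0 with u = exp(beta)
        fit = cox_fit(cox4)
        assert fit.beta == pytest.approx(math.log((1 + math.sqrt(17)) / 2), abs=1e-7)
        assert fit.hr == pytest.approx((1 + math.sqrt(17)) / 2, abs=1e-6)
        assert fit.converged

    def test_closed_form_with_delayed_entry(self, cox4_delayed):
        # score equation reduces to 2u^3 - 7u - 4 = 0
        root = [r.real for r in np.roots([2, 0, -7, -4]) if abs(r.imag) < 1e-12 and r.real > 0][0]
        fit = cox_fit(cox4_delayed)
        assert fit.beta == pytest.approx(math.log(root), abs=1e-7)

    def test_label_flip_symmetry(self, cox4, record_factory):
        flipped = [
            record_factory(r.id, 1 - r.group, r.entry, r.exit, r.event) for r in cox4
        ]
        f1, f2 = cox_fit(cox4), cox_fit(flipped)
        assert f2.beta == pytest.approx(-f1.beta, abs=1e-9)
        assert f2.se == pytest.approx(f1.se, abs=1e-9)

    def test_score_is_zero_at_optimum(self, random_instance):
        rng = np.random.default_rng(23)
        for _ in range(20):
            recs = random_instance(rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = cox_fit(recs)
            except DegenerateCovariateError:
                continue
            if fit.converged:
                eps = 1e-6
                deriv = (cox_loglik(recs, fit.beta + eps) - cox_loglik(recs, fit.beta - eps)) / (2 * eps)
                assert abs(deriv) < 1e-4

    def test_degenerate_covariate(self, record_factory):
        recs = [record_factory(i, 0, 0.0, float(i + 1), True) for i in range(4)]
        with pytest.raises(DegenerateCovariateError):
            cox_fit(recs)

    def test_monotone_likelihood_flagged(self, record_factory):
        # all treated events strictly precede all control events
        recs = [
            record_factory("a", 1, 0.0, 1.0, True),
            record_factory("b", 1, 0.0, 2.0, True),
            record_factory("c", 0, 0.0, 3.0, True),
            record_factory("d", 0, 0.0, 4.0, True),
        ]
        with pytest.warns(UserWarning, match="monotone"):
            fit = cox_fit(recs)
        assert not fit.converged
        assert abs(fit.beta) > 15

    def test_matches_lifelines(self, record_factory):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 120
        entry = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(0, 2, n))
        exit_ = entry + rng.uniform(0.1, 5, n)
        event = rng.random(n) < 0.7
        x = (rng.random(n) < 0.5).astype(int)
        recs = [
            record_factory(i, int(x[i]), entry[i], exit_[i], bool(event[i]))
            for i in range(n)
        ]
        fit = cox_fit(recs)
        df = pd.DataFrame({"entry": entry, "exit": exit_, "event": event.astype(int), "group": x})
        ref = CoxPHFitter().fit(
            df, duration_col="exit", event_col="event", entry_col="entry", formula="group"
        )
        assert fit.beta == pytest.approx(float(ref.params_["group"]), abs=1e-6)
        assert fit.se == pytest.approx(float(ref.standard_errors_["group"]), abs=1e-6)

    def test_newton_agrees_with_grid_search(self, random_instance):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 20:
            recs = random_instance(rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = cox_fit(recs)
            except DegenerateCovariateError:
                continue
            if not fit.converged:
                continue
            assert abs(fit.beta - brute_force_fit(recs)) < 1e-4
            checked += 1


class TestWaldSummary:
    def test_pooled_control_row(self):
        # printed point estimate 0.744 with SE 0.131 implies p ~ 0.024, upper CI ~ 0.962
        hr, ci, p = wald_summary(math.log(0.744), 0.131)
        assert round(p, 3) == 0.024
        assert round(ci[1], 3) == 0.962
        assert abs(ci[0] - 0.575) < 0.0015  # printed 0.575 comes from unrounded inputs

    def test_cc_row_with_rounding_caveat(self):
        hr, ci, p = wald_summary(math.log(0.755), 0.147)
        assert 0.056 <= round(p, 3) <= 0.057
        assert round(ci[0], 3) == 0.566
        assert abs(ci[1] - 1.008) < 0.0015  # printed value comes from unrounded inputs

    def test_null_beta(self):
        hr, ci, p = wald_summary(0.0, 0.5)
        assert hr == 1.0 and p == pytest.approx(1.0)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            wald_summary(0.1, 0.0)

    def test_ci_consistency(self):
        hr, ci, p = wald_summary(0.3, 0.1)
        assert hr == pytest.approx(math.exp(0.3))
        assert ci[0] == pytest.approx(math.exp(0.3 - Z95 * 0.1))
        assert ci[1] == pytest.approx(math.exp(0.3 + Z95 * 0.1))


class TestLogRank:
    def test_two_record_toy(self, record_factory):
        recs = [record_factory("a", 0, 0.0, 1.0, True), record_factory("b", 0, 0.0, 2.0, True)]
        res = logrank_test(recs, ["A", "B"])
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(0.3173, abs=1e-4)
        assert res.observed["A"] == 1.0 and res.expected["A"] == pytest.approx(0.5)

    def test_duplicated_groups_give_zero(self, record_factory):
        base = [record_factory(i, 0, 0.0, float(i + 1), True) for i in range(6)]
        dup = [record_factory(f"d{i}", 0, 0.0, float(i + 1), True) for i in range(6)]
        res = logrank_test(base + dup, ["A"] * 6 + ["B"] * 6)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_no_events_flagged(self, record_factory):
        recs = [record_factory("a", 0, 0.0, 1.0, False), record_factory("b", 0, 0.0, 2.0, False)]
        res = logrank_test(recs, ["A", "B"])
        assert not res.valid and res.p == 1.0

    def test_needs_two_groups(self, record_factory):
        recs = [record_factory("a", 0, 0.0, 1.0, True)]
        with pytest.raises(ValueError):
            logrank_test(recs, ["A"])

    def test_equals_cox_score_test(self, random_instance):
        rng = np.random.default_rng(41)
        for _ in range(10):
            recs = random_instance(rng, n_max=15)
            stat, _ = cox_score_test(recs, ties="breslow")
            res = logrank_test(recs)
            assert stat == pytest.approx(res.statistic, abs=1e-8)


class TestBruteForce:
    def test_beta_zero_value(self, cox4):
        assert brute_force_loglik(cox4, 0.0) == pytest.approx(-math.log(24), abs=1e-12)

    def test_fit_agrees_with_newton(self, cox4):
        assert brute_force_fit(cox4) == pytest.approx(cox_fit(cox4).beta, abs=1e-4)


@st.composite
def instances(draw):
    n = draw(st.integers(min_value=4, max_value=12))
    entries = draw(
        st.lists(st.floats(0, 2, allow_nan=False), min_size=n, max_size=n)
    )
    gaps = draw(
        st.lists(st.floats(0.05, 5, allow_nan=False), min_size=n, max_size=n)
    )
    events = draw(st.lists(st.booleans(), min_size=n, max_size=n))
    groups = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    return entries, gaps, events, groups


@given(instances(), st.floats(-2, 2, allow_nan=False))
@settings(max_examples=60, deadline=None)
def test_property_fast_loglik_equals_enumeration(instance, beta):
    from conftest import rec

    entries, gaps, events, groups = instance
    recs = [
        rec(i, groups[i], entries[i], entries[i] + gaps[i], events[i])
        for i in range(len(gaps))
    ]
    assert cox_loglik(recs, beta) == pytest.approx(
        brute_force_loglik(recs, beta), abs=1e-10
    )


@given(instances())
@settings(max_examples=40, deadline=None)
def test_property_km_bounds(instance):
    from conftest import rec

    entries, gaps, events, groups = instance
    recs = [
        rec(i, groups[i], entries[i], entries[i] + gaps[i], events[i])
        for i in range(len(gaps))
    ]
    est = km_fit(recs)
    assert np.all((est.survival >= 0) & (est.survival <= 1))
    assert np.all(np.diff(est.survival) <= 1e-15)
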