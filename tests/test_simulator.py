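"""Engine behavior: stepping rules, feedback scheduling, regret stocks,
threshold updates, and whole-run properties."""

import numpy as np
import pytest

from dynthresh.analytic import severity_cutoff, static_sensitivity, static_specificity
from dynthresh.domain import FeedbackEvent, ModelParameters, Outcome, PatientRecord
from dynthresh.simulator import (
    THRESHOLD_CLIP,
    EngineState,
    InsufficientSampleError,
    draw_patient,
    new_state,
    referral_summary,
    regret_levels,
    schedule_feedback,
    simulate,
    simulate_replicates,
    update_threshold,
)


def _record(outcome, visit=100):
    has_disorder = outcome in (Outcome.TP, Outcome.FN)
    referred = outcome in (Outcome.TP, Outcome.FP)
    return PatientRecord(visit, 0.0, 0.0, has_disorder, referred, outcome)


class TestDrawPatient:
    def test_perfect_correlation_means_perceived_equals_true(self):
        params = ModelParameters(rho=1.0)
        state = new_state(params, seed=1)
        for _ in range(200):
            rec = draw_patient(state, params)
            assert rec.perceived_severity == pytest.approx(rec.true_severity, abs=1e-12)

    def test_sampling_moments(self):
        params = ModelParameters(rho=0.65)
        state = new_state(params, seed=2)
        n = 10**5
        pairs = np.array(
            [
                (r.true_severity, r.perceived_severity, r.has_disorder)
                for r in (draw_patient(state, params) for _ in range(n))
            ]
        )
        corr = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert corr == pytest.approx(0.65, abs=0.01)
        frac = pairs[:, 2].mean()
        se = np.sqrt(0.15 * 0.85 / n)
        assert frac == pytest.approx(0.15, abs=3 * se)

    def test_missed_case_is_classified_fn(self):
        params = ModelParameters(rho=0.65)
        state = new_state(params, seed=3)
        state.threshold = 10.0  # nobody referred
        hits = 0
        for _ in range(2000):
            rec = draw_patient(state, params)
            if rec.has_disorder:
                hits += 1
                assert rec.outcome is Outcome.FN
        assert hits > 0


class TestScheduleFeedback:
    def test_certain_loss_never_generates_event(self):
        params = ModelParameters(fp_loss=1.0)
        state = new_state(params, seed=0)
        for _ in range(300):
            assert schedule_feedback(_record(Outcome.FP), state, params) is None

    def test_correct_decisions_generate_nothing(self):
        params = ModelParameters(fp_loss=0.0, fn_loss=0.0)
        state = new_state(params, seed=0)
        assert schedule_feedback(_record(Outcome.TP), state, params) is None
        assert schedule_feedback(_record(Outcome.TN), state, params) is None
        assert not state.pending

    def test_fp_revealed_after_fp_delay_with_retention_probability(self):
        params = ModelParameters(fp_loss=0.20)
        state = new_state(params, seed=5)
        events = [
            schedule_feedback(_record(Outcome.FP, visit=100), state, params)
            for _ in range(4000)
        ]
        kept = [e for e in events if e is not None]
        for e in kept:
            assert e.reveal_visit == 150  # origin + 50-visit FP delay
            assert e.error_type is Outcome.FP
        frac = len(kept) / len(events)
        se = np.sqrt(0.8 * 0.2 / len(events))
        assert frac == pytest.approx(0.80, abs=3 * se)

    def test_fn_uses_fn_delay(self):
        params = ModelParameters(fn_loss=0.0)
        state = new_state(params, seed=6)
        event = schedule_feedback(_record(Outcome.FN, visit=7), state, params)
        assert event.reveal_visit == 7 + params.fn_delay
        assert state.pending[event.reveal_visit] == [event]


class TestRegretLevels:
    def test_empty_stock(self):
        params = ModelParameters()
        state = new_state(params, seed=0)
        assert regret_levels(state, params) == (0.0, 0.0)

    def test_error_revealed_this_visit_has_full_regret(self):
        params = ModelParameters()
        state = new_state(params, seed=0)
        state.current_visit = 500
        state.known_fp = [500]
        fp, fn = regret_levels(state, params)
        assert fp == pytest.approx(1.0)
        assert fn == 0.0

    def test_linear_decay_with_weight(self):
        # one FN at half the memory window, weight 3 -> 3 * 0.5 = 1.5
        params = ModelParameters(fn_regret_weight=3.0, memory_window=100)
        state = new_state(params, seed=0)
        state.current_visit = 550
        state.known_fn = [500]
        fp, fn = regret_levels(state, params)
        assert fp == 0.0
        assert fn == pytest.approx(1.5)

    def test_memory_window_expiry(self):
        params = ModelParameters(memory_window=100)
        state = new_state(params, seed=0)
        state.known_fp = [500]
        state.current_visit = 600
        state.reveal_due(params.memory_window)
        assert state.known_fp == []


class TestUpdateThreshold:
    def _state_with_stocks(self, params, fp_visits, fn_visits, visit=1000):
        state = new_state(params, seed=0)
        state.current_visit = visit
        state.known_fp = list(fp_visits)
        state.known_fn = list(fn_visits)
        return state

    def test_balanced_regret_leaves_threshold_unchanged(self):
        params = ModelParameters(fn_regret_weight=1.0)
        state = self._state_with_stocks(params, [1000], [1000])
        before = state.threshold
        assert update_threshold(state, params) == before

    def test_fn_regret_dominance_lowers_threshold(self):
        params = ModelParameters()
        state = self._state_with_stocks(params, [], [1000])
        before = state.threshold
        assert update_threshold(state, params) < before

    def test_doubling_gain_doubles_single_step_change(self):
        p1 = ModelParameters(adjustment_gain=0.002)
        p2 = ModelParameters(adjustment_gain=0.004)
        s1 = self._state_with_stocks(p1, [1000, 990], [995])
        s2 = self._state_with_stocks(p2, [1000, 990], [995])
        t0 = s1.threshold
        delta1 = update_threshold(s1, p1) - t0
        delta2 = update_threshold(s2, p2) - t0
        assert delta1 != 0
        assert delta2 == pytest.approx(2 * delta1)

    def test_no_known_errors_is_inert(self):
        params = ModelParameters()
        state = self._state_with_stocks(params, [], [])
        before = state.threshold
        assert update_threshold(state, params) == before

    def test_threshold_clipped(self):
        params = ModelParameters(adjustment_gain=0.002)
        state = self._state_with_stocks(params, [1000], [])
        state.threshold = THRESHOLD_CLIP
        assert update_threshold(state, params) == THRESHOLD_CLIP


class TestSimulate:
    def test_same_seed_is_bit_identical(self, base_params):
        a = simulate(base_params, seed=123, n_burnin=300, n_measure=500)
        b = simulate(base_params, seed=123, n_burnin=300, n_measure=500)
        assert np.array_equal(a.threshold_trajectory, b.threshold_trajectory)
        assert np.array_equal(a.outcomes, b.outcomes)
        assert a.counts == b.counts

    def test_different_seed_differs(self, base_params):
        a = simulate(base_params, seed=1, n_burnin=300, n_measure=500)
        b = simulate(base_params, seed=2, n_burnin=300, n_measure=500)
        assert not np.array_equal(a.outcomes, b.outcomes)

    def test_conservation_and_metric_definitions(self, base_params):
        out = simulate(base_params, seed=9)
        assert out.n_tp + out.n_fp + out.n_tn + out.n_fn == out.n_measure
        assert out.sensitivity == pytest.approx(out.n_tp / (out.n_tp + out.n_fn))
        assert out.specificity == pytest.approx(out.n_tn / (out.n_tn + out.n_fp))
        assert out.referral_rate == pytest.approx(
            (out.n_tp + out.n_fp) / out.n_measure
        )
        diseased = out.n_tp + out.n_fn
        se = np.sqrt(0.15 * 0.85 / out.n_measure)
        assert diseased / out.n_measure == pytest.approx(0.15, abs=3 * se)

    @pytest.mark.parametrize(
        "threshold,rho", [(0.0, 0.3), (0.5, 0.65), (1.0, 0.85), (-0.8, 0.5)]
    )
    def test_no_feedback_limit_matches_analytic_operating_point(self, threshold, rho):
        """With all feedback lost the threshold never moves, so the run is a
        static classifier whose window metrics match the closed form."""
        params = ModelParameters(
            rho=rho, fp_loss=1.0, fn_loss=1.0, initial_threshold=threshold
        )
        out = simulate(params, seed=17)
        assert np.all(out.threshold_trajectory == threshold)
        sens = static_sensitivity(threshold, rho, 0.15)
        spec = static_specificity(threshold, rho, 0.15)
        n_dis = out.n_tp + out.n_fn
        n_heal = out.n_tn + out.n_fp
        assert out.sensitivity == pytest.approx(
            sens, abs=3 * np.sqrt(sens * (1 - sens) / n_dis)
        )
        assert out.specificity == pytest.approx(
            spec, abs=3 * np.sqrt(spec * (1 - spec) / n_heal)
        )

    def test_perfect_accuracy_yields_perfect_classification(self):
        params = ModelParameters(
            rho=1.0, initial_threshold=severity_cutoff(0.15)
        )
        out = simulate(params, seed=21)
        assert out.sensitivity == 1.0
        assert out.specificity == 1.0
        assert out.n_fp == 0 and out.n_fn == 0
        # no errors -> no regret -> the threshold never moves
        assert np.all(out.threshold_trajectory == params.initial_threshold)

    def test_insufficient_sample_raises(self):
        params = ModelParameters(prevalence=0.0001, rho=0.0)
        with pytest.raises(InsufficientSampleError):
            simulate(params, seed=3, n_burnin=10, n_measure=30)

    def test_oscillation_present_with_base_delays(self, base_params):
        out = simulate(base_params, seed=31)
        post = out.threshold_probability_trajectory[out.n_burnin:]
        assert np.var(post) > 0

    def test_regret_trajectories_nonnegative_and_weighted(self, base_params):
        out = simulate(base_params, seed=33, n_burnin=500, n_measure=1000)
        assert np.all(out.fp_regret_trajectory >= 0)
        assert np.all(out.fn_regret_trajectory >= 0)


class TestComparativeStatics:
    """Averaged over seed sets, the feedback parameters move the operating
    point in the directions the theory predicts."""

    @staticmethod
    def _means(params, seeds=10):
        runs = simulate_replicates(params, seed=50, replicates=seeds)
        return (
            np.mean([r.sensitivity for r in runs]),
            np.mean([r.specificity for r in runs]),
            np.mean([r.threshold_trajectory[r.n_burnin:].mean() for r in runs]),
        )

    def test_fn_regret_weight_lowers_threshold_and_raises_sensitivity(self):
        sens1, _, thr1 = self._means(ModelParameters(fn_regret_weight=1.0))
        sens3, _, thr3 = self._means(ModelParameters(fn_regret_weight=3.0))
        sens10, _, thr10 = self._means(ModelParameters(fn_regret_weight=10.0))
        assert sens1 < sens3 < sens10
        assert thr1 > thr3 > thr10

    def test_fn_loss_raises_threshold_and_lowers_sensitivity(self):
        sens_lo, _, thr_lo = self._means(ModelParameters(fn_loss=0.20))
        sens_hi, _, thr_hi = self._means(ModelParameters(fn_loss=0.90))
        assert sens_hi < sens_lo
        assert thr_hi > thr_lo


def test_referral_summary_identities(base_params):
    out = simulate(base_params, seed=77)
    rate, pos, among = referral_summary(out, base_params)
    assert rate == pytest.approx(out.referral_rate)
    assert among == pytest.approx(rate / pos)
    # the screen-positive denominator obeys total probability at the
    # screener's Youden point
    from dynthresh.analytic import youden_threshold

    op = youden_threshold(0.85, 0.15)
    expected = 0.15 * op.sensitivity + 0.85 * (1 - op.specificity)
    assert pos == pytest.approx(expected, abs=1e-9)
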