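"""The dynamic engine: sequential patients, delayed lossy error feedback,
linearly decaying regret stocks, and regret-driven threshold adjustment.

Time is discrete with exactly one patient per tick ("patient visits" are
the model's time unit).  Each visit proceeds in a fixed order so that a
run is bit-reproducible from its seed:

1. feedback events due this visit are revealed (so feedback can influence
   the very next decision);
2. known errors older than the memory window are forgotten;
3. regret stocks are recomputed from the remembered errors;
4. the decision threshold is adjusted in response to the regret imbalance;
5. a patient is drawn, the referral decision made and classified;
6. if the decision was an error, its future revelation is scheduled
   (or lost to follow-up).

The threshold moves by ``adjustment_gain`` times the *relative* regret
imbalance (FP regret - FN regret) / (FP regret + FN regret), a bounded
per-visit step: the direction of adjustment is set by which error type
currently dominates the physician's regret, while the step size does not
grow with the sheer volume of feedback.  Regret over false positives
pushes the threshold up (fewer referrals); regret over false negatives
pushes it down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.stats import norm

from .analytic import severity_cutoff, threshold_probability, youden_threshold
from .domain import (
    FeedbackEvent,
    ModelParameters,
    Outcome,
    PatientRecord,
    SimulationOutput,
    validate_parameters,
)

__all__ = [
    "EngineState",
    "InsufficientSampleError",
    "draw_patient",
    "schedule_feedback",
    "regret_levels",
    "update_threshold",
    "simulate",
    "simulate_replicates",
    "referral_summary",
    "THRESHOLD_CLIP",
]

THRESHOLD_CLIP = 4.0  # |threshold| bound, in severity standard deviations

_OUTCOME_CODE = {Outcome.TP: 0, Outcome.FP: 1, Outcome.TN: 2, Outcome.FN: 3}


class InsufficientSampleError(RuntimeError):
    """The measurement window contains no diseased (or no healthy) patients."""


@dataclass
class EngineState:
    """Mutable state of the engine between visits.

    ``pending`` maps a future reveal visit to the error events revealed
    then; ``known_fp``/``known_fn`` hold reveal visits of errors still
    inside the memory window.
    """

    threshold: float
    rng: np.random.Generator
    current_visit: int = 0
    pending: Dict[int, List[FeedbackEvent]] = field(default_factory=dict)
    known_fp: List[int] = field(default_factory=list)
    known_fn: List[int] = field(default_factory=list)

    def reveal_due(self, memory_window: int) -> None:
        """Reveal events due now and forget errors beyond the memory window."""
        due = self.pending.pop(self.current_visit, None)
        if due:
            for event in due:
                if event.error_type is Outcome.FP:
                    self.known_fp.append(event.reveal_visit)
                else:
                    self.known_fn.append(event.reveal_visit)
        if self.known_fp or self.known_fn:
            horizon = self.current_visit - memory_window
            # reveal visits are appended in increasing order
            self.known_fp = [r for r in self.known_fp if r > horizon]
            self.known_fn = [r for r in self.known_fn if r > horizon]


def _resolve_initial_threshold(params: ModelParameters) -> float:
    if params.initial_threshold is not None:
        return float(params.initial_threshold)
    if params.rho == 0.0:
        # degenerate ROC: start at the severity cutoff
        return severity_cutoff(params.prevalence)
    return youden_threshold(params.rho, params.prevalence).threshold


def new_state(params: ModelParameters, seed: int) -> EngineState:
    return EngineState(
        threshold=_resolve_initial_threshold(params),
        rng=np.random.default_rng(seed),
    )


def draw_patient(state: EngineState, params: ModelParameters) -> PatientRecord:
    """Draw one patient and classify the referral decision.

    (true, perceived) severity are standard bivariate normal with
    correlation rho; the patient has a disorder when true severity
    exceeds the prevalence cutoff and is referred when perceived severity
    meets or exceeds the current threshold.
    """
    z1 = state.rng.standard_normal()
    z2 = state.rng.standard_normal()
    true = z1
    perceived = params.rho * z1 + sqrt(1.0 - params.rho * params.rho) * z2
    has_disorder = bool(true > severity_cutoff(params.prevalence))
    referred = bool(perceived >= state.threshold)
    return PatientRecord(
        visit_index=state.current_visit,
        true_severity=float(true),
        perceived_severity=float(perceived),
        has_disorder=has_disorder,
        referred=referred,
        outcome=Outcome.classify(has_disorder, referred),
    )


def schedule_feedback(
    record: PatientRecord, state: EngineState, params: ModelParameters
) -> Optional[FeedbackEvent]:
    """Schedule the future revelation of an error, unless lost to follow-up.

    Correct decisions (TP, TN) never generate feedback: the model tracks
    regret about errors only.  A committed FP is revealed with probability
    1 - fp_loss after fp_delay visits (FN analogously).
    """
    if record.outcome is Outcome.FP:
        loss, delay = params.fp_loss, params.fp_delay
    elif record.outcome is Outcome.FN:
        loss, delay = params.fn_loss, params.fn_delay
    else:
        return None
    if state.rng.random() < loss:
        return None  # lost to follow-up: the physician never learns of it
    event = FeedbackEvent(
        error_type=record.outcome,
        origin_visit=record.visit_index,
        reveal_visit=record.visit_index + delay,
    )
    state.pending.setdefault(event.reveal_visit, []).append(event)
    return event


def regret_levels(state: EngineState, params: ModelParameters) -> Tuple[float, float]:
    """Current (FP regret, weighted FN regret) stocks.

    Each known error contributes ``max(0, 1 - age / memory_window)`` --
    full regret at revelation, decaying linearly to zero as memory fades.
    The FN stock is scaled by the FN regret weight.
    """
    w_inv = 1.0 / params.memory_window
    now = state.current_visit
    fp = sum(1.0 - (now - r) * w_inv for r in state.known_fp)
    fn = sum(1.0 - (now - r) * w_inv for r in state.known_fn)
    return fp, params.fn_regret_weight * fn


def update_threshold(state: EngineState, params: ModelParameters) -> float:
    """Adjust the threshold one step toward the dominant regret.

    new = old + gain * (fp_regret - fn_regret) / (fp_regret + fn_regret),
    clipped to [-THRESHOLD_CLIP, THRESHOLD_CLIP].  With no remembered
    errors the threshold stays put.
    """
    fp, fn = regret_levels(state, params)
    total = fp + fn
    if total > 0.0:
        state.threshold += params.adjustment_gain * (fp - fn) / total
        if state.threshold > THRESHOLD_CLIP:
            state.threshold = THRESHOLD_CLIP
        elif state.threshold < -THRESHOLD_CLIP:
            state.threshold = -THRESHOLD_CLIP
    return state.threshold


def _rolling_rate(hits: np.ndarray, trials: np.ndarray, window: int) -> np.ndarray:
    """Rolling proportion hits/trials over a trailing window (NaN if empty)."""
    ch = np.concatenate([[0.0], np.cumsum(hits, dtype=float)])
    ct = np.concatenate([[0.0], np.cumsum(trials, dtype=float)])
    n = len(hits)
    idx = np.arange(1, n + 1)
    lo = np.maximum(0, idx - window)
    num = ch[idx] - ch[lo]
    den = ct[idx] - ct[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def simulate(
    params: ModelParameters,
    seed: int,
    n_burnin: int = 2000,
    n_measure: int = 3000,
    rolling_window: int = 500,
) -> SimulationOutput:
    """Run the engine for ``n_burnin + n_measure`` visits.

    Summary metrics (outcome counts, sensitivity, specificity, referral
    rate) are computed over the measurement window only, discarding the
    burn-in so they do not depend on the arbitrary initial threshold.
    Identical (params, seed) produce identical output.
    """
    if n_burnin <= 0 or n_measure <= 0:
        raise ValueError("n_burnin and n_measure must be positive")
    params = validate_parameters(params)
    state = new_state(params, seed)
    n = n_burnin + n_measure

    thr = np.empty(n)
    fp_reg = np.empty(n)
    fn_reg = np.empty(n)
    codes = np.empty(n, dtype=np.int8)
    counts = [0, 0, 0, 0]  # TP FP TN FN in the measurement window

    for t in range(n):
        state.current_visit = t
        state.reveal_due(params.memory_window)
        update_threshold(state, params)
        fp_reg[t], fn_reg[t] = regret_levels(state, params)
        thr[t] = state.threshold
        record = draw_patient(state, params)
        schedule_feedback(record, state, params)
        code = _OUTCOME_CODE[record.outcome]
        codes[t] = code
        if t >= n_burnin:
            counts[code] += 1

    n_tp, n_fp, n_tn, n_fn = counts
    if n_tp + n_fn == 0 or n_tn + n_fp == 0:
        raise InsufficientSampleError(
            "measurement window lacks diseased or healthy patients; "
            "sensitivity/specificity undefined"
        )

    if params.rho < 1.0:
        c = severity_cutoff(params.prevalence)
        sigma = sqrt(1.0 - params.rho**2)
        thr_prob = norm.sf((c - params.rho * thr) / sigma)
    else:
        thr_prob = np.ones_like(thr)

    diseased = (codes == 0) | (codes == 3)
    referred = (codes == 0) | (codes == 1)
    return SimulationOutput(
        threshold_trajectory=thr,
        threshold_probability_trajectory=thr_prob,
        fp_regret_trajectory=fp_reg,
        fn_regret_trajectory=fn_reg,
        outcomes=codes,
        rolling_sensitivity=_rolling_rate(
            (diseased & referred).astype(float), diseased.astype(float), rolling_window
        ),
        rolling_specificity=_rolling_rate(
            (~diseased & ~referred).astype(float), (~diseased).astype(float), rolling_window
        ),
        n_burnin=n_burnin,
        n_measure=n_measure,
        n_tp=n_tp,
        n_fp=n_fp,
        n_tn=n_tn,
        n_fn=n_fn,
        sensitivity=n_tp / (n_tp + n_fn),
        specificity=n_tn / (n_tn + n_fp),
        referral_rate=(n_tp + n_fp) / n_measure,
        parameters=params,
        seed=seed,
    )


def simulate_replicates(
    params: ModelParameters,
    seed: int,
    replicates: int = 20,
    n_burnin: int = 2000,
    n_measure: int = 3000,
) -> List[SimulationOutput]:
    """Run ``replicates`` independent seeds seed, seed+1, ... seed+R-1.

    Cross-seed summaries should average the per-run proportions; within a
    run the proportions already pool the full measurement window.
    """
    return [
        simulate(params, seed + i, n_burnin=n_burnin, n_measure=n_measure)
        for i in range(replicates)
    ]


def referral_summary(
    output: SimulationOutput,
    params: ModelParameters = None,
    screener_rho: float = 0.85,
) -> Tuple[float, float, float]:
    """(referral rate, screen-positive rate, referred among screen-positives).

    The screen-positive rate is the analytic fraction of the population a
    screening instrument of accuracy ``screener_rho`` would flag at its
    Youden threshold; dividing the simulated referral rate by it expresses
    referrals as a share of screen-positive children.
    """
    params = params or output.parameters
    pos = float(
        norm.sf(youden_threshold(screener_rho, params.prevalence).threshold)
    )
    if pos <= 0.0:
        raise ZeroDivisionError("screen-positive rate is zero")
    return output.referral_rate, pos, output.referral_rate / pos
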