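"""Core model types: parameters, patient records, feedback events, outputs.

The model describes a physician who assesses the symptom severity of one
patient per visit with imperfect accuracy, refers the patient when the
perceived severity meets or exceeds a decision threshold, and later
receives delayed -- and frequently lost -- feedback about false-positive
and false-negative referral errors.  Known errors generate regret, which
feeds back on the decision threshold.

All severities live on a standard-normal scale: true and perceived
severity are marginally N(0, 1) with correlation ``rho`` (the assessment
accuracy).  A patient has a disorder when true severity falls in the
upper ``prevalence`` tail of the population.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Outcome",
    "ModelParameters",
    "PatientRecord",
    "FeedbackEvent",
    "SimulationOutput",
    "Scenario",
    "CalibrationTarget",
    "ParameterError",
    "validate_parameters",
    "preset",
    "PRESETS",
]


class ParameterError(ValueError):
    """A model parameter is outside its legal range.

    Attributes
    ----------
    field : str
        Name of the offending parameter.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class Outcome(str, Enum):
    """Classification of one referral decision against true disorder status."""

    TP = "TP"
    FP = "FP"
    TN = "TN"
    FN = "FN"

    @staticmethod
    def classify(has_disorder: bool, referred: bool) -> "Outcome":
        if has_disorder:
            return Outcome.TP if referred else Outcome.FN
        return Outcome.FP if referred else Outcome.TN


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter vector of the decision-threshold model.

    Parameters
    ----------
    rho : float
        Correlation in [0, 1] between true and perceived severity
        (assessment accuracy).
    prevalence : float
        Fraction in (0, 1) of patients with a disorder.
    fp_loss, fn_loss : float
        Probability in [0, 1] that a committed FP (resp. FN) error is
        never revealed to the physician (loss to follow-up).
    fp_delay, fn_delay : int
        Delay, in patient visits, between committing a revealed error and
        learning about it.
    fn_regret_weight : float
        Regret attached to a known FN relative to a known FP (>= 0).
    adjustment_gain : float
        Maximum threshold change per visit in response to regret
        imbalance, in severity standard deviations per visit.
    memory_window : int
        Number of visits over which a known error's influence decays
        linearly to zero.
    initial_threshold : float or None
        Starting decision threshold on the perceived-severity scale.
        ``None`` resolves to the Youden-index threshold for ``rho`` and
        ``prevalence`` (a neutral screening operating point).
    """

    rho: float = 0.65
    prevalence: float = 0.15
    fp_loss: float = 0.20
    fn_loss: float = 0.73
    fp_delay: int = 50
    fn_delay: int = 250
    fn_regret_weight: float = 3.0
    adjustment_gain: float = 0.003
    memory_window: int = 120
    initial_threshold: Optional[float] = None

    def replace(self, **overrides) -> "ModelParameters":
        """Return a copy with ``overrides`` applied and validated."""
        return validate_parameters(dataclasses.replace(self, **overrides))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown parameter")
        return validate_parameters(cls(**dict(data)))


def _check_prob(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and np.isfinite(value)):
        raise ParameterError(name, f"must be a finite number, got {value!r}")
    if not 0.0 <= value <= 1.0:
        raise ParameterError(name, f"must lie in [0, 1], got {value}")


def validate_parameters(params: ModelParameters) -> ModelParameters:
    """Validate every field of ``params``; return it unchanged if legal.

    Raises
    ------
    ParameterError
        Naming the offending field, for any out-of-range value.
    """
    _check_prob("rho", params.rho)
    _check_prob("fp_loss", params.fp_loss)
    _check_prob("fn_loss", params.fn_loss)
    if not 0.0 < params.prevalence < 1.0:
        raise ParameterError("prevalence", f"must lie in (0, 1), got {params.prevalence}")
    for name in ("fp_delay", "fn_delay", "memory_window"):
        value = getattr(params, name)
        if not (isinstance(value, (int, np.integer)) and not isinstance(value, bool)):
            raise ParameterError(name, f"must be an integer, got {value!r}")
        if value <= 0:
            raise ParameterError(name, f"must be a positive integer, got {value}")
    if not (np.isfinite(params.fn_regret_weight) and params.fn_regret_weight >= 0):
        raise ParameterError("fn_regret_weight", f"must be >= 0, got {params.fn_regret_weight}")
    if not (np.isfinite(params.adjustment_gain) and params.adjustment_gain > 0):
        raise ParameterError("adjustment_gain", f"must be > 0, got {params.adjustment_gain}")
    if params.initial_threshold is not None and not np.isfinite(params.initial_threshold):
        raise ParameterError("initial_threshold", "must be finite or None")
    return params


@dataclass(frozen=True)
class PatientRecord:
    """One simulated visit."""

    visit_index: int
    true_severity: float
    perceived_severity: float
    has_disorder: bool
    referred: bool
    outcome: Outcome

    def __post_init__(self):
        expected = Outcome.classify(self.has_disorder, self.referred)
        if self.outcome is not expected:
            raise ValueError(
                f"outcome {self.outcome} inconsistent with "
                f"(has_disorder={self.has_disorder}, referred={self.referred})"
            )


@dataclass(frozen=True)
class FeedbackEvent:
    """A scheduled revelation of a past FP or FN error.

    Only errors generate feedback: the model tracks regret about
    mistakes, not satisfaction about correct decisions.
    """

    error_type: Outcome
    origin_visit: int
    reveal_visit: int

    def __post_init__(self):
        if self.error_type not in (Outcome.FP, Outcome.FN):
            raise ValueError("only FP and FN outcomes generate feedback events")
        if self.reveal_visit <= self.origin_visit:
            raise ValueError("reveal_visit must follow origin_visit")


@dataclass
class SimulationOutput:
    """Trajectories and window-averaged summaries from one simulation run.

    Trajectories cover every simulated visit (burn-in included); counts
    and summary proportions cover the measurement window only.
    """

    threshold_trajectory: np.ndarray
    threshold_probability_trajectory: np.ndarray
    fp_regret_trajectory: np.ndarray
    fn_regret_trajectory: np.ndarray
    outcomes: np.ndarray  # per-visit outcome codes: 0=TP 1=FP 2=TN 3=FN
    rolling_sensitivity: np.ndarray
    rolling_specificity: np.ndarray
    n_burnin: int
    n_measure: int
    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int
    sensitivity: float
    specificity: float
    referral_rate: float
    parameters: ModelParameters = None
    seed: int = None

    @property
    def counts(self) -> tuple:
        return (self.n_tp, self.n_fp, self.n_tn, self.n_fn)


# Calibration targets from the systematic review of physician detection of
# developmental-behavioral disorders: sensitivity 38.7% (95% CI 26.1-53.1),
# specificity 87.7% (95% CI 80.2-92.5).
@dataclass(frozen=True)
class CalibrationTarget:
    sensitivity: float = 0.387
    sensitivity_ci: tuple = (0.261, 0.531)
    specificity: float = 0.877
    specificity_ci: tuple = (0.802, 0.925)

    def __post_init__(self):
        if not self.sensitivity_ci[0] <= self.sensitivity <= self.sensitivity_ci[1]:
            raise ValueError("sensitivity CI must bracket the point value")
        if not self.specificity_ci[0] <= self.specificity <= self.specificity_ci[1]:
            raise ValueError("specificity CI must bracket the point value")

    def lower(self) -> "CalibrationTarget":
        """Target at the lower CI bounds (degenerate CIs)."""
        lo_s, lo_p = self.sensitivity_ci[0], self.specificity_ci[0]
        return CalibrationTarget(lo_s, (lo_s, lo_s), lo_p, (lo_p, lo_p))

    def upper(self) -> "CalibrationTarget":
        hi_s, hi_p = self.sensitivity_ci[1], self.specificity_ci[1]
        return CalibrationTarget(hi_s, (hi_s, hi_s), hi_p, (hi_p, hi_p))


@dataclass(frozen=True)
class Scenario:
    """One point in the calibration grid.

    ``fn_delay = fn_delay_multiple * fp_delay`` and the regret weight are
    structural assumptions of the scenario; ``fn_loss`` is calibrated
    against ``target`` for each scenario.
    """

    fp_loss: float
    fn_delay_multiple: float
    fn_regret_weight: float
    target: CalibrationTarget = field(default_factory=CalibrationTarget)
    name: str = ""

    def __post_init__(self):
        if not 0.10 <= self.fp_loss <= 0.60:
            raise ValueError("scenario fp_loss must lie in [0.10, 0.60]")
        if not 1 <= self.fn_delay_multiple <= 5:
            raise ValueError("fn_delay_multiple must lie in [1, 5]")
        if not 1 <= self.fn_regret_weight <= 5:
            raise ValueError("scenario fn_regret_weight must lie in [1, 5]")

    def to_parameters(self, base: ModelParameters = None) -> ModelParameters:
        base = base or ModelParameters()
        return base.replace(
            fp_loss=self.fp_loss,
            fn_delay=int(round(self.fn_delay_multiple * base.fp_delay)),
            fn_regret_weight=self.fn_regret_weight,
        )


# Named presets reproducing the published parameter table.  Experiments 1-4
# are the virtual-experiment overrides; base_alt is the alternate baseline
# from the sensitivity analysis (60% FP loss, regret ratio 2).
PRESETS: dict = {
    "base_case": ModelParameters(),
    "experiment_1": ModelParameters(rho=0.85),
    "experiment_2": ModelParameters(fn_loss=0.20),
    "experiment_3": ModelParameters(fn_regret_weight=10.0),
    "experiment_4": ModelParameters(rho=0.85, fn_loss=0.20, fn_regret_weight=10.0),
    "base_alt": ModelParameters(fp_loss=0.60, fn_regret_weight=2.0),
}


def preset(name: str) -> ModelParameters:
    """Return a named parameter preset (see ``PRESETS``)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
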