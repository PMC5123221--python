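"""Shared fixtures.

The heavy session fixtures run the calibration + experiment pipeline once
at the replicate counts the analyses report (20 seeds of 2000 burn-in +
3000 measured patients); everything downstream reads from them.
"""

import numpy as np
import pytest

from dynthresh.calibration import (
    CalibrationOptions,
    base_case,
    build_scenarios,
    calibrate,
)
from dynthresh.domain import ModelParameters
from dynthresh.experiments import (
    case_study,
    run_virtual_experiment,
    screening_effect,
    sensitivity_sweep,
)

# Fixed arbitrary seeds: 101 for calibration common random numbers,
# 11 for experiment replicate sets.
CAL_SEED = 101
EXP_SEED = 11
REPLICATES = 20

CAL_OPTIONS = CalibrationOptions(
    replicates=REPLICATES,
    seed=CAL_SEED,
    coarse_grids=(("fn_loss", tuple(np.round(np.arange(0.65, 0.901, 0.01), 4))),),
    polish=True,
)


@pytest.fixture(scope="session")
def calibrated_base():
    """Base case with fn_loss calibrated to the review targets."""
    return base_case(CAL_OPTIONS)


@pytest.fixture(scope="session")
def virtual_reports(calibrated_base):
    """All four virtual experiments against the calibrated base."""
    return {
        i: run_virtual_experiment(
            i, calibrated_base, replicates=REPLICATES, seed=EXP_SEED
        )
        for i in (1, 2, 3, 4)
    }


@pytest.fixture(scope="session")
def screening_report(calibrated_base):
    return screening_effect(calibrated_base, replicates=REPLICATES, seed=EXP_SEED)


@pytest.fixture(scope="session")
def suicide_reports():
    return case_study(
        "suicide",
        replicates=REPLICATES,
        seed=EXP_SEED,
        options=CalibrationOptions(replicates=REPLICATES, seed=CAL_SEED),
    )


@pytest.fixture(scope="session")
def colocated_reports():
    return case_study(
        "colocated",
        replicates=REPLICATES,
        seed=EXP_SEED,
        options=CalibrationOptions(replicates=10, seed=CAL_SEED),
    )


@pytest.fixture(scope="session")
def screening_sweep():
    """Screening experiment across a reduced calibrated scenario ensemble.

    The corners of the plausible ranges (FP loss 10/60%, FN delay 1x/5x,
    regret 1/5) crossed with the point and CI-bound targets -- the spread
    across CI-bound calibrations carries most of the ensemble's width.
    Reduced replicate counts keep the suite fast.
    """
    scenarios = build_scenarios(
        fp_loss_range=(0.10, 0.60),
        fn_delay_multiple_range=(1, 5),
        regret_range=(1, 5),
    )
    options = CalibrationOptions(
        replicates=8,
        seed=CAL_SEED,
        coarse_grids=(("fn_loss", tuple(np.round(np.arange(0.55, 0.951, 0.02), 4))),),
        polish=False,
    )
    calibrated = [calibrate(s, options=options) for s in scenarios]
    return sensitivity_sweep(
        calibrated, experiment="screening", replicates=8, seed=EXP_SEED
    )


@pytest.fixture
def base_params():
    return ModelParameters()
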