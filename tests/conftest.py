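"""Shared fixtures: the demographic model, a neutral background spectrum and
session-wide null-threshold calibration (used by several slow tests)."""

import numpy as np
import pytest

from sweepvalley import DemographicModel, simulate
from sweepvalley.coalsim import calibrate_thresholds
from sweepvalley.sweep_clr import background_from_simulations, clr_max_statistic
from sweepvalley.sweep_omega import omega_max_statistic

REGION_L = 20011
EU_N = 12

CALIBRATION_REPS = 600
CALIBRATION_SEED = 77
BACKGROUND_SEED0 = 900_000


@pytest.fixture(scope="session")
def model() -> DemographicModel:
    return DemographicModel()


@pytest.fixture(scope="session")
def eu_background(model):
    """Neutral European background spectrum pooled over 50 region replicates."""
    sims = [simulate(model, {"EU": EU_N}, REGION_L, seed=BACKGROUND_SEED0 + s)
            for s in range(50)]
    return background_from_simulations(sims, EU_N)


@pytest.fixture(scope="session")
def calibration(model, eu_background):
    """95th-percentile null thresholds for CLR_max and omega_max.

    600 neutral region replicates of the European sample (the published
    analysis used 10,000; the Monte-Carlo error of the 95th percentile at
    600 replicates is small against the factor-scale tolerances used here).
    """
    statistics = {
        "clr_max": clr_max_statistic(eu_background),
        "omega_max": omega_max_statistic(),
    }
    thresholds, null = calibrate_thresholds(
        model, {"EU": EU_N}, REGION_L, statistics,
        reps=CALIBRATION_REPS, q=0.95, seed=CALIBRATION_SEED,
    )
    return thresholds, null
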