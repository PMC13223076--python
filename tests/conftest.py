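import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, max_examples=50)
settings.load_profile("derandomized")

from degradose.case_study import load_case_study
from degradose.exposure import MassLossCurve


@pytest.fixture(scope="session")
def case_study():
    """(bom, registry, hazard_db, curves) for the shipped vessel-closure device."""
    return load_case_study()


@pytest.fixture(scope="session")
def bom(case_study):
    return case_study[0]


@pytest.fixture(scope="session")
def registry(case_study):
    return case_study[1]


@pytest.fixture(scope="session")
def hazards(case_study):
    return case_study[2]


@pytest.fixture(scope="session")
def curves(case_study):
    return case_study[3]


def brute_force_window_loss(curve: MassLossCurve, window_days: float,
                            step: float = 0.01) -> float:
    """Independent brute-force oracle for the worst sliding-window mass loss.

    Evaluates the window difference on a dense uniform grid of window starts
    augmented with every interpolation knot (and every knot shifted back by
    the window), which captures the maximum of a piecewise-linear difference
    exactly.
    """
    t = curve.times
    f = curve.fractions
    last_start = t[-1] - window_days
    starts = np.union1d(
        np.arange(t[0], last_start + step / 2, step),
        np.concatenate([t, t - window_days, [last_start]]),
    )
    starts = starts[(starts >= t[0]) & (starts <= last_start)]
    gains = np.interp(starts + window_days, t, f) - np.interp(starts, t, f)
    return float(np.clip(gains.max(), 0.0, 1.0))
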