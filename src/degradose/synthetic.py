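"""Synthetic mass-loss curve generation.

Emulates the degradation kinetics of hydrolytically eroding polymers for
testing and method development: a slow induction period, a bulk-erosion
phase, and a plateau, with an optional late-acceleration (biphasic) variant
mimicking autocatalytic behaviour. Curves are deterministic for a fixed
seed; Gaussian sampling noise, when requested, is re-monotonised and clamped
so every generated curve is a valid cumulative-loss profile.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from pydantic import BaseModel, Field, PositiveFloat

from .exposure import CurveProvenance, MassLossCurve


class CurveShape(str, Enum):
    linear = "linear"
    logistic = "logistic"
    biphasic_late_acceleration = "biphasic_late_acceleration"


class FixtureSpec(BaseModel):
    """Parameters of a generated mass-loss curve.

    Defaults emulate a bulk-eroding glycolide copolymer: sigmoidal loss with
    midpoint near 35 days, plateau at 90% by 180 days, and under 2.5% loss in
    the first week.
    """

    curve_shape: CurveShape = CurveShape.logistic
    plateau_fraction: float = Field(default=0.9, ge=0.0, le=1.0)
    midpoint_days: PositiveFloat = 35.0
    steepness_per_day: PositiveFloat = 0.15
    duration_days: PositiveFloat = 180.0
    n_samples: int = Field(default=61, ge=2)
    noise_sd: float = Field(default=0.0, ge=0.0)
    seed: int = 0

    model_config = {"frozen": True}


def _normalized_logistic(t: np.ndarray, mid: float, k: float, dur: float) -> np.ndarray:
    """Logistic CDF rescaled so the curve is 0 at t=0 and 1 at t=dur."""
    raw = 1.0 / (1.0 + np.exp(-k * (t - mid)))
    lo = 1.0 / (1.0 + np.exp(k * mid))
    hi = 1.0 / (1.0 + np.exp(-k * (dur - mid)))
    return (raw - lo) / (hi - lo)


def generate_fixture_curve(spec: FixtureSpec) -> MassLossCurve:
    """Generate a deterministic synthetic cumulative mass-loss curve.

    linear: constant-rate loss to the plateau. logistic: single sigmoidal
    bulk-erosion phase. biphasic_late_acceleration: a slow early linear phase
    carrying 10% of the plateau plus a steep late sigmoid centred at 80% of
    the duration, so late windows lose mass faster than early ones.
    """
    t = np.linspace(0.0, spec.duration_days, spec.n_samples)
    if spec.curve_shape is CurveShape.linear:
        f = spec.plateau_fraction * t / spec.duration_days
    elif spec.curve_shape is CurveShape.logistic:
        f = spec.plateau_fraction * _normalized_logistic(
            t, spec.midpoint_days, spec.steepness_per_day, spec.duration_days
        )
    else:
        early = 0.1 * spec.plateau_fraction * t / spec.duration_days
        late = 0.9 * spec.plateau_fraction * _normalized_logistic(
            t, 0.8 * spec.duration_days, 2.0 * spec.steepness_per_day, spec.duration_days
        )
        f = early + late
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)
        f[0] = 0.0
        f = np.maximum.accumulate(f)  # restore monotonicity after noise
    f = np.clip(f, 0.0, 1.0)
    f[0] = 0.0
    return MassLossCurve(
        samples=list(zip(t.tolist(), f.tolist())),
        provenance=CurveProvenance.synthetic,
        label=f"{spec.curve_shape.value} synthetic curve (seed={spec.seed})",
    )
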