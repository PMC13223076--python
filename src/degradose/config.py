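"""Assessment-wide configuration knobs."""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, Field, PositiveFloat


class RoundingProfile(str, Enum):
    """``regulatory``: report-style display rounding (3 significant figures
    for doses, margin-dependent rounding for MOS). ``none``: full precision."""

    regulatory = "regulatory"
    none = "none"


class AssessmentConfig(BaseModel):
    """Options threaded through a full device assessment.

    All internal arithmetic is unrounded; ``rounding_profile`` only affects
    rendered reports.
    """

    body_weight_kg: PositiveFloat = 60.0
    scaling_factor_override: int | None = Field(default=None, ge=1)
    water_correction: bool = False
    refinement_window_days: PositiveFloat = 7.0
    review_band_upper: PositiveFloat = 10.0
    rounding_profile: RoundingProfile = RoundingProfile.regulatory

    model_config = {"frozen": True}
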