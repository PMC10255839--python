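"""Foot-strike angle handling and strike-pattern classification.

The foot-strike angle is the sagittal foot angle at initial contact relative
to quiet standing (radians; positive = more dorsiflexed, i.e. heel-first).
Angles above 0.14 rad are rear-foot strikes, below -0.03 rad forefoot
strikes, and the closed interval [-0.03, 0.14] mid-foot strikes.
"""

from __future__ import annotations

import math

REARFOOT_THRESH = 0.14  # rad, exclusive lower bound for rearfoot
FOREFOOT_THRESH = -0.03  # rad, exclusive upper bound for forefoot


def classify_footstrike(angle: float) -> str:
    """Strike pattern from the foot-strike angle (rad).

    Boundary values belong to midfoot: the partition is
    (-inf, -0.03) -> forefoot, [-0.03, 0.14] -> midfoot,
    (0.14, inf) -> rearfoot.
    """
    if not math.isfinite(angle):
        raise ValueError(f"foot-strike angle must be finite, got {angle!r}")
    if angle > REARFOOT_THRESH:
        return "rearfoot"
    if angle < FOREFOOT_THRESH:
        return "forefoot"
    return "midfoot"


def footstrike_angle(strike_angle_raw: float, neutral_standing_angle: float) -> float:
    """Foot-strike angle: raw sagittal foot angle at IC minus the neutral
    standing angle.  Positive output = more dorsiflexed at contact."""
    return strike_angle_raw - neutral_standing_angle
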