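"""Viscous curl force-field definitions.

A curl field pushes the hand orthogonally to its velocity with magnitude
proportional to speed, ``F = k * B * R @ v``, where ``R`` is the 90-degree
rotation matrix.  Two opposite-signed instances (``FF_LATERAL`` and
``FF_CENTER = -FF_LATERAL``) make up the composite training environment:
lateral (+/-30 deg) targets are paired with one field sign and the center
(0 deg) target with the other.

Sign convention: ``k = +1`` rotates velocity counter-clockwise (a CW-pushing
field under the usual screen convention is the mirror case); only the
*pairing* of signs between the center and lateral targets matters for the
analysis, and that is carried entirely by ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

#: Velocity-dependent curl gain (N*s/m).
CURL_GAIN_B = 15.0

#: Error-clamp channel stiffness (N/m); metadata only, the channel is not integrated.
CLAMP_STIFFNESS = 6000.0
#: Error-clamp channel damping (N*s/m); metadata only.
CLAMP_DAMPING = 250.0
#: Displacement at which a partial error clamp releases into a null field (m).
PARTIAL_CLAMP_RELEASE = 0.11

# counter-clockwise 90-degree rotation
_ROT90 = np.array([[0.0, -1.0], [1.0, 0.0]])


class ClampMode(str, Enum):
    """Whether (and how) a trial's lateral motion is clamped to a channel."""

    NONE = "none"
    FULL = "full"
    PARTIAL = "partial"


@dataclass(frozen=True)
class FFCondition:
    """Force-field condition attached to a trial.

    Parameters
    ----------
    B : float
        Viscous gain in N*s/m (``B >= 0``; 0 means a null field).
    k : int
        Field sign in {-1, +1}, or 0 for a null field.
    clamp : ClampMode
        Error-clamp status.  Full clamps occur on 1-target trials only,
        partial clamps on 2-target trials only (enforced by the generator).
    """

    B: float = CURL_GAIN_B
    k: int = 0
    clamp: ClampMode = ClampMode.NONE

    def __post_init__(self) -> None:
        if self.B < 0:
            raise ValueError(f"curl gain B must be >= 0, got {self.B}")
        if self.k not in (-1, 0, 1):
            raise ValueError(f"field sign k must be in {{-1, 0, +1}}, got {self.k}")


NULL_FIELD = FFCondition(B=0.0, k=0)


def curl_force(velocity: np.ndarray, ff: FFCondition) -> np.ndarray:
    """Force exerted by a curl field on a hand moving at ``velocity``.

    ``F = k * B * R @ v`` with ``R`` the counter-clockwise 90-degree
    rotation, so ``||F|| = B * ||v||`` and ``F`` is orthogonal to ``v``.

    Parameters
    ----------
    velocity : (2,) or (n, 2) array
        Hand velocity in m/s.
    ff : FFCondition
        Field condition; must not be a clamp trial (on clamp trials the
        robot renders a channel, not the curl field).
    """
    if ff.clamp is not ClampMode.NONE:
        raise ValueError("curl_force is undefined on clamp trials")
    v = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite velocity")
    return ff.k * ff.B * (v @ _ROT90.T)
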