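"""Initial conditions and the transient graded Cdc42-activation stimulus.

Polarization is triggered by transiently replacing the Cdc42 activation
input I_C with a linear spatial gradient for a fixed duration (10 s by
default), after which I_C drops to a uniform post-stimulus baseline:

    I_C(x, t) = b + m·x   for t ≤ τ          (standard: 2.6 + 0.05·x)
    I_C(x, t) = I_C_post  for t > τ          (standard: 2.95)

Direction naming follows "second letter = prospective front": L-R puts
the high-activation end at the right (+x), R-L at the left, U-D at the
bottom (−y).  The gradient coordinate is measured from the relevant edge
of the shape's bounding box, so the stimulus range adapts to cell size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryMask
from .model import ParameterSet, StateField

__all__ = ["StimulusProtocol", "cdc42_input_rate", "initial_state", "DIRECTIONS"]

DIRECTIONS = ("L-R", "R-L", "U-D")

#: standard initial concentrations of the nine species (μM), a uniform
#: resting cell: (C, Ci, R, Ri, rho, rhoi, P1, P2, P3)
INITIAL_LEVELS = {
    "C": 1.0, "Ci": 1.4, "R": 3.0, "Ri": 4.5,
    "rho": 1.25, "rhoi": 1.85, "P1": 55.0, "P2": 30.0, "P3": 0.05,
}


@dataclass(frozen=True)
class StimulusProtocol:
    """A transient linear Cdc42-activation gradient.

    Attributes
    ----------
    direction : {"L-R", "R-L", "U-D"}
        Axis and orientation; the second letter names the front.
    intercept : float
        b, μM s⁻¹ (activation at the low end of the gradient).
    slope : float
        m, μM s⁻¹ per μm.
    duration : float or None
        τ in seconds; None means the gradient is sustained forever.
    I_C_post : float
        Uniform Cdc42 activation rate after the stimulus ends.
    """

    direction: str = "L-R"
    intercept: float = 2.6
    slope: float = 0.05
    duration: float | None = 10.0
    I_C_post: float = 2.95

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.intercept < 0 or self.slope < 0:
            raise ValueError("intercept and slope must be >= 0")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be positive (or None for sustained)")

    @property
    def sustained(self) -> bool:
        return self.duration is None

    def mirrored(self) -> "StimulusProtocol":
        """Protocol with the horizontal orientation flipped (L-R <-> R-L)."""
        flip = {"L-R": "R-L", "R-L": "L-R", "U-D": "U-D"}
        return StimulusProtocol(flip[self.direction], self.intercept, self.slope,
                                self.duration, self.I_C_post)


def cdc42_input_rate(x, y, t: float, protocol: StimulusProtocol,
                     geometry: GeometryMask):
    """Cdc42 activation input I_C at position(s) (x, y) and time t, μM s⁻¹.

    Positions are in μm from the left/bottom edge of the shape's bounding
    box and must lie within it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    h = geometry.h
    if (np.any(x < -h) or np.any(x > geometry.length + h)
            or np.any(y < -h) or np.any(y > geometry.width + h)):
        raise ValueError("stimulus evaluated outside the cell bounding box")
    p = protocol
    if not p.sustained and t > p.duration:
        return np.broadcast_arrays(np.asarray(p.I_C_post, dtype=float), x)[0].copy()
    if p.direction == "L-R":
        coord = x
    elif p.direction == "R-L":
        coord = geometry.length - x
    else:  # U-D: front at the bottom
        coord = geometry.width - y
    return p.intercept + p.slope * coord


def initial_state(geometry: GeometryMask, params: ParameterSet | None = None) -> StateField:
    """Uniform resting-cell state over the geometry's interior cells."""
    n = geometry.n_interior
    return StateField(**{k: np.full(n, v) for k, v in INITIAL_LEVELS.items()})
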