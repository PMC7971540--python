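"""Polarization metrics and categorical pattern outcomes.

A run is summarized by where the active-Cdc42 maximum sits and how it
moved: *normal* polarization keeps the maximum at an extremity of the
cell (a defined front), *reverse* polarization means the maximum has
shifted away from the extremities (opposite to the initial gradient),
and *uniform* means the field is flat to within 0.01 μM.  Multi-front
states are detected as connected superlevel components of the Cdc42
field, and ΔC — the drop from the on-axis maximum to the concentration
at the front extremity — measures how sharp the front is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import GeometryMask
from .solver import TrajectorySummary
from .stimulus import StimulusProtocol

__all__ = [
    "PatternClass",
    "track_maximum",
    "onset_of_reversal",
    "main_axis_profile",
    "delta_c",
    "count_fronts",
    "classify_pattern",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: uniformity threshold: max-min below this is "no pattern" (μM)
UNIFORM_TOL = 0.01
#: a maximum within this many grid cells of the mask extremity counts as
#: sitting "at" the extremity (normal polarization)
EXTREMITY_CELLS = 2


@dataclass(frozen=True)
class PatternClass:
    """Categorical outcome of a polarization run."""

    label: str               # "uniform" | "normal" | "reverse"
    axis: str | None         # "initial" | "new" (None for uniform)
    axis_length: str | None  # "longer" | "shorter"
    front_count: int
    delta_c: float           # μM
    onset_time: float | None  # s, None if the maximum never retreated

    @property
    def pattern(self) -> str | None:
        """Six-category pattern name for directional runs."""
        if self.label == "uniform":
            return None
        kind = "polarization" if self.label == "normal" else "reverse polarization"
        return f"{kind}, {self.axis_length} {self.axis} axis"


def track_maximum(trajectory: TrajectorySummary) -> pd.DataFrame:
    """Maximum-tracking series: per record time the global active-Cdc42
    maximum (μM) and its tie-broken position (μm from the bounding-box
    left/bottom edge)."""
    if len(trajectory.track) < 2:
        raise ValueError("need at least two recorded times")
    return trajectory.track[["t", "max_C", "x", "y", "degenerate"]].copy()


def _forward_coordinate(track: pd.DataFrame, protocol: StimulusProtocol) -> np.ndarray:
    """Signed position along the stimulus axis, increasing toward the front."""
    if protocol.direction == "L-R":
        return track["x"].to_numpy()
    if protocol.direction == "R-L":
        return -track["x"].to_numpy()
    return -track["y"].to_numpy()  # U-D: front at the bottom


def onset_of_reversal(track: pd.DataFrame, protocol: StimulusProtocol,
                      h: float) -> float | None:
    """First recorded time the Cdc42 maximum retreats from its running
    frontmost position by more than one grid cell, opposite to the
    stimulus direction; None if it never does."""
    coord = _forward_coordinate(track, protocol)
    t = track["t"].to_numpy()
    run_max = np.maximum.accumulate(coord)
    retreated = coord < run_max - h
    hits = np.flatnonzero(retreated)
    return float(t[hits[0]]) if hits.size else None


def main_axis_profile(values: np.ndarray, geometry: GeometryMask,
                      axis: str = "x") -> tuple[np.ndarray, np.ndarray]:
    """Concentration profile along the cell's main axis.

    Averages the one or two rows (columns for axis='y') of cells nearest
    the midline.  Returns (positions μm, values μM) sorted by position.
    """
    xs, ys = geometry.cell_centers()
    if axis == "x":
        along, across, mid = xs, ys, geometry.width / 2.0
    else:
        along, across, mid = ys, xs, geometry.length / 2.0
    # cells whose center is within one spacing of the midline
    sel = np.abs(across - mid) <= geometry.h * (1.0 + 1e-9) / 2.0 + 1e-12
    if not sel.any():  # very thin shapes: fall back to nearest row
        sel = np.abs(across - mid) <= np.abs(across - mid).min() + 1e-12
    pos = along[sel]
    val = np.asarray(values)[sel]
    uniq = np.unique(np.round(pos, 9))
    prof = np.array([val[np.isclose(pos, u)].mean() for u in uniq])
    return uniq, prof


def delta_c(profile: tuple[np.ndarray, np.ndarray], geometry: GeometryMask,
            front: str = "right") -> float:
    """ΔC: main-axis maximum minus the concentration at the front
    extremity of the profile (μM, always ≥ 0)."""
    pos, val = profile
    edge = val[np.argmax(pos)] if front == "right" else val[np.argmin(pos)]
    return float(val.max() - edge)


def count_fronts(values: np.ndarray, geometry: GeometryMask,
                 threshold: float = 3.0) -> int:
    """Number of 4-connected components where active Cdc42 > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    grid = geometry.to_grid(np.asarray(values), fill=-np.inf)
    return int(ndimage.label(grid > threshold, structure=_STRUCT4)[1])


def _projection_range(values: np.ndarray, geometry: GeometryMask, axis: str) -> float:
    """Range (max-min) of the field averaged across the perpendicular axis."""
    grid = geometry.to_grid(np.asarray(values), fill=np.nan)
    ax = 0 if axis == "x" else 1
    mask = np.isfinite(grid)
    cnt = mask.sum(axis=ax)
    sums = np.where(mask, grid, 0.0).sum(axis=ax)
    prof = sums[cnt > 0] / cnt[cnt > 0]
    return float(prof.max() - prof.min())


def classify_pattern(trajectory: TrajectorySummary,
                     protocol: StimulusProtocol | None = None,
                     geometry: GeometryMask | None = None,
                     front_threshold: float = 3.0) -> PatternClass:
    """Classify the final state of a directional run.

    uniform : final max−min < 0.01 μM.
    normal  : the final maximum sits within 2 grid cells of the cell
              extremity along the final polarization axis (for the
              initial axis, the stimulus-front extremity specifically).
    reverse : otherwise — the maximum left the extremities.

    The final polarization axis is whichever axis shows the steeper
    projected concentration range; it is "initial" if it coincides with
    the stimulus axis, else "new".
    """
    protocol = protocol or trajectory.protocol
    geometry = geometry or trajectory.geometry
    C = np.asarray(trajectory.final_state.C)
    xs, ys = geometry.cell_centers()
    h = geometry.h

    n_fronts = count_fronts(C, geometry, threshold=front_threshold)
    stim_axis = "x" if protocol.direction in ("L-R", "R-L") else "y"
    prof = main_axis_profile(C, geometry, axis=stim_axis)
    if protocol.direction == "L-R":
        dc_front = "right"
    elif protocol.direction == "R-L":
        dc_front = "left"
    else:
        dc_front = "left"  # U-D front at the bottom = low-coordinate end
    dC = delta_c(prof, geometry, front=dc_front)
    onset = onset_of_reversal(trajectory.track, protocol, h)

    if C.max() - C.min() < UNIFORM_TOL:
        return PatternClass("uniform", None, None, n_fronts, dC, onset)

    # position of the final maximum (tie-broken centroid)
    tied = C >= C.max() - trajectory.config.abs_tol
    px, py = float(xs[tied].mean()), float(ys[tied].mean())

    # a maximum sitting at the stimulated front extremity is maintained
    # polarization by definition, whatever the projected-steepness
    # comparison says (the comparison can tie for a single compact peak)
    stim_pos = px if stim_axis == "x" else py
    stim_all = xs if stim_axis == "x" else ys
    if protocol.direction == "L-R":
        at_stim_front = stim_pos >= float(stim_all.max()) - EXTREMITY_CELLS * h
    elif protocol.direction == "R-L":
        at_stim_front = stim_pos <= float(stim_all.min()) + EXTREMITY_CELLS * h
    else:  # U-D, front at the bottom
        at_stim_front = stim_pos <= float(stim_all.min()) + EXTREMITY_CELLS * h
    ext_stim = geometry.length if stim_axis == "x" else geometry.width
    ext_perp = geometry.width if stim_axis == "x" else geometry.length
    if at_stim_front:
        return PatternClass("normal", "initial",
                            "longer" if ext_stim >= ext_perp else "shorter",
                            n_fronts, dC, onset)

    # final polarization axis by projected steepness
    axis_final = "x" if _projection_range(C, geometry, "x") >= _projection_range(C, geometry, "y") else "y"
    axis = "initial" if axis_final == stim_axis else "new"
    along = px if axis_final == "x" else py
    along_all = xs if axis_final == "x" else ys
    lo, hi = float(along_all.min()), float(along_all.max())

    tol = EXTREMITY_CELLS * h
    if axis == "initial":
        if protocol.direction in ("L-R",):
            at_front = along >= hi - tol
        elif protocol.direction == "R-L":
            at_front = along <= lo + tol
        else:  # U-D, front at the bottom
            at_front = along <= lo + tol
        label = "normal" if at_front else "reverse"
    else:
        label = "normal" if (along >= hi - tol or along <= lo + tol) else "reverse"

    ext_along = geometry.length if axis_final == "x" else geometry.width
    ext_across = geometry.width if axis_final == "x" else geometry.length
    axis_length = "longer" if ext_along >= ext_across else "shorter"
    return PatternClass(label, axis, axis_length, n_fronts, dC, onset)
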