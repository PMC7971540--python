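"""Packaged end-to-end scenarios and figure-style rendering.

Each scenario reproduces one of the study's standard computational
experiments (single-shape time course, direction grid, stimulus
strength/duration grid, maximum tracking across shapes, aspect-ratio
grid, 1D sensitivity, phase diagrams) and writes its outputs — a copy of
the configuration, CSV summaries, an HDF5 snapshot container and PNG
panels — into an output directory.  Scenario runs are deterministic;
re-running overwrites identical files.

The default meshes and horizons of the heavier sweep scenarios are
deliberately reduced relative to single runs so a full scenario finishes
in minutes on a laptop; pass ``n_mesh``/``t_end`` to override.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classify import classify_pattern, track_maximum
from .config import RunConfig
from .model import SPECIES
from .solver import TrajectorySummary, simulate
from .stimulus import StimulusProtocol
from .sweeps import aspect_ratio_sweep, phase_diagram, sensitivity_1d, SweepSpec

__all__ = ["SCENARIOS", "run_scenario", "render_field", "save_snapshots"]

log = logging.getLogger(__name__)

#: record times used for time-course panels (s)
TIMECOURSE_TIMES = (1.0, 10.0, 30.0, 100.0, 300.0, 1000.0)

#: the seven standard outlines at their standard sizes (name, L, W)
STANDARD_SHAPES = (
    ("circle", 50.0, 50.0),
    ("square", 50.0, 50.0),
    ("rectangle", 50.0, 30.0),
    ("teardrop", 50.0, 30.0),
    ("narrow_drop", 50.0, 20.0),
    ("wide_drop", 50.0, 40.0),
    ("triangle", 50.0, 40.0),
)


def render_field(values: np.ndarray, geometry, path, threshold: float = 3.0,
                 title: str | None = None) -> None:
    """Render a concentration field; superlevel regions (> threshold) are
    shown white, matching the activity-profile display convention."""
    grid = geometry.to_grid(np.asarray(values))
    fig, ax = plt.subplots(figsize=(4, 4))
    masked = np.ma.masked_invalid(grid)
    im = ax.imshow(np.clip(masked, None, threshold), origin="lower",
                   cmap="viridis", vmax=threshold)
    over = masked > threshold
    if over.any():
        white = np.ma.masked_where(~over, np.ones_like(grid))
        ax.imshow(white, origin="lower", cmap="gray", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, shrink=0.8, label="μM")
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_snapshots(traj: TrajectorySummary, path) -> None:
    """Write all recorded snapshots to an HDF5 container
    (groups ``t_<time>``, one dataset per species, plus grid metadata)."""
    with h5py.File(path, "w") as f:
        f.attrs["h"] = traj.geometry.h
        f.attrs["shape_name"] = traj.geometry.shape_name
        f.attrs["length"] = traj.geometry.length
        f.attrs["width"] = traj.geometry.width
        f.create_dataset("inside", data=traj.geometry.inside)
        for t, state in sorted(traj.snapshots.items()):
            grp = f.create_group(f"t_{t:g}")
            grp.attrs["time"] = t
            for s in SPECIES:
                grp.create_dataset(s, data=getattr(state, s))


def _outdir(out_dir, cfg: RunConfig) -> Path:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    cfg.dump(d / f"config_{cfg.hash}.yaml")
    return d


def _simulate_cfg(cfg: RunConfig) -> TrajectorySummary:
    return simulate(cfg.build_geometry(), cfg.build_params(),
                    cfg.build_protocol(), cfg.build_solver())


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def _teardrop_timecourse(out: Path, n_mesh: int, t_end: float,
                         rel_tol: float, abs_tol: float) -> None:
    """All nine species on the standard teardrop at the standard record times."""
    times = tuple(t for t in TIMECOURSE_TIMES if t <= t_end)
    cfg = RunConfig(shape="teardrop", length=50, width=30, n_mesh=n_mesh,
                    solver=dict(t_end=t_end, record_times=times, method="bdf",
                                rel_tol=rel_tol, abs_tol=abs_tol),
                    scenario="teardrop_timecourse")
    out = _outdir(out, cfg)
    traj = _simulate_cfg(cfg)
    save_snapshots(traj, out / f"snapshots_{cfg.hash}.h5")
    track_maximum(traj).to_csv(out / f"max_track_{cfg.hash}.csv", index=False)
    for t in times:
        render_field(traj.snapshots[t].C, traj.geometry,
                     out / f"cdc42_t{t:g}_{cfg.hash}.png", threshold=3.0,
                     title=f"active Cdc42, t={t:g}s")


def _direction_grid(out: Path, n_mesh: int, t_end: float,
                    rel_tol: float, abs_tol: float) -> None:
    """Seven shapes × three stimulus directions, classified at t_end."""
    rows = []
    for shape, L, W in STANDARD_SHAPES:
        for direction in ("L-R", "R-L", "U-D"):
            cfg = RunConfig(shape=shape, length=L, width=W, n_mesh=n_mesh,
                            protocol=dict(direction=direction),
                            solver=dict(t_end=t_end, rel_tol=rel_tol, abs_tol=abs_tol,
                                        method="bdf"),
                            scenario="direction_grid")
            out_d = _outdir(out, cfg)
            traj = _simulate_cfg(cfg)
            pc = classify_pattern(traj)
            rows.append(dict(shape=shape, length=L, width=W, direction=direction,
                             label=pc.label, axis=pc.axis, pattern=pc.pattern,
                             front_count=pc.front_count, delta_c=pc.delta_c,
                             onset_time=pc.onset_time))
            render_field(traj.final_state.C, traj.geometry,
                         out_d / f"final_{shape}_{direction}_{cfg.hash}.png")
    pd.DataFrame(rows).to_csv(Path(out) / "direction_grid.csv", index=False)


def _strength_duration(out: Path, n_mesh: int, t_end: float,
                       rel_tol: float, abs_tol: float) -> None:
    """Stimulus intercepts × slopes × durations for circle and teardrop."""
    rows = []
    for shape, L, W in (("circle", 50.0, 50.0), ("teardrop", 50.0, 30.0)):
        for intercept in (1.6, 2.6, 3.6):
            for slope in (0.025, 0.05, 0.1):
                for duration in (5.0, 10.0, 20.0, None):
                    proto = StimulusProtocol(intercept=intercept, slope=slope,
                                             duration=duration)
                    cfg = RunConfig(shape=shape, length=L, width=W, n_mesh=n_mesh,
                                    protocol=dict(intercept=intercept, slope=slope,
                                                  duration="sustained" if duration is None else duration),
                                    solver=dict(t_end=t_end, rel_tol=rel_tol, abs_tol=abs_tol,
                                                method="bdf"),
                                    scenario="strength_duration")
                    _outdir(out, cfg)
                    traj = simulate(cfg.build_geometry(), cfg.build_params(), proto,
                                    cfg.build_solver())
                    pc = classify_pattern(traj)
                    rows.append(dict(shape=shape, intercept=intercept, slope=slope,
                                     duration=duration, label=pc.label, axis=pc.axis,
                                     delta_c=pc.delta_c, onset_time=pc.onset_time))
    pd.DataFrame(rows).to_csv(Path(out) / "strength_duration.csv", index=False)


def _max_tracking(out: Path, n_mesh: int, t_end: float,
                  rel_tol: float, abs_tol: float) -> None:
    """Maximum value/position series for the 7 shapes × {L-R, R-L}."""
    frames = []
    for shape, L, W in STANDARD_SHAPES:
        for direction in ("L-R", "R-L"):
            cfg = RunConfig(shape=shape, length=L, width=W, n_mesh=n_mesh,
                            protocol=dict(direction=direction),
                            solver=dict(t_end=t_end, rel_tol=rel_tol, abs_tol=abs_tol,
                                        method="bdf"),
                            scenario="max_tracking")
            _outdir(out, cfg)
            traj = _simulate_cfg(cfg)
            tm = track_maximum(traj)
            tm["shape"] = shape
            tm["direction"] = direction
            frames.append(tm)
    pd.concat(frames).to_csv(Path(out) / "max_tracking.csv", index=False)


def _aspect_ratio(out: Path, n_mesh: int, t_end: float,
                  rel_tol: float, abs_tol: float) -> None:
    sizes = (10.0, 30.0, 50.0, 70.0, 90.0)
    frames = []
    for shape in ("teardrop", "ellipse", "rectangle"):
        df = aspect_ratio_sweep(shape, sizes, sizes, StimulusProtocol(),
                                n_mesh=n_mesh, t_end=t_end,
                                rel_tol=rel_tol, abs_tol=abs_tol)
        frames.append(df)
    pd.concat(frames).to_csv(Path(out) / "aspect_ratio.csv", index=False)


def _sensitivity(out: Path, n_mesh: int, t_end: float,
                 rel_tol: float, abs_tol: float) -> None:
    from .sweeps import SENSITIVITY_VALUES
    spec = SweepSpec(variations=tuple(SENSITIVITY_VALUES.items()),
                     n_mesh=n_mesh, t_end=t_end,
                     rel_tol=rel_tol, abs_tol=abs_tol)
    sensitivity_1d(spec).to_csv(Path(out) / "sensitivity_1d.csv", index=False)


def _phase_diagram(out: Path, n_mesh: int, t_end: float,
                   rel_tol: float, abs_tol: float) -> None:
    frames = []
    for shape in ("circle", "teardrop"):
        df = phase_diagram(shape=shape, n_mesh=n_mesh, t_end=t_end,
                           rel_tol=rel_tol, abs_tol=abs_tol)
        df["shape"] = shape
        frames.append(df)
    pd.concat(frames).to_csv(Path(out) / "phase_diagram.csv", index=False)


SCENARIOS = {
    "fig4_teardrop_timecourse": (_teardrop_timecourse, dict(n_mesh=110, t_end=1000.0)),
    "fig5_direction_grid": (_direction_grid, dict(n_mesh=72, t_end=1000.0)),
    "fig6_strength_duration": (_strength_duration, dict(n_mesh=72, t_end=1000.0)),
    "fig7_max_tracking": (_max_tracking, dict(n_mesh=110, t_end=150.0)),
    "fig8_aspect_ratio": (_aspect_ratio, dict(n_mesh=72, t_end=1000.0)),
    "fig9_sensitivity": (_sensitivity, dict(n_mesh=72, t_end=1000.0)),
    "fig10_phase_diagram": (_phase_diagram, dict(n_mesh=72, t_end=1000.0)),
}


def run_scenario(name: str, out_dir="results/scenarios", n_mesh: int | None = None,
                 t_end: float | None = None, rel_tol: float = 1e-4,
                 abs_tol: float = 1e-7) -> Path:
    """Run a packaged scenario; returns the output directory."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    fn, defaults = SCENARIOS[name]
    kw = dict(defaults)
    if n_mesh is not None:
        kw["n_mesh"] = n_mesh
    if t_end is not None:
        kw["t_end"] = t_end
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    log.info("scenario %s -> %s (mesh %d, t_end %g)", name, out, kw["n_mesh"], kw["t_end"])
    fn(out, rel_tol=rel_tol, abs_tol=abs_tol, **kw)
    return out
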