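import numpy as np
import pandas as pd
import pytest

from shapepolar.classify import (
    classify_pattern,
    count_fronts,
    delta_c,
    main_axis_profile,
    onset_of_reversal,
    track_maximum,
)
from shapepolar.geometry import make_shape
from shapepolar.model import ParameterSet
from shapepolar.solver import SolverConfig, TrajectorySummary
from shapepolar.stimulus import StimulusProtocol, initial_state


def make_traj(geom, C_field, protocol=None, track=None):
    """Assemble a minimal TrajectorySummary around a prescribed final field."""
    state = initial_state(geom, ParameterSet())
    state.C = np.asarray(C_field, dtype=float)
    if track is None:
        xs, ys = geom.cell_centers()
        i = int(np.argmax(state.C))
        track = pd.DataFrame({"t": [0.0, 1.0], "max_C": [1.0, state.C.max()],
                              "x": [xs[i]] * 2, "y": [ys[i]] * 2,
                              "degenerate": [False, False]})
    cfg = SolverConfig(t_end=max(track.t.max(), 1.0), rel_tol=1e-4, abs_tol=1e-7)
    return TrajectorySummary(
        geometry=geom, params=ParameterSet(), protocol=protocol or StimulusProtocol(),
        config=cfg, track=track, snapshots={}, final_state=state,
        mass=pd.DataFrame({"t": [0.0], "Cdc42": [1.0], "Rac": [1.0],
                           "Rho": [1.0], "PI": [1.0]}))


@pytest.fixture(scope="module")
def rect():
    return make_shape("rectangle", 50, 30, 60)


class TestTrackMaximum:
    def test_monotone_field_max_at_right_edge(self, rect):
        xs, _ = rect.cell_centers()
        traj = make_traj(rect, xs)  # rises with x
        tm = track_maximum(traj)
        assert tm.iloc[-1].x == pytest.approx(xs.max())

    def test_requires_two_times(self, rect):
        xs, _ = rect.cell_centers()
        traj = make_traj(rect, xs)
        traj.track = traj.track.iloc[:1]
        with pytest.raises(ValueError):
            track_maximum(traj)

    def test_uniform_field_centroid_with_flag(self, rect):
        # the degenerate plateau tie-break reports the centroid
        from shapepolar.solver import _argmax_position
        xs, ys = rect.cell_centers()
        v, px, py, degen = _argmax_position(np.ones(rect.n_interior), xs, ys, 1e-9)
        assert degen
        assert px == pytest.approx(xs.mean())
        assert py == pytest.approx(ys.mean())


class TestOnset:
    def _track(self, ts, xs):
        return pd.DataFrame({"t": ts, "max_C": np.ones(len(ts)),
                             "x": xs, "y": [15.0] * len(ts),
                             "degenerate": [False] * len(ts)})

    def test_retreat_detected(self):
        tr = self._track([0, 1, 2, 3, 4], [40, 45, 48, 44, 30])
        assert onset_of_reversal(tr, StimulusProtocol(), h=1.0) == 3.0

    def test_monotone_advance_gives_none(self):
        tr = self._track([0, 1, 2, 3], [10, 20, 30, 40])
        assert onset_of_reversal(tr, StimulusProtocol(), h=1.0) is None

    def test_sub_cell_jitter_ignored(self):
        tr = self._track([0, 1, 2], [40.0, 40.5, 39.8])
        assert onset_of_reversal(tr, StimulusProtocol(), h=1.0) is None

    def test_rl_direction_flips_sense(self):
        # for R-L the front is at low x, so retreat means moving right
        tr = self._track([0, 1, 2], [10, 8, 12])
        rl = StimulusProtocol(direction="R-L")
        assert onset_of_reversal(tr, rl, h=1.0) == 2.0


class TestProfilesAndFronts:
    def test_delta_c_uniform_and_front_max(self, rect):
        xs, _ = rect.cell_centers()
        prof = main_axis_profile(np.ones(rect.n_interior), rect)
        assert delta_c(prof, rect) == pytest.approx(0.0)
        prof2 = main_axis_profile(xs, rect)  # max at the front edge
        assert delta_c(prof2, rect) == pytest.approx(0.0)

    def test_delta_c_linear_rise_from_front(self, rect):
        # profile falling from an interior max to the front edge by 1 μM
        xs, _ = rect.cell_centers()
        vals = 2.0 - np.abs(xs - 20.0) / 30.0  # max 2.0 at x=20, 1.0 at x=50
        prof = main_axis_profile(vals, rect)
        assert delta_c(prof, rect) == pytest.approx(1.0, abs=0.05)

    def test_count_fronts_gaussian_bumps(self, rect):
        xs, ys = rect.cell_centers()
        one = 4 * np.exp(-((xs - 40) ** 2 + (ys - 15) ** 2) / 20)
        two = one + 4 * np.exp(-((xs - 10) ** 2 + (ys - 15) ** 2) / 20)
        assert count_fronts(one, rect, threshold=3.0) == 1
        assert count_fronts(two, rect, threshold=3.0) == 2
        assert count_fronts(np.ones(rect.n_interior), rect, threshold=3.0) == 0


class TestClassifyPattern:
    def test_uniform(self, rect):
        traj = make_traj(rect, np.full(rect.n_interior, 2.0))
        pc = classify_pattern(traj)
        assert pc.label == "uniform"
        assert pc.front_count in (0, 1)
        assert pc.delta_c < 1e-9

    def test_normal_polarization_initial_axis(self, rect):
        xs, _ = rect.cell_centers()
        traj = make_traj(rect, 1.0 + xs / 10.0)
        pc = classify_pattern(traj)
        assert pc.label == "normal" and pc.axis == "initial"
        assert pc.axis_length == "longer"
        assert pc.pattern == "polarization, longer initial axis"

    def test_reverse_polarization_interior_max(self, rect):
        xs, ys = rect.cell_centers()
        field = 1.0 + 3 * np.exp(-((xs - 25) ** 2) / 30)  # bump mid-cell
        traj = make_traj(rect, field)
        pc = classify_pattern(traj)
        assert pc.label == "reverse" and pc.axis == "initial"

    def test_new_axis_detection(self, rect):
        _, ys = rect.cell_centers()
        traj = make_traj(rect, 1.0 + ys / 5.0)  # gradient along y after L-R stimulus
        pc = classify_pattern(traj)
        assert pc.axis == "new"
        assert pc.axis_length == "shorter"  # width 30 < length 50

    def test_mirror_invariance(self):
        g = make_shape("teardrop", 40, 24, 50)
        xs, ys = g.cell_centers()
        field = 1.0 + 3 * np.exp(-((xs - 15) ** 2 + (ys - 12) ** 2) / 40)
        traj = make_traj(g, field)
        pc = classify_pattern(traj)

        gm = g.mirrored("x")
        xm, ym = gm.cell_centers()
        fieldm = 1.0 + 3 * np.exp(-((xm - 25) ** 2 + (ym - 12) ** 2) / 40)
        trajm = make_traj(gm, fieldm, protocol=StimulusProtocol().mirrored())
        pcm = classify_pattern(trajm)
        assert (pc.label, pc.axis, pc.axis_length) == (pcm.label, pcm.axis, pcm.axis_length)
        assert pc.front_count == pcm.front_count
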