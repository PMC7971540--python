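import numpy as np
import pytest
from scipy.integrate import solve_ivp

from shapepolar.geometry import make_shape
from shapepolar.model import ParameterSet, StateField, reaction_rhs
from shapepolar.solver import (
    SolverConfig,
    build_diffusion_operator,
    evolve_diffusion,
    simulate,
)
from shapepolar.stimulus import StimulusProtocol, initial_state


class TestDiffusionOperator:
    def test_rows_sum_to_zero(self, small_teardrop):
        L = build_diffusion_operator(small_teardrop, 5.0)
        assert np.abs(np.asarray(L.sum(axis=1)).ravel()).max() < 1e-12

    def test_uniform_field_in_null_space(self, small_circle):
        L = build_diffusion_operator(small_circle, 50.0)
        u = np.ones(small_circle.n_interior)
        assert np.abs(L @ u).max() < 1e-12

    def test_symmetry(self, small_teardrop):
        L = build_diffusion_operator(small_teardrop, 1.0)
        assert abs(L - L.T).max() < 1e-12

    def test_negative_diffusivity_rejected(self, small_circle):
        with pytest.raises(ValueError):
            build_diffusion_operator(small_circle, -1.0)

    def test_cosine_mode_decay_rate(self):
        # Neumann eigenmode cos(pi x / L) decays at exactly D (pi/L)^2
        D, Lx = 50.0, 50.0
        strip = make_shape("rectangle", Lx, 10, 110)
        x, _ = strip.cell_centers()
        u0 = np.cos(np.pi * x / Lx)
        t_end, dt = 2.0, 0.02
        u = evolve_diffusion(strip, D, u0, t_end, dt)
        # amplitude of the mode via projection
        amp = (u @ u0) / (u0 @ u0)
        rate = -np.log(amp) / t_end
        exact = D * (np.pi / Lx) ** 2
        assert rate == pytest.approx(exact, rel=0.01)


class TestSimulate:
    def test_zero_diffusion_matches_ode_oracle(self, params):
        # with all D = 0 and a spatially uniform stimulus the PDE solver
        # must reproduce the space-free reaction kinetics
        g = make_shape("circle", 20, 20, 24)
        p = params.with_(D_m=0.0, D_mc=0.0, D_P=0.0)
        proto = StimulusProtocol(intercept=3.5, slope=0.0, duration=5.0)
        cfg = SolverConfig(t_end=10.0, rel_tol=1e-6, abs_tol=1e-9,
                           record_times=(2.0, 5.0, 10.0))
        traj = simulate(g, p, proto, cfg)

        y0 = initial_state(g, p).stack()[:, 0]

        def rhs(t, y):
            ic = 3.5 if t <= 5.0 else proto.I_C_post
            return reaction_rhs(StateField.from_stack(y.reshape(9, 1)), p, I_C=ic).ravel()

        for t_chk in (2.0, 5.0, 10.0):
            sol = solve_ivp(rhs, (0, t_chk), y0, method="LSODA",
                            rtol=1e-11, atol=1e-13, max_step=2.5)
            ref = sol.y[:, -1]
            got = traj.snapshots[t_chk].stack()
            rel = np.abs(got - ref[:, None]).max() / np.abs(ref).max()
            assert rel < 100 * cfg.rel_tol

    def test_mass_conservation_short_run(self, small_teardrop, params, standard_protocol):
        cfg = SolverConfig(t_end=20.0, rel_tol=1e-4, abs_tol=1e-7)
        traj = simulate(small_teardrop, params, standard_protocol, cfg)
        for drift in traj.mass_drift.values():
            assert drift < 1e-9

    def test_pi_mass_budget(self, small_circle, params, standard_protocol):
        # total PI obeys d/dt Σ(P1+P2+P3) = Σ(I_P1 − δ_P1 P1): bounded by
        # the production/decay extremes of the run
        cfg = SolverConfig(t_end=10.0, rel_tol=1e-4, abs_tol=1e-7)
        traj = simulate(small_circle, params, standard_protocol, cfg)
        area = small_circle.area
        m = traj.mass
        dm = np.diff(m.PI.to_numpy()) / np.diff(m.t.to_numpy())
        # with P1 near 50-55 the net source is I_P1 - δ_P1*P1 ∈ [-1.05, 0.45] μM/s·area
        assert np.all(dm < 0.5 * area)
        assert np.all(dm > -1.2 * area)

    def test_snapshots_and_track_schedule(self, small_circle, params, standard_protocol):
        cfg = SolverConfig(t_end=5.0, rel_tol=1e-4, abs_tol=1e-7,
                           record_times=(1.5, 4.0), track_dt=1.0)
        traj = simulate(small_circle, params, standard_protocol, cfg)
        assert set(traj.snapshots) >= {1.5, 4.0, 5.0}
        assert list(traj.track.t) == [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        assert (traj.track.t.diff().dropna() > 0).all()

    def test_fields_stay_nonnegative_and_finite(self, small_teardrop, params, standard_protocol):
        cfg = SolverConfig(t_end=15.0, rel_tol=1e-4, abs_tol=1e-7)
        traj = simulate(small_teardrop, params, standard_protocol, cfg)
        Y = traj.final_state.stack()
        assert np.isfinite(Y).all() and Y.min() >= 0

    def test_halving_dt_max_converged(self, small_circle, params, standard_protocol):
        # recorded maxima are step-size converged: halving dt_max moves
        # them by no more than ~10x the relative tolerance
        kw = dict(t_end=8.0, rel_tol=1e-6, abs_tol=1e-9)
        t1 = simulate(small_circle, params, standard_protocol, SolverConfig(dt_max=1.0, **kw))
        t2 = simulate(small_circle, params, standard_protocol, SolverConfig(dt_max=0.5, **kw))
        a = t1.track.max_C.to_numpy()
        b = t2.track.max_C.to_numpy()
        assert np.abs(a - b).max() / np.abs(b).max() < 10 * kw["rel_tol"] * 10

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(t_end=-1.0)
        with pytest.raises(ValueError):
            SolverConfig(rel_tol=0.0)
        with pytest.raises(ValueError):
            SolverConfig(t_end=10.0, record_times=(20.0,))


class TestBdfPath:
    def test_bdf_matches_split_integrator(self, params, standard_protocol):
        # two independent integration routes (adaptive Strang splitting
        # vs fully implicit BDF method of lines) agree on the transient
        g = make_shape("teardrop", 30, 20, 34)
        kw = dict(t_end=20.0, rel_tol=1e-5, abs_tol=1e-8)
        t_split = simulate(g, params, standard_protocol, SolverConfig(**kw))
        t_bdf = simulate(g, params, standard_protocol, SolverConfig(method="bdf", **kw))
        a = t_split.track.max_C.to_numpy()
        b = t_bdf.track.max_C.to_numpy()
        assert np.abs(a - b).max() / np.abs(a).max() < 5e-3
        f1 = t_split.final_state.stack()
        f2 = t_bdf.final_state.stack()
        assert np.abs(f1 - f2).max() / np.abs(f1).max() < 5e-3

    def test_bdf_mass_drift_small(self, small_teardrop, params, standard_protocol):
        cfg = SolverConfig(t_end=30.0, rel_tol=1e-4, abs_tol=1e-7, method="bdf")
        traj = simulate(small_teardrop, params, standard_protocol, cfg)
        assert max(traj.mass_drift.values()) < 1e-6
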