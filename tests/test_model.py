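import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shapepolar.model import (
    ParameterSet,
    StateField,
    activation_rates,
    gtpase_reaction_rhs,
    load_parameters,
    pi_reaction_rhs,
    pi_steady_state,
    reaction_rhs,
    wellmixed_steady_state,
)


def state_from(levels):
    return StateField.from_stack(np.asarray(levels, dtype=float).reshape(9, 1))


class TestActivationRates:
    def test_basal_hand_values(self, params):
        # at basal levels both Hill denominators equal 2 and the PI
        # feedback factor is exactly 1, so the rates reduce to
        # (2.95/2, 0.5+4.5, (3.3+0.9)/2)
        QC, QR, Qr = activation_rates(1.0, 3.0, 1.25, 0.05, params)
        assert QC == pytest.approx(1.475, abs=1e-12)
        assert QR == pytest.approx(5.0, abs=1e-12)
        assert Qr == pytest.approx(2.1, abs=1e-12)

    def test_no_feedback_limit(self, params):
        # f = 0 removes the PI dependence entirely
        p0 = params.with_(f=0.0)
        for P3 in (0.0, 0.05, 7.0):
            out = activation_rates(1.0, 3.0, 1.25, P3, p0)
            ref = activation_rates(1.0, 3.0, 1.25, 0.05, p0)
            assert out == pytest.approx(ref)

    def test_strong_rho_silences_cdc42(self, params):
        QC, _, _ = activation_rates(1.0, 3.0, 1e6, 0.05, params)
        assert QC < 1e-12

    def test_rejects_negative_concentrations(self, params):
        with pytest.raises(ValueError):
            activation_rates(-0.1, 3.0, 1.25, 0.05, params)

    @given(f=st.floats(0.0, 1.0), P3=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_feedback_continuous_and_basal_independent(self, f, P3):
        p = ParameterSet(f=f)
        QC, QR, Qr = activation_rates(1.0, 3.0, 1.25, P3, p)
        assert np.isfinite([QC, QR, Qr]).all()
        # at P3 = P_3b the output cannot depend on f
        QCb, QRb, Qrb = activation_rates(1.0, 3.0, 1.25, p.P_3b, p)
        ref = activation_rates(1.0, 3.0, 1.25, p.P_3b, ParameterSet(f=0.0))
        assert (QCb, QRb, Qrb) == pytest.approx(ref)


class TestGtpaseRhs:
    def test_basal_hand_values(self, params, basal_levels):
        st_ = state_from(basal_levels)
        q = activation_rates(st_.C, st_.R, st_.rho, st_.P3, params)
        dC, dCi, dR, dRi, dr, dri = gtpase_reaction_rhs(st_, *q, params)
        assert dC[0] == pytest.approx(1.475 * (1.4 / 2.4) - 1.0, abs=1e-12)
        assert dR[0] == pytest.approx(0.0, abs=1e-12)  # Q_R·(Ri/R_tot) = 3 exactly
        assert dCi[0] == -dC[0] and dRi[0] == -dR[0] and dri[0] == -dr[0]

    @given(st.lists(st.floats(0.0, 10.0), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_pointwise_mass_conservation(self, levels):
        # reaction terms move mass only between active and inactive forms
        p = ParameterSet()
        st_ = state_from(levels)
        d = reaction_rhs(st_, p)
        for a, i in ((0, 1), (2, 3), (4, 5)):
            assert d[a] + d[i] == pytest.approx(0.0, abs=1e-14)


class TestPiRhs:
    def test_calibrated_basal_fixed_point(self, params, basal_levels):
        lv = basal_levels.copy()
        lv[6] = 50.0  # basal P1 (the standard *initial* P1 is 55)
        dP1, dP2, dP3 = pi_reaction_rhs(state_from(lv), params)
        assert abs(dP1[0]) < 1e-12 and abs(dP2[0]) < 1e-12 and abs(dP3[0]) < 1e-12

    def test_basal_p2_p3_fluxes_balance(self, params):
        # κ23·P_2b == κ32·P_3b (enzyme-level independent ratio)
        assert params.kappa23 * params.P_2b == pytest.approx(
            params.kappa32 * params.P_3b)

    def test_pure_decay_limit(self, basal_levels):
        p = ParameterSet(I_P1=0.0, kappa12=0.0, kappa21=0.0, kappa23=0.0, kappa32=0.0)
        dP1, dP2, dP3 = pi_reaction_rhs(state_from(basal_levels), p)
        assert dP1[0] == pytest.approx(-p.delta_P1 * 55.0)
        assert dP2[0] == 0.0 and dP3[0] == 0.0


class TestWellMixed:
    def test_pi_subsystem_steady_state_is_basal(self, params):
        P1, P2, P3 = pi_steady_state(params)
        assert P1 == pytest.approx(50.0, abs=1e-9)
        assert P2 == pytest.approx(30.0, abs=1e-9)
        assert P3 == pytest.approx(0.05, abs=1e-12)

    def test_fixed_point_is_consistent(self, params):
        C, R, rho, P1, P2, P3 = wellmixed_steady_state(params)
        # residual of the reaction system at the returned point ~ 0
        lv = [C, params.C_tot - C, R, params.R_tot - R,
              rho, params.rho_tot - rho, P1, P2, P3]
        assert np.abs(reaction_rhs(state_from(lv), params)).max() < 1e-8
        # P1* = I_P1/δ_P1 independent of everything else
        assert P1 == pytest.approx(50.0, abs=1e-6)

    def test_no_activation_kills_active_forms(self):
        p = ParameterSet(I_C=0, I_R=0, I_rho=0, alpha=0, beta=0)
        C, R, rho, *_ = wellmixed_steady_state(p)
        assert max(C, R, rho) < 1e-6


class TestParameterSet:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            ParameterSet(f=1.5)
        with pytest.raises(ValueError):
            ParameterSet(d_C=-1)
        with pytest.raises(ValueError):
            ParameterSet(D_m=100.0, D_mc=50.0)

    def test_parameter_file_roundtrip(self, tmp_path):
        f = tmp_path / "params.txt"
        f.write_text("# tweaked run\nn = 4\nf = 0.8  # strong feedback\n")
        p = load_parameters(f)
        assert p.n == 4 and p.f == 0.8
        assert p.I_C == 2.95  # omitted keys keep defaults

    def test_parameter_file_rejects_unknown_key(self, tmp_path):
        f = tmp_path / "params.txt"
        f.write_text("nn = 4\n")
        with pytest.raises(ValueError, match="unknown parameter"):
            load_parameters(f)
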