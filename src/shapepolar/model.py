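"""Reaction kinetics of the nine-species polarization network.

Three Rho GTPases (Cdc42, Rac, Rho) each cycle between a slowly diffusing
active membrane form (C, R, ρ) and a fast cytosolic inactive form
(Ci, Ri, ρi), with fixed totals per GTPase.  Activation is modulated by
mutual Cdc42–Rho inhibition (Hill exponent n), Cdc42→Rac (α) and
Rac→Rho (β) amplification, and a phosphoinositide feedback of strength
f ∈ [0, 1] in which membrane PIP3 (P3) boosts Cdc42 and Rac activation.
The phosphoinositide layer (P1 → P2 → P3 interconversion, PIP/PIP2/PIP3)
is driven by Rac (kinase side) and Rho (phosphatase side); the lipid
kinases/phosphatases PI5K, PI3K and PTEN are treated as well mixed and
folded into effective first-order rates κ12, κ21, κ23, κ32.

κ12 is calibrated so that the basal lipid levels (P_1b, P_2b, P_3b) =
(50, 30, 0.05) μM are an exact fixed point of the PI subsystem when Rac
and Rho sit at their basal levels:

    κ12 = (I_P1 + κ21 P_2b − δ_P1 P_1b) / P_1b = 0.0084 s⁻¹

Every modulated conversion uses the half-rate convention (κ/2)(1 + X/X_b),
which equals κ exactly at basal X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

__all__ = [
    "ParameterSet",
    "StateField",
    "SPECIES",
    "activation_rates",
    "gtpase_reaction_rhs",
    "pi_reaction_rhs",
    "reaction_rhs",
    "pi_steady_state",
    "wellmixed_steady_state",
    "load_parameters",
]

#: canonical species order used throughout the package
SPECIES = ("C", "Ci", "R", "Ri", "rho", "rhoi", "P1", "P2", "P3")


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic and transport parameters (defaults: standard parameterization).

    Units: concentrations μM, rates s⁻¹ or μM s⁻¹, diffusion μm² s⁻¹.
    """

    # totals and activation inputs
    C_tot: float = 2.4
    R_tot: float = 7.5
    rho_tot: float = 3.1
    I_C: float = 2.95
    I_R: float = 0.5
    I_rho: float = 3.3
    # mutual inhibition and crosstalk
    a1: float = 1.25      # Rho level for half-max inhibition of Cdc42
    a2: float = 1.0       # Cdc42 level for half-max inhibition of Rho
    n: float = 3.0        # Hill coefficient of the mutual inhibition
    f: float = 0.4        # PI-feedback strength, 0 (none) .. 1 (full)
    alpha: float = 4.5    # Cdc42-dependent Rac activation
    beta: float = 0.3     # Rac-dependent Rho activation
    # inactivation
    d_C: float = 1.0
    d_R: float = 1.0
    d_rho: float = 1.0
    # diffusion
    D_m: float = 0.1      # active (membrane) GTPase forms
    D_mc: float = 50.0    # inactive (cytosolic) GTPase forms
    D_P: float = 5.0      # phosphoinositides
    # basal levels
    C_b: float = 1.0
    R_b: float = 3.0
    rho_b: float = 1.25
    # phosphoinositide layer
    I_P1: float = 10.5
    delta_P1: float = 0.21
    kappa12: float = 0.0084   # P1->P2 (PI5K), calibrated, Rac-modulated
    kappa21: float = 0.014    # P2->P1
    kappa23: float = 0.0072   # P2->P3 (PI3K), Rac-modulated
    kappa32: float = 4.32     # P3->P2 (PTEN), Rho-modulated
    P_1b: float = 50.0
    P_2b: float = 30.0
    P_3b: float = 0.05

    def __post_init__(self) -> None:
        for fld in fields(self):
            v = getattr(self, fld.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {fld.name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.D_m > self.D_mc:
            raise ValueError("active forms must not diffuse faster than inactive (D_m <= D_mc)")
        for name in ("C_tot", "R_tot", "rho_tot"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **updates) -> "ParameterSet":
        """Copy with selected parameters replaced."""
        return replace(self, **updates)


def load_parameters(path) -> ParameterSet:
    """Read a flat ``key = value`` parameter file.

    Lines starting with ``#`` (or inline ``#`` comments) are ignored;
    unknown keys raise; omitted keys keep their defaults.
    """
    valid = {f.name for f in fields(ParameterSet)}
    updates: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            updates[key] = float(val)
    return ParameterSet(**updates)


@dataclass
class StateField:
    """The nine concentration fields over a geometry's interior cells.

    Each field is a 1-D array (one value per interior cell, in μM); a
    well-mixed state can be represented with length-1 arrays.
    """

    C: np.ndarray
    Ci: np.ndarray
    R: np.ndarray
    Ri: np.ndarray
    rho: np.ndarray
    rhoi: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray

    def stack(self) -> np.ndarray:
        """(9, N) array in canonical species order."""
        return np.stack([getattr(self, s) for s in SPECIES])

    @classmethod
    def from_stack(cls, Y: np.ndarray) -> "StateField":
        return cls(**{s: Y[i] for i, s in enumerate(SPECIES)})

    def copy(self) -> "StateField":
        return StateField.from_stack(self.stack().copy())

    def validate(self) -> None:
        Y = self.stack()
        if not np.all(np.isfinite(Y)):
            raise ValueError("state contains non-finite values")
        if Y.min() < 0:
            raise ValueError(f"state contains negative concentrations (min {Y.min():.3g})")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def activation_rates(C, R, rho, P3, params: ParameterSet, I_C=None):
    """Activation rates (Q_C, Q_R, Q_ρ) in μM s⁻¹.

    Q_C = [I_C / (1 + (ρ/a1)^n)] · [(1−f) + f·P3/P_3b]
    Q_R = (I_R + αC) · [(1−f) + f·P3/P_3b]
    Q_ρ = (I_ρ + βR) / (1 + (C/a2)^n)          (PIP-independent)

    ``I_C`` may be passed explicitly (scalar or per-cell array) to apply
    the transient stimulus; it defaults to the baseline params.I_C.
    """
    C = np.asarray(C, dtype=float)
    R = np.asarray(R, dtype=float)
    rho = np.asarray(rho, dtype=float)
    P3 = np.asarray(P3, dtype=float)
    low = min(C.min(), R.min(), rho.min(), P3.min())
    if low < -1e-6:
        raise ValueError("activation_rates requires non-negative concentrations")
    if low < 0:  # tolerate integrator round-off, clamp for the Hill powers
        C, R, rho, P3 = (np.maximum(v, 0.0) for v in (C, R, rho, P3))
    p = params
    Ic = p.I_C if I_C is None else I_C
    feedback = (1.0 - p.f) + p.f * P3 / p.P_3b
    Q_C = Ic / (1.0 + (rho / p.a1) ** p.n) * feedback
    Q_R = (p.I_R + p.alpha * C) * feedback
    Q_rho = (p.I_rho + p.beta * R) / (1.0 + (C / p.a2) ** p.n)
    return Q_C, Q_R, Q_rho


def gtpase_reaction_rhs(state: StateField, Q_C, Q_R, Q_rho, params: ParameterSet):
    """Reaction part of the GTPase equations.

    For each GTPase G: dG/dt = Q_G·(Gi/G_tot) − d_G·G and
    dGi/dt = −dG/dt, so active+inactive mass is conserved pointwise.

    Returns (dC, dCi, dR, dRi, drho, drhoi).
    """
    p = params
    dC = Q_C * (state.Ci / p.C_tot) - p.d_C * state.C
    dR = Q_R * (state.Ri / p.R_tot) - p.d_R * state.R
    drho = Q_rho * (state.rhoi / p.rho_tot) - p.d_rho * state.rho
    return dC, -dC, dR, -dR, drho, -drho


def pi_reaction_rhs(state: StateField, params: ParameterSet):
    """Reaction part of the phosphoinositide equations.

    dP1/dt = I_P1 − δ_P1 P1 + κ21 P2 − (κ12/2)(1+R/R_b) P1
    dP2/dt = −κ21 P2 + (κ12/2)(1+R/R_b) P1 − (κ23/2)(1+R/R_b) P2
             + (κ32/2)(1+ρ/ρ_b) P3
    dP3/dt = (κ23/2)(1+R/R_b) P2 − (κ32/2)(1+ρ/ρ_b) P3

    Returns (dP1, dP2, dP3).
    """
    p = params
    kin = 0.5 * (1.0 + state.R / p.R_b)     # Rac-modulated kinase factor
    pho = 0.5 * (1.0 + state.rho / p.rho_b)  # Rho-modulated phosphatase factor
    j12 = p.kappa12 * kin * state.P1
    j21 = p.kappa21 * state.P2
    j23 = p.kappa23 * kin * state.P2
    j32 = p.kappa32 * pho * state.P3
    dP1 = p.I_P1 - p.delta_P1 * state.P1 + j21 - j12
    dP2 = j12 - j21 + j32 - j23
    dP3 = j23 - j32
    return dP1, dP2, dP3


def reaction_rhs(state: StateField, params: ParameterSet, I_C=None) -> np.ndarray:
    """Full pointwise reaction right-hand side as a (9, N) stack."""
    Q_C, Q_R, Q_rho = activation_rates(state.C, state.R, state.rho, state.P3, params, I_C=I_C)
    g = gtpase_reaction_rhs(state, Q_C, Q_R, Q_rho, params)
    pi = pi_reaction_rhs(state, params)
    return np.stack([*g, *pi])


# ---------------------------------------------------------------------------
# space-free oracles
# ---------------------------------------------------------------------------

def pi_steady_state(params: ParameterSet, R=None, rho=None):
    """Algebraic steady state (P1*, P2*, P3*) of the linear PI subsystem
    at clamped Rac/Rho levels (default: their basal levels)."""
    p = params
    R = p.R_b if R is None else R
    rho = p.rho_b if rho is None else rho
    kin = 0.5 * (1.0 + R / p.R_b)
    pho = 0.5 * (1.0 + rho / p.rho_b)
    A = np.array([
        [-p.delta_P1 - p.kappa12 * kin, p.kappa21, 0.0],
        [p.kappa12 * kin, -p.kappa21 - p.kappa23 * kin, p.kappa32 * pho],
        [0.0, p.kappa23 * kin, -p.kappa32 * pho],
    ])
    b = np.array([-p.I_P1, 0.0, 0.0])
    return tuple(np.linalg.solve(A, b))


def _table_initial_levels() -> np.ndarray:
    # standard initial concentrations (uniform resting cell)
    return np.array([1.0, 1.4, 3.0, 4.5, 1.25, 1.85, 55.0, 30.0, 0.05])


def wellmixed_steady_state(params: ParameterSet, t_max: float = 1000.0,
                           residual_tol: float = 1e-8):
    """Fixed point of the space-free (reaction-only) system.

    Integrates from the standard initial concentrations to ``t_max`` s and
    polishes with a Newton solve.  Returns (C*, R*, ρ*, P1*, P2*, P3*).
    Warns (without raising) if the residual norm stays above
    ``residual_tol`` — the signature of an oscillatory regime.
    """
    def rhs(t, y):
        return reaction_rhs(StateField.from_stack(y.reshape(9, 1)), params).ravel()

    sol = solve_ivp(rhs, (0.0, t_max), _table_initial_levels(),
                    method="LSODA", rtol=1e-10, atol=1e-12)
    y = sol.y[:, -1]
    # Newton polish on the non-conserved coordinates: use (C, R, rho, P1, P2, P3)
    # with Ci etc. eliminated through the conserved totals.
    tot_y = np.array([y[0] + y[1], y[2] + y[3], y[4] + y[5]])

    def reduced(z):
        C, R, rho, P1, P2, P3 = z
        full = np.array([C, tot_y[0] - C, R, tot_y[1] - R, rho, tot_y[2] - rho, P1, P2, P3])
        d = rhs(0.0, full)
        return d[[0, 2, 4, 6, 7, 8]]

    z = fsolve(reduced, y[[0, 2, 4, 6, 7, 8]], full_output=False)
    res = np.linalg.norm(reduced(z))
    if res > residual_tol:
        warnings.warn(
            f"well-mixed system did not settle to a fixed point "
            f"(residual {res:.3g} μM/s after {t_max} s); possibly oscillatory",
            RuntimeWarning,
        )
        z = y[[0, 2, 4, 6, 7, 8]]
    return tuple(float(v) for v in z)
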