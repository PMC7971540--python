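# Methods

## The model

`shapepolar` simulates a mass-conserved reaction–diffusion ("wave
pinning") model of cell polarization on static two-dimensional cell
shapes.  Nine concentration fields evolve on the cell interior:

* three Rho GTPases — Cdc42 (`C`), Rac (`R`) and Rho (`ρ`) — each
  cycling between a slowly diffusing active membrane form and a fast
  cytosolic inactive form (`Ci`, `Ri`, `ρi`), with the total amount of
  each GTPase conserved;
* three phosphoinositides — PIP (`P1`), PIP2 (`P2`), PIP3 (`P3`) —
  interconverting on the membrane.

For each GTPase `G` with activation rate `Q_G`, inactivation rate `d_G`
and active/inactive diffusivities `D_m ≪ D_mc`:

    ∂G/∂t  =  Q_G · (Gi/G_tot) − d_G·G + D_m ΔG
    ∂Gi/∂t = −Q_G · (Gi/G_tot) + d_G·G + D_mc ΔGi

The activation rates encode mutual Cdc42–Rho inhibition (Hill
exponent `n`), Cdc42→Rac (`α`) and Rac→Rho (`β`) amplification, and a
PIP3 feedback of strength `f ∈ [0, 1]`:

    Q_C = [I_C / (1 + (ρ/a1)^n)] · [(1−f) + f·P3/P_3b]
    Q_R = (I_R + α·C)            · [(1−f) + f·P3/P_3b]
    Q_ρ = (I_ρ + β·R) / (1 + (C/a2)^n)          (PIP-independent)

The lipid layer is driven by Rac on the kinase side and Rho on the
phosphatase side, each conversion using a half-rate modulation
`(κ/2)(1 + X/X_b)` that equals `κ` exactly at the basal level `X_b`:

    dP1/dt = I_P1 − δ_P1·P1 + κ21·P2 − (κ12/2)(1+R/R_b)·P1
    dP2/dt = −κ21·P2 + (κ12/2)(1+R/R_b)·P1 − (κ23/2)(1+R/R_b)·P2
             + (κ32/2)(1+ρ/ρ_b)·P3
    dP3/dt = (κ23/2)(1+R/R_b)·P2 − (κ32/2)(1+ρ/ρ_b)·P3

(plus `D_P Δ` diffusion for each lipid).  Two transcription ambiguities
in the source equations were repaired on mass-balance grounds: the Rho
Hill term divides `Q_C` (Rho *inhibits* Cdc42 — `a1` is defined as the
Rho level for half-maximal inhibition), and the PTEN term removes PIP3,
not PIP (its appearance with `P1` in the PIP2 equation does not balance
the PIP3 equation, and PTEN dephosphorylates PIP3→PIP2).

### Effective lipid rates and calibration

The lipid kinases/phosphatases PI5K, PI3K and PTEN are treated as
well-mixed and folded into effective first-order rates.  With the
second-order rate constants and a 10 μM enzyme level, `κ23 = 0.0072 s⁻¹`
and `κ32 = 4.32 s⁻¹`; their ratio fixes the basal PIP3 level and is
enzyme-level independent.  Folding PI5K literally the same way is
inconsistent with the stated basal lipid levels (it would imply a basal
PIP2 of ~3000 μM instead of 30 μM), so `κ12` is instead calibrated so
the basal levels (P_1b, P_2b, P_3b) = (50, 30, 0.05) μM are an exact
fixed point of the lipid subsystem at basal Rac/Rho:

    κ12 = (I_P1 + κ21·P_2b − δ_P1·P_1b) / P_1b = 0.0084 s⁻¹

All κ values are plain parameters and can be overridden in a parameter
file or `ParameterSet`.

### The resting state is not a fixed point

With the standard parameter set the uniform resting state drifts: the
baseline Cdc42 input (2.95 μM s⁻¹, the post-stimulus rate) is too small
to hold active Cdc42 at its nominal basal 1 μM (that would require
≈3.43 μM s⁻¹; the Rac and Rho inputs, by contrast, are exactly
consistent with their basal levels).  The space-free system therefore
relaxes to (C*, R*, ρ*) ≈ (0.633, 2.071, 1.557) μM — verified
independently with `scipy` (LSODA + Newton polish) and R/`deSolve` —
rather than to (1, 3, 1.25).  `wellmixed_steady_state` reports the true
fixed point; basal levels enter the kinetics only through the
modulation factors.

### Unbounded local amplification

The cross-activation terms are linear (`α·C`, and a feedback factor
linear in PIP3), so nothing caps the local activation loop
C → Rac → PIP3 → C.  In 50 μm cells the late-time dynamics concentrate
active Cdc42 into a narrow, slowly intensifying peak that can exceed
20–30 μM (an order of magnitude above the total concentration — local
active density is not bounded by the mean because the inactive pool is
shared through fast cytosolic diffusion).  These near-stationary sharp
peaks are metastable on very long timescales and effectively pin the
polarization pattern in place; with the feedback off (`f = 0`) maxima
stay near 2 μM and fronts remain mobile.  This strongly shapes which
long-horizon qualitative outcomes the simulation reproduces (see
"Known limitations").

## Geometry

Cell outlines follow micropattern confinement shapes: symmetric
(circle, ellipse, square, rectangle — two mirror axes) and asymmetric
(teardrop, narrow drop, wide drop, triangle — one mirror axis, blunt
end at +x).  The drops are a blunt half-ellipse joined to a triangular
tail; the blunt cap occupies 1/2 (teardrop), 1/3 (narrow drop) or 2/3
(wide drop) of the length, capped by the half-width.  These proportions
are approximations of the published outlines, which are not available
in parametric form; arbitrary outlines can be supplied as PNG/PGM masks
(`import_mask`).  Shapes are rasterized at cell centers on an
`n_mesh × n_mesh` square grid (default 110) with spacing
`h = max(L, W)/(n_mesh − 2)`, i.e. the longest extent plus a two-cell
margin spans the grid; rasterization uses centered, rounded coordinates
so masks are exactly mirror-symmetric, and pointed tails keep a minimal
one-cell spine so the bounding box is preserved at any mesh.

## Stimulus

Polarization is triggered by transiently replacing the Cdc42 activation
input with a linear gradient, `I_C = b + m·x` for `t ≤ τ` and a uniform
`I_C` afterwards (standard: `2.6 + 0.05·x` μM s⁻¹ for 10 s, then
2.95 μM s⁻¹), with `x` measured from the upstream edge of the shape's
bounding box so the stimulus range adapts to cell size.  Direction
naming puts the prospective front at the second letter: L-R stimulates
toward +x, R-L toward −x, U-D toward −y (the vertical sign is a
convention; the geometry is mirror-symmetric about the horizontal
midline, so outcomes are sign-invariant).

## Numerics

Two interchangeable integrators advance the nine fields; both use the
same 5-point finite-volume Laplacian on the mask with zero-flux faces
(rows and columns sum to zero, so diffusion is discretely conservative;
the discrete cosine mode on a strip decays within 0.01% of the analytic
Neumann rate at 110 cells).

**Strang splitting (default).**  Half-step RK4 reaction, full-step
Crank–Nicolson diffusion with cached sparse LU factors, half-step RK4
reaction.  Step sizes live on a dyadic ladder `dt_max/2^k` (times
bookkept in integer dyadic units so alignment never degrades) and are
controlled by step doubling with a weighted-RMS tolerance test plus
local Richardson extrapolation; requested output times are hard step
targets, so the stimulus switch-off is hit exactly.  Because reactions
move mass only between the active and inactive form of the same GTPase
and the diffusion solve is conservative, per-GTPase totals are
conserved to ~1e-14 relative over 1000-s runs.  A step whose total
solution change is below the tolerance scale is accepted regardless of
the splitting-error estimate: near-stationary pinned peaks carry a
persistent O(dt²) splitting bias that would otherwise pin the step size
even though the trajectory no longer moves.

**Fully implicit BDF (method="bdf").**  A method-of-lines formulation
solved with SciPy's variable-order BDF using a colored-finite-difference
sparse Jacobian (9×9 reaction blocks per cell plus the diffusion
stencils), integrating in segments split at the stimulus discontinuity.
This is the efficient path for long runs dominated by slowly evolving
sharp peaks (a 1000-s teardrop at 72² costs ~2 minutes; the split
integrator needs ~100× more steps in that regime).  The two routes
agree to <0.5% on transients and to ~0.1% on 1000-s endpoints, which we
use as a routine cross-validation; BDF mass drift is bounded by its
truncation error (≈5e-9 relative at rtol 1e-4 over 1000 s).

Default tolerances follow the reference solver settings (abs 1e-9,
rel 1e-7).  Production runs use looser, verified-converged settings:
rel 1e-4/abs 1e-7 for 30-s transients (the 30-s circle maximum moves by
<0.03% when tightened to rel 1e-6, by <0.1% when loosened to rel 1e-3,
and by <0.4% from 110² to 160² and 220² meshes) and rel 1e-4 BDF for
1000-s sweeps.  The 1000-s qualitative anchors in the acceptance suite
run at coarse meshes chosen once for throughput (44² for the teardrop
anchors, 36² for the circle phase-slice and rectangle anchors); the
categorical labels were checked against 48²/72² runs.  One caveat: the
lifetime of *metastable multi-front* states is inherently sensitive to
mesh and solver noise (such states are long-lived saddle-like
configurations), so whether a given multi-front transient has merged by
a fixed horizon can differ between meshes; the classify-then-extend
rule (re-examine at 3000 s) absorbs most, but not all, of this.

Degenerate maxima (plateaus) are reported as the centroid of all cells
within `abs_tol` of the maximum, with a degeneracy flag.  Fields are
clipped at zero with a logged warning if an undershoot exceeds
`abs_tol`; RK stages evaluate rates on the non-negative part of the
state.

## Classification

A run is summarized by the final active-Cdc42 field and the 1-s cadence
track of its maximum: *uniform* if max−min < 0.01 μM; otherwise the
final polarization axis is whichever axis has the steeper projected
concentration range, and the outcome is *normal* if the maximum lies
within 2 grid cells of the cell extremity along that axis (for the
stimulus axis, the stimulated-front extremity specifically), else
*reverse*.  Fronts are 4-connected components above a display threshold
(3 μM; 8 μM for large-cell regimes).  ΔC is the drop from the on-axis
maximum to the front-extremity concentration.  Onset of reversal is the
first recorded time the maximum retreats by more than one grid cell
from its running frontmost position (the alternative "retreat from the
initial position" rule is available via the running-extreme definition
being a maximum over the whole history).  Classification is invariant
under mirroring both the mask and the protocol.

## Sweeps

Aspect-ratio sweeps classify one run per (length, width); runs ending
with more than one front at 1000 s are re-run to 3000 s (unresolved
multi-front transients are metastable and usually merge).  The 1D
sensitivity module varies one parameter at a time around the standard
set; the phase diagrams label an (a1, d_C) lattice at n = 1, 4, 8.
All runs are deterministic and order-independent; there is no
randomness anywhere in the pipeline (the config schema reserves a seed
field for future stochastic extensions, unused).

## What the generator emulates — and what it does not

The geometry module is the synthetic-data generator of this study: it
emulates confined micropattern cell shapes as ideal, static, binary
masks.  It does not emulate membrane fluctuations, adhesion
heterogeneity, cytoskeletal mechanics or 3D effects, so passing tests
demonstrate properties of the reaction–diffusion model on ideal
geometries, not predictions about real motile cells.

## Known limitations

* The unbounded local amplification described above means long-horizon
  (≥100 s) maxima reach tens of μM and polarization patterns freeze
  once a peak forms.  Reported early-transient quantities (≤30 s) are
  mesh- and tolerance-converged; the late-time *labels* are robust
  across meshes but inherit this freezing behavior.  In particular, a
  perpendicular (U-D) stimulus on a teardrop does not re-orient onto
  the long axis here, and some medium teardrops retain two frozen
  fronts at 3000 s; with feedback off (f = 0) fronts remain mobile.
* Quantitative early-transient values differ from the reference
  implementation of record (e.g. the 30-s circle maximum is 4.23 μM
  here vs 3.3 μM reported, and the maximum detaches from the front only
  after the 10-s stimulus ends): the original lipid-layer
  implementation is not fully recoverable from its published equation
  set (enzyme folding and two transcription defects), and the
  calibrated reading adopted here is the one consistent with all three
  printed basal lipid levels.
* The drop/teardrop outlines are parametric approximations.
* No cell mechanics, no moving boundaries, no 3D bulk-surface coupling.
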