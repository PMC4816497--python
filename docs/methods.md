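# Methods

## Scope and modelling assumptions

`cardioib` simulates one pressurized beat of an isolated left ventricle
immersed in fluid: a diastolic inflation to an assumed end-diastolic
pressure, followed by systolic activation (pressure raised to the
end-systolic value while the intracellular calcium is raised to its peak
and held) until the mechanics reach a steady state. There are no valves,
atria, pericardium, electrophysiological propagation or residual
stresses; calcium is spatially uniform and analytic. The reference
configuration is the unloaded early-diastolic geometry, taken stress
free. Fluid and solid share density (1.0 g/ml) and viscosity, as the
classical IB formulation assumes.

All internal quantities are CGS (cm, g, s, dyne/cm²); material constants
and pressures are configured in kPa and mmHg and converted once
(1 kPa = 1e4 dyne/cm², 1 mmHg = 1333.22 dyne/cm²). The blood viscosity
default is 0.04 g/(cm·s) = 4 cP; the value is sometimes quoted in cP
with the same numeral, which would be two orders below water and is not
used here.

## Structural model

Passive elasticity is the orthotropic Holzapfel–Ogden energy with
clamped anisotropic invariants `I4i* = max(I4i, 1)`; collagen fibres
store energy only in extension, and the derivative at the clamp is taken
one-sided from below (zero), giving continuous stresses. The working
first Piola–Kirchhoff stress

    P~p = dW/dF + { -a exp[b(I1-3)] + beta_s log(I3) } F^{-T}

contains (i) a pressure-like term that makes the reference configuration
exactly stress free and (ii) a volumetric penalty `beta_s log(I3)` that
reinforces incompressibility of the spatially discretized wall (the
continuous formulation is incompressible through `div u = 0`, but the
interpolated Lagrangian velocity field is not discretely divergence
free). In infarcted tissue the entire material response is scaled by
`(1 + 49 M)`; the `beta_s` penalty is deliberately *not* scaled, since
it is a discretization device rather than a material property. Active
stress is `P_a = J T F f0 (x) f0` (Cauchy form `T f (x) f`), with `T`
ablated by `(1 - M)`.

Healthy constants (kPa / dimensionless): a = 0.24, b = 5.08,
a_f = 1.46, b_f = 4.15, a_s = 0.87, b_s = 1.6, a_fs = 0.3, b_fs = 1.3;
beta_s = 100 kPa (cluster presets). The MI parameter set scales
(a_f, a_s, a_fs) jointly by C_a^MI (preset 7.5), mirroring how the
diseased model's anisotropic response is estimated from the measured
end-diastolic volume.

## Active tension

The excitation–contraction model is the Niederer–Hunter–Smith (2006)
myofilament description: calcium–troponin binding with tension-dependent
unbinding, tropomyosin activation `z` with nonlinear relaxation, a
length-dependent maximum tension `T_ref (1 + beta_0 (lambda - 1))`, a
length-dependent calcium sensitivity (`beta_1`), and three fading-memory
crossbridge variables responding to the stretch rate. Constants:
T_ref = 56.2 kPa, beta_0 = 4.9, beta_1 = −4, Ca_50ref = 1.05 µM,
Ca_TRPN_max = 70 µM, k_on = 100 /µM/s, k_off_ref = 200 /s, gamma = 2,
alpha_0 = 8 /s, alpha_r1 = 2 /s, alpha_r2 = 1.75 /s, n = n_rel = 3,
K_z = 0.15, a = 0.35, A = (−29, 138, 129), alpha_Q = (30, 130, 625) /s.
Stretch is valid on [0.8, 1.15]; 1.0 is the resting and 1.15 the maximum
sarcomere length. Under saturating calcium the steady isometric tension
is `T_ref (1 + beta_0 (lambda - 1))` up to the calcium occupancy of
troponin, i.e. 56.2 kPa at rest and ≈97.5 kPa at maximum length; scaled
by the estimated contractilities (3.0 healthy, 5.5 patient) this gives
168.6 / 309.1 kPa at rest and ≈292 / ≈536 kPa at maximum length.

Two numerical choices differ from common practice and are intentional:

* `z_max(lambda)` (the normalization of the isometric tension) is the
  exact root of the tropomyosin steady state at troponin saturation,
  found by Brent's method and tabulated over the stretch window, instead
  of the customary linearization about z_p = 0.85; the difference is
  O(1e−3) and the exact form keeps the saturating steady tension
  consistent with the length-dependence factor.
* The ODEs are integrated by forward Euler with automatic sub-stepping
  keeping the fastest local rate below 0.25 per substep; a fine-step
  adaptive integration (scipy `solve_ivp`) serves as the reference in
  the tests.

The driving transient is `Ca(t) = Ca_b + (Ca_peak - Ca_b)(t/tau)
exp(1 - t/tau)` (baseline 0.09 µM, tau 60 ms); the systolic protocol
uses its sustained variant (held at the peak). The default peak of
4 µM near-saturates the shortened myocardium, which reproduces the
regime where mean systolic active tension sits near 80 kPa at
contractilities around 3.

## Anatomy generator

The Lagrangian anatomy is the wall between two confocal truncated
ellipsoids (long axis z, open base, closed apex), meshed on a structured
azimuth × longitude × transmural lattice whose hexahedra are split into
tetrahedra; the apical ring collapses onto per-layer axis nodes. The
last ring is kept at polar angle ≥ 0.45 rad from the apex so the apex
cap stays well shaped — collapsing rings all the way to the pole
produces pancake slivers whose penalty forces destabilize the explicit
coupling. Fibre/sheet frames rotate linearly across the wall (helix
−60°→+60°, sheet −45°→+45°) in the local
circumferential/longitudinal/transmural basis of the ellipsoid
parametrization; the transmural coordinate is the lattice coordinate,
which is exact for generated meshes. Regional reporting follows the
7-slice division (6 azimuthal segments on slices 1–5, 4 on the apical
slices 6–7), assigning every point to its nearest slice plane.

The synthetic infarct is a connected septal sector plus apical cap
(defaults emulate a scar of ≈60% of the wall volume). The extent field
is `M = 1` inside, `1 − d/l_bz` across the border zone (l_bz = 10 mm)
and 0 beyond, with `d` the exact Euclidean point-to-triangle distance to
the scar's triangulated boundary.

What the generator does **not** emulate: patient-specific shape (no
segmentation-derived surfaces), regional wall-thickness variation,
trabeculation, the imaging-derived scar geometry, or fibre dispersion.
Tests passing on this anatomy demonstrate the mechanics, coupling and
estimation machinery; they do not validate patient-specific strain
magnitudes.

## Discretization and coupling

* **Fluid**: uniform MAC grid; explicit centered advection and
  viscosity; exact pressure projection by fast DST (open boundaries:
  zero tangential velocity + zero normal traction, which pins p = 0 on
  the boundary) or FFT (periodic verification mode). Discrete divergence
  after projection is at roundoff. Centered (rather than upwind-biased)
  advection keeps the scheme second order; the resolved regimes are
  viscous-dominated.
* **Structure**: linear tetrahedra, total-Lagrangian weak form with test
  functions free on the boundary; endocardial pressure as a follower
  load on the deformed surface; basal tethering as a displacement
  penalty on the axial and circumferential components only (radial
  free), stiffness `kappa` per node chosen so basal in-plane motion
  stays below ~1% of wall thickness in inflation.
* **Transfer**: Peskin four-point kernel; forces are spread from
  per-element barycentric quadrature lattices refined so point spacing
  resolves the grid (weights sum exactly to element volumes), and — the
  one choice that matters most for stability — structure nodes move with
  the *lumped-L2 projection* of the quadrature-point velocities, the
  exact adjoint of the force interpolation. Interpolating velocities
  directly at the nodes makes the discrete force→motion loop indefinite
  and is violently unstable for sub-kernel-scale deformation modes.
* **Time stepping**: explicit midpoint (RK2) for the coupled update;
  the contraction ODEs advance once per step with the per-element fibre
  stretch and its backward-difference rate.
* **Relaxation aids** (steady-state protocols only): an optional
  Lagrangian drag force `−gamma v` (Brinkman-style, desk presets
  gamma = 300 dyne·s/cm per cm³) damps structural modes below the kernel
  scale that fluid viscosity cannot reach, and the desk fluid viscosity
  is raised to 1.0 g/(cm·s). Neither affects the steady states being
  sought, only the transient toward them.

## Problem sizes

Two families of presets ship:

* **Cluster reference** (`healthy`, `mi-patient`): 96×96×128 grid over a
  15×15×20 cm box (dx = 0.156 cm), beta_s = 1e6 dyne/cm², mu = 0.04,
  diastolic/systolic dt = 1.22e−4 / 3.0e−5 s, quadrature at two points
  per mesh width, measured volume targets 143/61 ml (healthy) and
  116/86 ml (patient). These carry the subject-derived conditions and
  are not run by the test suite.
* **Desk** (`desk`, `desk-mi`): a thick-walled small LV (endocardial
  radius 1.1 cm, wall 0.9 cm, length 2.8 cm, ≈800 tets) on a 20×20×28
  grid over 6×6×8.4 cm (dx = 0.3 cm), beta_s = 5e5 dyne/cm²,
  dt = 1.5e−4 / 1.0e−4 s, quadrature density 0.5 points per mesh width.
  The wall must span at least ~3 grid cells: thinner walls fall inside
  the four-point kernel's footprint, opposing transmural forces blur
  together on the grid, and the wall becomes spuriously compressible.
  Desk loading is 8/40 mmHg (healthy) and 16/60 mmHg (infarcted) with
  contractilities of order 1; a desk beat runs in ~2 minutes on one CPU
  and reproduces the qualitative mechanics (shortening signs, wall
  thickening, base-to-apex twist, post-MI hypokinesis), not the
  patient-scale volumes.

## Parameter estimation

`T_scale` is bisected against a target end-systolic volume (each
evaluation restarts systole from a snapshot of the end-diastolic state);
for the infarcted model, the anisotropic multiplier C_a^MI is bisected
against the end-diastolic volume first, then T_scale — both maps are
monotone over sensible brackets. The convergence criterion is the
volume tolerance (default 5%, matching how such models are matched to
imaging-derived volumes), not a parameter tolerance. The pipeline is
fully deterministic; the only random numbers anywhere are in tests and
in the acceptance script's sampling of deformation gradients.

Steady states are declared when the relative cavity-volume change over a
trailing window falls below a tolerance (desk: 0.3% over 20 ms) after
the loading ramp; ramp durations (diastolic 40 ms, systolic 30 ms at
desk scale) are configuration values, as the loading history before
steady state is not part of the estimate.

## Known limitations

* The desk anatomy is geometrically crude; strain magnitudes are
  resolution-dependent even though their signs and ordering are robust.
* Explicit coupling restricts the stable time step through the penalty
  stiffness and the smallest element; the apex cap is the usual binding
  constraint.
* The open-boundary condition set radiates pressure waves out of the
  box; it is appropriate for the quasi-static protocol phases used here,
  not for acoustics.
* Fibre stress reported from pure-structure analyses omits the fluid
  pressure contribution `−p I` unless a pressure field is supplied.
* With the basal plane tethered in-plane, basal rotation is suppressed
  by construction, so reported twist is relative to an almost fixed
  base.
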