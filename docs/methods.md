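# Methods

`pttsim` simulates photothermal therapy (PTT) of a squamous cell carcinoma
embedded in layered skin: gold nanorods injected into the tumor absorb a
1064 nm continuous-wave laser, the absorbed light becomes a volumetric heat
source, and the goal is to hold the tumor inside the apoptosis temperature
band (43–50 °C) for the 600 s treatment while sparing the surrounding
normal tissue. This note records the models, the numerical choices, and the
limits of what the test suite demonstrates.

## Scenario

A cylinder of tissue (radius 10 mm, depth 20 mm) contains four skin layers
(epidermis 0.08 mm, papillary dermis 0.5 mm, reticular dermis 0.6 mm,
subcutaneous fat below). The tumor is modeled as a right cylinder, 3 mm in
diameter and 2 mm deep, flush with the surface on the axis; the published
description gives only its diameter and depth, so the cylinder-versus-
spheroid choice is ours and is isolated in `domain.build_domain`. The
nanoparticle suspension occupies a 1 mm-radius sphere centered at 1 mm
depth — it touches both the skin surface and the tumor base. All tissue
thermal and optical properties are pinned, with their parse documented, in
`constants.py`.

The domain is voxelized on a 3-D Cartesian grid (default Δx = 0.2 mm)
because oblique beams break axial symmetry; the cylinder is embedded in a
box and voxels outside it are inert. The 0.08 mm epidermis is thinner than
the default voxel, so the top voxel layer carries volume-weighted blended
epidermis/papillary properties; at Δx ≤ 0.08 mm it is resolved exactly.
The AuNP sphere mask is clipped to the tumor mask: its bottom pole lies
exactly on the tumor base plane and voxel-center rounding could otherwise
place it one voxel outside.

## Nanoparticle optics

Efficiencies of individual particles come from a coupled-dipole (DDA)
solver: cubic-lattice dipoles with Clausius–Mossotti polarizability plus
the radiative-reaction correction (switchable to plain Clausius–Mossotti),
a dense interaction matrix solved directly below ~1200 dipoles and by
preconditioned BiCGSTAB above, and the standard optical-theorem /
dissipation-sum cross-sections with `C_sca = C_ext − C_abs` by
construction. The lattice constant is rescaled after site selection so
that `N d³` equals the particle volume exactly, which keeps the effective
radius of the discretized particle identical to the nominal one. A
Bohren–Huffman Mie series (`optics.mie`) is the independent closed-form
oracle.

**Known limitation — gold in the NIR.** At 1064 nm gold has
ε ≈ −49.9 + 3.85i. The staircased dipole lattice supports spurious corner
surface-plasmon modes that resonate near large negative Re ε and dominate
the (small) absorption efficiency; the error is several-fold and
non-monotone in dipole count at any desk-scale resolution. We verified
this with dense direct solves up to ~3000 dipoles and with filtered- and
integrated-Green's-function variants; none repaired it. The solver is
therefore validated against Mie on well-conditioned materials (absorbing
dielectrics converge at 1–2 %) and by structural invariants (extinction
identity, lossless materials absorb nothing, rotation invariance, Rayleigh
limit), and the DDA gold-sphere comparison is kept as a failing check
rather than silently relaxed. None of the treatment results depend on it:
the composite tumor optics below are calibrated to the tabulated
coefficients.

Dilute suspensions mix by the independent-scattering rule
`μ_abs,np = 0.75 f_v Q_abs / r_eff` (and likewise for scattering, reduced
by `1 − g_np`), added to the host coefficients; the relation is exactly
linear in the volume fraction `f_v`. The AuNP-loaded tumor coefficients at
the four study fractions (10⁻³…10⁻⁶) are tabulated; inverting the rule on
the densest fraction gives `Q_abs = 50.163` at 1064 nm, which regenerates
the other three absorption entries to the printed precision. The tabulated
*reduced-scattering* column is **not** linear in `f_v` although the rule
says it must be; we implement the rule as stated, use the tabulated values
verbatim for the AuNP region, and do not chase the inconsistency. The rod
anisotropy `g_np` is never printed; it defaults to the tumor's 0.8, and in
transport the composite scatters with the host Henyey–Greenstein `g` with
`μ_sca` chosen to preserve the summed reduced scattering (similarity
relation).

## Photon transport

A weighted-packet voxel Monte Carlo: azimuth uniform (`ψ = 2πξ`),
deflection from the Henyey–Greenstein inverse CDF (isotropic at `g = 0`),
free paths exponential in optical depth consumed piecewise across voxels
of differing extinction, per-interaction deposition `ΔW = W μ_abs/μ_ext`,
Russian roulette below weight 10⁻⁴ with survival probability 0.1. Voxel
indices are tracked explicitly and stepped at face crossings; recomputing
them from a nudged position can stall when a packet moves nearly parallel
to a face. The energy ledger
(deposited + escaped + roulette-killed − roulette-gains = launched) closes
to round-off and is asserted per run.

The beam is a CW Gaussian with 1/e² intensity radius 1.5 mm; entry points
are sampled in the beam's own cross-section and projected onto the surface
(the footprint stretches by `1/cos φ_a` along the tilt axis), with initial
direction `(sin φ_a, 0, cos φ_a)`. No Fresnel step at the air–skin
boundary: the model's sampling formulas carry no refractive-index term, so
the internal angle equals the irradiation angle. Photons leaving any face
or the cylinder wall escape. A single seeded RNG stream per run keeps
results bit-reproducible for a fixed (seed, photon count); per-case seeds
are derived from a base seed by hashing the case parameters.

The absorbed field is normalized per watt, so the heat source is exactly
linear in beam power. An `r–z` shell reduction is provided as a
cross-check utility for vertical incidence only, where the field is
axisymmetric.

## Bioheat

The Pennes equation `ρc ∂T/∂τ = q + ∇·(k∇T) + ρ_b ω_b c_b (T_b − T)` is
integrated by conservative finite volumes with harmonic-mean face
conductivities. Default scheme: explicit FTCS at 0.9× the per-voxel
stability limit; a backward-Euler option (conjugate-gradient solves,
intended for coarse grids) agrees with it to < 0.1 °C. A vectorized
reference step backs the compiled kernel and the two are asserted equal.

Blood constants are not part of the published property table; we use
ρ_b = 1050 kg/m³, c_b = 3617 J/kg·K, T_b = 37 °C (standard literature
values, configurable). Initial condition 37 °C everywhere; deep and
lateral boundaries clamped to 37 °C; the skin surface is adiabatic by
default. With these defaults the problem is linear in the source, so the
temperature **rise** scales exactly with laser power — the sweep driver
runs one transport and one unit-power transient per (angle, f_v) and
evaluates all 76 powers by scaling, which it also verifies against a
direct rerun.

Verification: exact equilibrium at T_b, per-step energy balance to
round-off on insulated blocks, a 1-D slab against its Fourier series
(< 1 %), and the perfusion-limited uniform-heating transient against its
closed form `T_b + (q/ρ_b ω_b c_b)(1 − e^{−t/τ})`.

Grid convergence: treatment-scale observables (the 2 mm axial probe, the
apoptosis retention ratio) change by < 2 % when the voxel is halved. The
single hottest voxel does **not** converge that fast: the AuNP sphere apex
touches the adiabatic surface and forms a near-singular hot spot whose
peak keeps sharpening under refinement. Point values at that spot should
not be over-interpreted at any fixed grid.

## Treatment metrics

* `θ_A` (apoptosis retention ratio): trapezoidal time average over the
  600 s treatment of the tumor volume fraction inside [43, 50) °C — closed
  below, open above, matching apoptosis between 43 and 50 °C and necrosis
  at or above 50 °C; the convention is configurable.
* `θ_H` (thermal hazard retention value): time- and volume-averaged sum of
  temperature-band weights over the shell of normal tissue within 1 mm
  (50 % of the tumor length) outward of the tumor boundary, computed by a
  Euclidean distance transform and cross-checked against an exhaustive
  scan. The published work defers its band-weighting scheme to an earlier
  reference that does not print it; our default (0 below 43 °C, 1 in the
  apoptosis band, 2 at necrosis temperatures) is an explicit, configurable
  placeholder, so absolute θ_H/θ_eff values are meaningful only relative
  to a chosen weighting.
* `θ_eff = θ_A/θ_H`: the efficacy/safety ratio; a zero-hazard case returns
  a flagged "no-hazard optimum" sentinel rather than dividing by zero.

Snapshots default to 10 s spacing; θ_A is invariant to oversampling of a
piecewise-linear occupancy history and equals brute-force recomputation to
10⁻¹².

## Parametric study

The full grid is 6 angles (0–75°, step 15°) × 4 volume fractions
(10⁻³…10⁻⁶) × 76 powers (0–150 mW, step 2 mW) = 1824 cases; with the
linear-scaling reuse this costs 24 transport+transient pairs. Optima are
taken on the discrete grid, ties broken toward lower power then lower
`f_v`, boundary optima flagged. Results are cached (memory plus optional
on-disk NPZ keyed by a parameter hash), making sweeps resumable and
re-runs recomputation-free.

Problem sizes used by the shipped runs: the acceptance script runs the
reference 0.2 mm voxel grid with 2.5×10⁵ photons per transport (the
integral band metrics are insensitive to photon count at this level — they
agree with 10⁶-photon runs to well under the Monte Carlo noise of a single
voxel); the analysis scripts and most tests use 0.3–0.4 mm grids with
0.5–2×10⁵ photons.

## Fidelity to the published study, and what passing tests show

With no free parameters beyond the documented defaults, the chain
reproduces the study's calibration points closely: θ_A at the vertical
optimum (f_v = 10⁻⁶, 42 mW) within ~0.01–0.04 and at the 75° optimum
(10⁻⁴, 106 mW) within ~0.01, the rising optimal-power trend with angle,
the unimodal θ_A-versus-power curves, the vertical-beam symmetry, and the
oblique-beam shadow corner. Two quantities disagree honestly:

* At intermediate angles (30–60°) our θ_A-versus-power curves peak at
  ~15–20 % higher powers than the published optima (while reaching
  slightly *higher* maxima), so θ_A evaluated at the published optimal
  powers undershoots by up to ~0.04–0.08 depending on resolution. The
  oblique-beam footprint convention (projected and stretched by
  `1/cos φ_a`, which dilutes surface irradiance) is the most likely
  modeling freedom involved; the published description does not specify
  its convention.
* The perfusion on/off probe comparison (vertical, 10⁻⁴, 100 mW) gives a
  grid-stable ~5.9 °C maximum difference at 600 s versus the published
  "about 2 degrees". With an adiabatic surface the surface probe sits in
  the AuNP-sphere apex hot spot (μ_abs = 188 /mm absorbs the beam within
  microns of the surface) and rises ~47 K, and the perfusion effect scales
  with the rise; a ~2 K effect corresponds to a ~15 K probe rise. The
  published figure's absolute temperatures, blood constants and
  boundary/initial conditions are not printed, so this comparison is
  conditional on assumptions the source does not pin down.

The synthetic-data layer (uniform-tissue blocks, piecewise-constant
temperature bands) exists to verify the numerics against closed forms; it
does not emulate biological variability, irregular tumor geometry, or
temperature-dependent properties, so green tests demonstrate correctness
of the stated model, not clinical validity. Known limitations beyond
those above: no Fresnel/refraction option is enabled by default, no
polarization or pulsed-laser physics, no Arrhenius damage kinetics (the
band metrics are the endpoint), and single-particle optics only (no
interparticle electromagnetic coupling).
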