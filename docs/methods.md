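# Methods

This note records the model assumptions, parameter choices, numerical
details and known limitations of `mucoclear`. It is written for a reader who
wants to judge what a result from this package does and does not mean.

## Surface domain

The nasal-cavity wall is represented as an unwrapped planar surface: one
rectangular strip per chamber (anterior vestibule, then a main zone banded
from the shared boundary outward into septum, main passage, olfactory and
maxillary-sinus strips), merging into a single shared nasopharynx strip that
ends at the outlet edge. This mirrors how wall-bound mucus transport is
usually visualised and analysed; no anatomical unwrapping is performed — the
domain is born unwrapped.

Cells are square (default 1 mm) in the plane but carry individual surface
areas, set so that each (region, chamber) group sums exactly to its
configured anatomical area (defaults: vestibule 8.04/8.42, main passage
56.3/54.1, septum 20.8/20.4, olfactory 9.12/9.87, maxillary sinus 15.4/10.9
cm² per chamber, nasopharynx 11.7 cm² shared; total 225.05 cm²). A real
unwrapped surface has non-uniform areal distortion, so a per-cell area is
the natural representation; it also makes the regional bookkeeping exact by
construction.

Only the areas are anatomically constrained; the strip dimensions are free
parameters. Defaults are vestibule length 8 mm, main zone 75 mm, nasopharynx
strip 25 mm, chamber height 90 mm — chosen once so that transit times from
the deposition sites to the outlet at the calibrated mean mucus speed fall
in the physiologically reported ranges (nasopharynx deposits clear within a
minute, septum within tens of minutes, much of the vestibule not within
30 minutes).

The maxillary sinuses carry area for the regional table but are excluded
from the surface flow and never receive deposition; their mucus production
enters through ostium patches (4 mm square, default at 40 % of the main-zone
length) marked inside each chamber's main-passage band. A metric width
factor emulates the local circumference of the real passage: 1 in the
chambers, decaying linearly to 0.4 across the nasopharynx strip, which
accelerates the film the way the converging nasopharynx does.

## Mucus velocity field

At film Reynolds numbers of order 1e-4 inertia is irrelevant, so instead of
a thin-shell Navier–Stokes solve the module solves the source-driven
continuity problem as a potential flow: div(w ∇φ) = −w·s with φ = 0 on the
outlet cells and zero normal flux elsewhere; v = −∇φ. The discretisation is
a 5-point finite-volume scheme with harmonic-mean face weights; the sparse
system is solved directly and the linear residual is required to be below
1e-8 (direct solves land near 1e-13). Faces between the left and right
chamber are closed except inside the nasopharynx strip, where the two walls
merge.

The absolute source strength is not prescribed anywhere; it is calibrated so
the area-weighted mean speed over main passage + septum + olfactory cells is
exactly 6 mm/min (linearity makes this a single rescale). The split of
production between the general mucosa and the ostia is also not prescribed;
the default sends 60 % of the total flux through the ostium patches, which
produces the observed radial flow pattern around the ostia and mean speeds
in the septum band near the calibration target. Mucus density (1000 kg/m³)
and viscosity (12 Pa·s) are carried as metadata: a potential reduction does
not use them, and nothing downstream consumes them.

`check_mass_balance` recomputes the source flux from the per-cell injection
and the outlet flux from the velocities at the outlet column (where the
one-sided gradient makes velocity × face transmissibility equal the discrete
face flux), so a corrupted velocity field is detected, not just a corrupted
potential.

**Recirculation.** The full-physics solve this module replaces produces
recirculation zones near the vestibule and anterior to the ostia; a pure
potential flow cannot (the vestibule is a dead end with no source, so its
potential velocity is essentially zero). A configurable divergence-free
perturbation — stream-function vortices — restores the two behaviours that
matter downstream: vestibule-deposited particles are slowly swept into the
mainstream, and main-passage particles anterior to the ostium detour
anteriorly before clearing. Defaults per chamber: two sweep vortices just
inside the vestibule (σ = 5–6 mm) and one broad vortex in the anterior main
passage (σ = 12 mm), peak speeds 2.5 and 2.0 mm/min. The peaks are kept
comparable to the local drift speed: much stronger vortices create closed
orbits that trap particles permanently, much weaker ones never move the
vestibule deposits. Since the perturbation is divergence-free and
negligible at the outlet, the flux balance is unaffected.

## Spray population and droplet kinetics

Droplet sizes follow the Rosin–Rammler law (retained mass fraction above d
is exp(−(d/d_m)^n)) with d_m = 78 µm, n = 2.7, truncated and renormalised
over 1–150 µm in 150 bins; 200 streams per bin by default (30 000 streams).
Number weights divide bin mass by the single-droplet mass ρ_p π d³/6.

Droplet kinetics implement the discrete-phase equation of motion with
Stokes-drag scaling f_D = (18µ/ρ_p d_p²)(C_D Re_p/24)(u_air − u) and the
Morsi–Alexander piecewise drag table. Two deliberate choices:

- **Reynolds-number density.** The standard discrete-phase form uses the
  gas density in Re_p; that is the default. Formulations are sometimes
  written with the particle density; a `reynolds_density="particle"` toggle
  reproduces that variant, because with water-density droplets the two
  differ by a factor ~800 and silently choosing one would make comparisons
  impossible.
- **Integrator.** Trajectories are integrated with adaptive embedded
  Runge–Kutta (scipy RK45, rtol 1e-10) rather than a fixed-step high-order
  scheme; what downstream tests assert is trajectory accuracy against
  closed forms (exponential velocity relaxation with τ_p = ρ_p d_p²/18µ,
  Stokes terminal velocity), which the adaptive integrator meets to better
  than 0.1 %.

Full in-airway trajectories to deposition are out of scope — they require a
resolved 3-D airflow — so the kinetics exist to make the drag law and its
constants verifiable in analytic flows.

## Synthetic deposition

Deposition is generative, not mechanistic. Each size class (large > 60 µm,
medium 20–60 µm, small < 20 µm) owns a mixture of 2-D Gaussian hot-spots
anchored to named locations in the sprayed (right) chamber: posterior
vestibule / anterior septum band and middle-turbinate tip for large
droplets; a vestibule-lateral lobe, anterior main passage and ostium
vicinity for medium; the nasopharynx tail plus an anterior main-passage
residue for fines. Components are truncated to their region group by
resampling, and the mixture weights are rebalanced once at build time so the
*expected* regional mass split equals the configured targets (79.8 %
vestibule, 19 % main cavity, 1.2 % nasopharynx, at 100 % deposition
efficiency); the realised split then fluctuates only with sampling noise
(≈0.2 % at the default stream count). Hot-spot coordinates are qualitative
reads of reported deposition maps and are configuration, not ground truth.

## Clearance

Deposited droplets are passive surface tracers (at 6 mm/min the film is
quasi-static; droplet inertia and rheological interaction are ignored).
Advection uses midpoint RK2 on the bilinearly interpolated cell-centred
velocity, default step 1–2 s with automatic sub-stepping whenever the
fastest cell would be crossed in one step. Region transitions are located by
12 bisection iterations along the step segment and assigned to the
downstream region (half-open intervals, t_out = next t_in); outlet crossings
are linearly interpolated in time. A step that would land off the surface is
cancelled (slip-wall behaviour). Horizons: 30 min for transport snapshots,
4 h for absorption sweeps ("until cleared or absorbed" is unbounded for
vestibule-trapped particles, so the sweep horizon caps it; by 4 h every
solute in the 1–110 nm range has A(t) ≈ 1, so the cap does not bias the
absorbed totals).

## Absorption

The gel layer (h_g = 10 µm, reflective top, fully absorbing bottom — the
periciliary layer below holds no mucin and is treated as instantaneous
uptake) gives the classical separation-of-variables solution for a unit
Dirac deposit at the surface; integrating the concentration over the layer
gives the absorption function A(t). Deposited droplets dissolve
instantly; each particle runs a single absorption clock from deposition
(diffusion does not pause while the carrier moves), and interval increments
α·m·[A(t_out) − A(t_in)] are credited to the resident region if it absorbs.

Increments accrued while the particle sits on the vestibule are *discarded*
(lost), not deferred: the vestibule's squamous epithelium does not absorb,
and solute released there drains with the mucus. This reading makes the
fast-diffusion limit exact — for solutes small enough that A → 1 within
seconds, total absorption equals the non-vestibule deposited mass fraction —
which is the behaviour the integrated model is expected to show (a ~20 %
plateau for small radii).

Physical constants: mucin fibre radius r_f = 3.5 nm and mesh spacing
r_g = 50 nm in the Obstruction-Scaling model; Boltzmann constant;
temperature and water viscosity default to body temperature values
(T = 310.15 K, µ₀ = 6.913e-4 Pa·s). Temperature and viscosity are
configurable because reported absorption levels for large solutes vary by
about a percentage point between room- and body-temperature water constants.

Numerics: the alternating series for A(t) is truncated when the next term
bounds the remainder below 1e-12 (capped at 10 000 terms, error if not
met); A(0) is exactly 0; below dimensionless time π²D t/4h² = 1e-3 the true
absorbed fraction underflows double precision (< erfc(25)) and 0 is
returned, which keeps the per-particle conservation identity exact. The
cosine series for c(x, t) uses the same magnitude bound. Both are validated
against an explicit finite-difference solve of the dimensionless problem
(500 nodes, mesh ratio 0.4, Dirac mass in the first node) to 1e-4, and
∫c dx = 1 − A(t) holds to 1e-6.

The radius sweep reuses the (radius-independent) passages and recomputes
only D_g and the accounting per radius, vectorised over all intervals.
Dosage conversion to absorbed drug mass is (4/3)π c Σ A_i r_i³ over carrier
droplets of radius r_i at formulation concentration c.

## Pipeline, seeding, outputs

A scenario config aggregates all module configs plus one global seed;
per-stage child seeds are derived by hashing (seed, stage name), so any
stage can be re-run in isolation and the whole run is byte-reproducible.
Outputs are unit-suffixed CSVs plus a JSON manifest with a config hash and
sha256 checksums of every file. Per-stream carrier masses are normalised to
a unit (1 kg) dose; all percentages are percent of dose.

## Problem sizes used in the test suite

The shipped tests run the default scenario with 40 streams per bin (6 000
streams), a 2 s step and the 4 h horizon, and sweep 11 radii across
1–110 nm; the regional-split and qualitative-shape assertions hold across
seeds at this size, with tolerances matching its sampling noise. The
finite-difference cross-check marches once to the largest dimensionless
time and reads out 20 intermediate states.

## What passing tests do and do not show

The generator reproduces the *structure* of real spray experiments —
size-stratified hot-spots, the regional mass split, mass-balanced posterior
transport, the clearance-time ordering between regions, and the two-sided
radius trade-off (absorption rising as vestibule losses convert into
delayed absorption, then falling as clearance outruns diffusion, giving an
interior optimum of total absorption vs solute radius). It does not predict
patient-specific values: hot-spot coordinates, vestibule escape times and
hence the precise location and height of the absorption peak depend on the
real geometry and airflow, which are outside this model. Quantities
downstream of the analytical core (diffusivities, A(t), regional area
percentages, mass balances) are exact to the stated tolerances.

## Known limitations

- Potential-flow mucus: no genuine recirculation; the vortex perturbation
  is a stand-in with hand-placed geometry.
- No turbulent dispersion, droplet breakup/evaporation, or two-way coupling
  in the kinetics; no in-airway deposition prediction.
- No convection inside the gel normal to the wall; dissolution is
  instantaneous; no pharmacokinetic (plasma) stage.
- The vestibule-trapped fraction is sensitive to the vortex layout; only
  the qualitative trends, not its numeric value, should be interpreted.
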