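# mucoclear

Desk-scale simulator of nasal spray drug fate after deposition: droplets
land on the nasal-cavity wall, ride the mucociliary escalator toward the
nasopharynx, and release drug solute that diffuses through the mucin gel
layer into the epithelium. The package answers the question clinicians and
formulators care about: **what fraction of a sprayed dose is absorbed, where,
and how does that depend on the drug solute's macromolecular radius?**

It is aimed at researchers in nasal drug delivery / bioequivalence modelling
who want the post-deposition transport-and-absorption stage as a fast,
scriptable, fully testable model — without a CFD solver or patient geometry.

## Model

Everything lives on an unwrapped 2-D representation of the nasal wall with
labelled anatomical regions (vestibule, main passage, septum, olfactory,
maxillary sinus, nasopharynx) whose areas default to measured values
(225.05 cm² total).

**Mucus flow.** Mucus produced over the mucosa (and entering through the
maxillary ostia) must exit at the nasopharynx. With film Reynolds numbers
~1e-4, the velocity field is the solution of a source-driven continuity
problem — a metric-weighted Poisson equation

    div(w ∇φ) = −w·s,   v = −∇φ,

with a zero-potential outlet and no-flux walls. The source strength is
calibrated so the area-weighted mean speed over the main cavity wall
(excluding vestibules and sinuses) is 6 mm/min.

**Spray.** Droplet sizes follow a Rosin–Rammler distribution
(d_m = 78 µm, spread n = 2.7, 1–150 µm, 150 bins × 200 streams). Individual
droplet kinetics use the discrete-phase equation of motion with
Morsi–Alexander drag, du/dt = f_D + f_G, exercised in prescribed analytic
air flows.

**Deposition.** Size-stratified Gaussian hot-spots reproduce the observed
pattern: large droplets (> 60 µm) impact the posterior vestibule / anterior
septum band and the middle-turbinate tip; only fines reach the nasopharynx.
The mixture is rebalanced so the expected regional mass split is
79.8 / 19 / 1.2 % (vestibule / main cavity / nasopharynx) at 100 % total
deposition.

**Clearance.** Deposited droplets are passive surface tracers advected by
the mucus field (RK2, bilinear interpolation); every region transition is
logged as an interval (region, t_in, t_out) until the particle clears the
outlet or the horizon ends.

**Absorption.** A dissolved solute diffuses 1-D through the gel layer
(thickness h_g = 10 µm; reflective top, absorbing bottom). The cumulative
absorbed fraction is the series

    A(t) = 1 − (4/π) Σₙ (−1)ⁿ/(2n+1) · exp(−(2n+1)²π² D_g t / (4 h_g²)),

with gel diffusivity from the Obstruction-Scaling model,
D_g = D₀·exp(−(π/4)((r_s+r_f)/(r_g+r_f))²) (mucin fibre radius
r_f = 3.5 nm, mesh spacing r_g = 50 nm), and D₀ = k_B T/(6π µ₀ r_s) from
Stokes–Einstein. A particle passing through region r during (t_in, t_out)
deposits α·m·[A(t_out) − A(t_in)] of drug there — unless the region is the
non-absorbing vestibule, where that increment is lost. Summing over
particles gives total and per-region absorption and the contribution of each
initial deposition region, as functions of r_s.

## Worked example

The absorption function at the two interesting operating points:

```bash
$ mucoclear absorb run --radius 90 --time 500
D_g = 3.3161e-13 m^2/s; A(500 s) = 97.87%

$ mucoclear absorb run --radius 10 --time 10
D_g = 3.1259e-11 m^2/s; A(10 s) = 99.94%
```

A 10 nm solute is absorbed essentially instantly; a 90 nm solute needs
minutes — long enough for mucociliary clearance to compete.

A full scenario (domain → flow → spray → deposition → clearance → radius
sweep) and its report:

```bash
$ mucoclear run --seed 1 --out runs/demo
$ mucoclear report runs/demo
run with seed 1 (ab15122702d4)
deposition split (% of dose):
  main_cavity      19.45
  nasopharynx       1.08
  vestibule        79.47
absorption at the configured solute radius:
  solute_radius_nm              50.000
  total_absorbed_pct            21.849
  lost_vestibule_pct            77.848
  cleared_unabsorbed_pct         0.303
  residual_pct                   0.000
peak total absorption 24.9% at r_s = 88 nm
```

Reading: at r_s = 50 nm about 22 % of the dose is absorbed (most of the
~79 % deposited on the non-absorbing vestibule is lost there). Total
absorption peaks near 90 nm: slower diffusion lets vestibule-deposited drug
survive until recirculation carries it onto absorbing epithelium, while even
slower diffusion starts losing drug to clearance. Python users get the same
results from `mucoclear.run_scenario(ScenarioConfig(...), outdir)` or the
individual stage functions.

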