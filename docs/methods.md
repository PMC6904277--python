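# Methods

This note documents the models behind `lblcellfit`, the defaults that
matter, what the synthetic data do and do not emulate, and the numerical
choices a user auditing results will want to know.

## The system

A bacterial cell coated layer-by-layer with polyelectrolytes sits inside
a nanometre-thick shell whose mechanical strength grows with the number
of deposited layers. Three measurable consequences are modelled:

1. **Delayed growth.** Encapsulated cells resume elongation and division
   only after a lag that lengthens with layer count, observable both in
   single-cell time-lapse biomass and in population OD curves.
2. **A stalled phenotype.** In thick shells (>6 layers) a subpopulation
   never divides; these cells become 2–3× longer and wider and several
   times brighter in a leaky reporter.
3. **Altered surface electrokinetics.** Deposition flips the surface
   potential sign; the bare and coated surfaces are soft (ion- and
   water-permeable) layers whose charge density and hydrodynamic
   softness are accessible through ionic-strength-dependent
   electrophoretic mobility.

## Synthetic data

### Colony movies

Cells are 2-D spherocylinders on a single focal plane. Each founding
cell draws an individual lag from `Normal(mean_lag, sd_lag)` truncated
at 0; lag is a hard delay (no elongation before it ends, exponential
elongation `dL/dt = g(L−W)` after), the simplest model consistent with a
two-line lag definition. Division triggers at a per-cell length drawn
from `Normal(division_length_mean, sd)` truncated at ~2 widths; daughter
lengths conserve summed projected area (so ground-truth biomass is
non-decreasing), with a small angle jitter and an axial separation gap
scaled by `1 − adhesion`. Overlaps relax by iterative pairwise
displacement of spherocylinder pairs (≤80 sweeps, step scaled by
`1 − adhesion`; adhesion 1 leaves colonies compact). Residual contact up
to 35% of a cell width is tolerated — rods in dense microcolonies are
legitimately pressed together — and only severe interpenetration
(>60% after all sweeps) raises an error naming the offending cells.
Stalled cells never divide and relax exponentially (τ = 45 min) toward
`length × 2.5`, `width × 2.0`, `gfp × 5.0`.

Rendering: 512×512 px at 0.1 μm/px (resolves 1 μm rods), Gaussian PSF
σ = 2 px, background 100, additive Gaussian noise σ = 10, 16-bit; the
shell channel draws a 2 px-wide outline band (the true nm-scale shell is
far below optical resolution). Frames default to 5-min cadence; movie
length defaults to `mean_lag + 85 min` (the encoded lag plus roughly
three doublings), which keeps default stacks at 30–40 frames.

Preset lag means encode the condition-level lags of the study
(single cells: 65.2 ± 9.9 min control, 111.5 ± 1.3 min at 8 layers,
linear in layer count between; populations: 1.5 h control, 2.5 h at 2–3
bilayers, 5 h at 4). Elongation rate (0.028/min; 0.024 at 8 layers) and
division length (4.5 ± 0.4 μm) are not reported per condition anywhere;
they are fixed at values typical for *E. coli* on rich solid medium and
calibrated once so the full render→segment→regress pipeline recovers the
encoded lags and ratios.

What the movies deliberately do **not** emulate: capsule rupture and
escape mechanics (entrapment appears only as the stalled flag), 3-D
structure, photobleaching, stage drift, uneven illumination, or cell
motility. Passing tests therefore show the *analysis* chain is correct
and unbiased on data obeying the stated growth model — not that the
model captures every artefact of real micrographs.

### Plate curves

OD per well is `blank + K/(1 + ((K−N0)/N0) e^{−r·max(0, t−lag)})` plus
Gaussian noise; fluorescence is `factor × 1000 RFU/OD × (OD − blank)`
plus matching noise. Defaults: K = 1.0 OD, N0 = 0.01 OD (a 1:40
inoculum of an OD 0.38 culture), r = 2.0/h (≈21 min doubling in rich
medium), blank 0.08, noise 0.003 OD — a well-behaved shaken microplate.
The grid is 0–16 h every 20 min (49 reads). Expression factors are 1.2×
(3 bilayers) and 2.1× (4 bilayers) relative to control.

### Mobility series

The forward Ohshima model is evaluated on the measurement grid of the
electrophoresis protocol — NaCl ionic strengths 0.00062–0.11 M in 12
steps (the printed per-step increment implies 13 points; the 12-point
reading is used) — plus Gaussian noise. Default true parameters
ZN = −0.05 M, 1/λ_s = 2 nm are typical bacterial surface values.
Conductivity standards use 126.4 mS·cm⁻¹ per mol/L for dilute NaCl.

## Estimators

### Two-line lag (λ)

Two regression lines — one through the lag phase, one through the
exponential phase — are grown forward point by point from the first
point (then from the first excluded point); λ is the time coordinate of
their intersection. Two numerical choices matter and were validated by
Monte Carlo (300–500 curves per condition) during design:

- **Stopping rule.** A segment stops when its R² falls more than
  `r2_drop` (default 0.01) below the best R² that segment has reached.
  Comparing to the running best rather than the immediately preceding
  fit keeps the exponential window from creeping into the logistic bend
  (slope attenuation there biased λ by 20–70% on the raw scale).
- **Flatness floor.** A segment counts as zero-variance (R² := 1) while
  its spread is below `flat_tol` (default 0.01) of the signal's dynamic
  range **or** below twice the robust point noise (lower-quartile
  successive difference / (0.3186·√2)). Without this, R² of a flat noisy
  baseline is scale-free random and the forward extension terminates
  essentially at random inside the lag.
- **Scale.** By default both lines are fitted to log(signal) (clipped at
  half the flatness floor), where the exponential phase is genuinely
  linear and the intersection with the flat baseline estimates the lag
  end with little bias. Raw-scale fitting (`scale="raw"`) is exact for
  piecewise-linear data but overestimates lag on sigmoidal curves by a
  roughly constant ~1 h on the default plate grid, so log is the
  default. Affine invariance of λ holds exactly on the raw scale;
  on the log scale the invariance is to positive rescaling.

Residual performance at the defaults: plate curves — bias within ±7% of
the true lag at noise 0–0.01 OD, single-curve sd ≤ 0.3 h; colony-style
biomass curves — bias +5 to +10% (the population biomass corner is
rounded by per-cell lag heterogeneity and the baseline offset of cell
caps). Both segments' full R² traces are returned so breakpoints can be
audited; a λ outside the fitted span sets a warning flag.

### Logistic fit

Least squares in log-parameter space (positivity for free), multi-start
over K ≈ max, N0 ≈ first positive value ×{1, 0.1}, r from the middle
third log-slope ×{0.5, 1, 2}. Curves with a lag are still fitted with
the plain logistic (the same convention as standard growth-curve
packages); the lag is absorbed into an underestimated N0, which is why λ
comes from the two-line estimator, not from this fit. AUC is reported
both as the closed-form integral of the fitted curve between the data
endpoints and as the trapezoid on the raw data, since the two differ
under noise and neither is canonical.

### Imaging

Binarization defaults to Otsu (with a fixed-threshold mode for
reproducibility); particles are 8-connected components with
`min_area ≥ 5 px` (removes noise speckles at default render settings).
Coordinates are 0-based pixel indices, centroids at pixel centers,
areas pixel counts × pixel_size². Cell length/width come from mask
second moments calibrated for a uniform (rectangular) profile,
`2√3·σ` — on rendered rods this lands within 10%/20% of truth where the
ellipse-axis convention overshoots width by ~23%. The particle table
also carries the raw ellipse axes. The shape descriptor uses the
Crofton perimeter (4 directions): staircase contour lengths overestimate
smooth perimeters by ~6%, enough to push a discrete disk's score above
0.1. The convention is exported as `imaging.PERIMETER_CONVENTION`.
There is no cell tracking and no watershed splitting of touching cells;
biomass is aggregate area by design. Consequently, per-cell morphometry
of a growing condition is measured on frames where cells are still
optically separable (the stalled condition, which never divides, is
measured fully relaxed at its final frame; its GFP level is
time-invariant, so the intensity ratio is frame-independent).

### Soft-particle inversion

ZN is parameterized in mol/L of signed elementary charges (converted by
e·N_A·1000 to C/m³), keeping fitted magnitudes O(0.01–0.1); softness is
fitted as log(1/λ_s) to stay positive. The objective has shallow valleys
in the softness direction, so the fit is multi-start over a 5×5
log-spaced grid (|ZN| ∈ [0.001, 0.5] M, 1/λ_s ∈ [0.1, 10] nm) with the
charge sign taken from the data; standard errors come from Gauss–Newton
curvature. A softness pinned to the grid edge raises a warning.
Relaxation/polarization corrections beyond the analytic formula are not
modelled, and mobilities are fitted directly (no Smoluchowski
preconversion). Medium defaults: ε_r = 78.5, η = 0.89 mPa·s,
T = 298.15 K, z = 1 (NaCl at room temperature).

## Problem sizes

Default analyses use 15 founding cells per movie (110 for the viability
count, where per-cell matching needs a large denominator), 3 replicate
wells and 3 blank wells per plate condition, and 12-point mobility
series; noisy-recovery summaries use 100 seeds. These sizes give
condition-level means whose Monte-Carlo scatter is well inside the
tolerances quoted above.

## Known limitations

- The lag estimator's +5–10% bias on colony biomass curves is inherent
  to a two-line description of a corner rounded by lag heterogeneity;
  a parametric lag model (Baranyi-type) would remove it but is out of
  scope here.
- Touching cells merge into single particles; morphometry on dense late
  frames of dividing conditions is not meaningful.
- The soft-particle model assumes a uniformly charged, planar-limit
  layer; fitted ZN and 1/λ_s are effective parameters, and no reference
  values are available for them — only self-consistent recovery is
  verified.
- The plate fluorescence model ties signal strictly to blank-corrected
  OD; real expression peaks relative to OD in mid-exponential phase are
  not reproduced beyond the overall per-condition factor.
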