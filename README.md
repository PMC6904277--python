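# lblcellfit

Quantitative analysis of growth, morphology and surface electrokinetics of
bacteria encapsulated in layer-by-layer (LBL) polyelectrolyte shells.

Coating single *E. coli* cells with alternating polycation/polyanion layers
(PEI/PSS) wraps each cell in a nanometre-thick but mechanically strong
capsule. The shell delays division — the lag phase grows with the number of
deposited layers — and cells trapped in thick shells stop dividing
altogether while becoming larger and markedly brighter in a leaky
GFP reporter. `lblcellfit` packages the full measurement chain used to
quantify these effects, together with synthetic-data generators that
produce every input class with known ground truth, so the whole pipeline
is testable end to end:

- **synthetic_data** — agent-based rod-cell microcolony movies
  (spherocylinder rendering, per-cell lag, division, shell channel),
  delayed-logistic plate-reader OD/fluorescence curves, and
  ionic-strength-dependent electrophoretic mobility (ISDEM) series.
- **imaging** — make-binary / analyze-particles quantification: Otsu or
  fixed thresholding, 8-connected particles, biomass-vs-time series,
  per-cell length/width/intensity, and a colony circularity descriptor
  `1 − 4πA/P²` (0 = perfect disk).
- **growth_kinetics** — logistic fits
  `N(t) = K / (1 + ((K−N0)/N0) e^{−rt})` with derived `tmid = ln((K−N0)/N0)/r`,
  `tgen = ln2/r` and AUC, plus the two-line lag estimator: regression
  lines through the lag and exponential phases, extended point by point
  under an R² rule, with the lag duration λ read off at their
  intersection.
- **electrophoresis** — Ohshima's soft-particle model
  `μ = (ε/η)·(ψ₀/κ_m + ψ_DON/λ_s)/(1/κ_m + 1/λ_s) + ρ_fix/(η λ_s²)`,
  its inversion for the layer charge density ZN and softness 1/λ_s from
  ISDEM data, conductivity→ionic-strength calibration, and the
  Smoluchowski mobility↔zeta conversion.
- **pipeline / CLI** — config-driven generate → analyze → compare runs
  with JSON reports, config hashes and per-stage timing.

## Worked example

Recover the single-cell lag duration of control versus 8-layer
encapsulated cells from rendered time-lapse movies:

```python
import numpy as np
from lblcellfit import protocols

lams_c = protocols.single_cell_lag_min("control", seeds=(1, 2, 3))
lams_8 = protocols.single_cell_lag_min("layers8", seeds=(1, 2, 3))
print("control  lag estimates (min):", np.round(lams_c, 1), "mean", round(float(np.mean(lams_c)), 1))
print("8-layer  lag estimates (min):", np.round(lams_8, 1), "mean", round(float(np.mean(lams_8)), 1))
```

```
control  lag estimates (min): [66.2 70.  69.2] mean 68.5
8-layer  lag estimates (min): [114.7 115.7 115.5] mean 115.3
```

Each number is a full pipeline pass: an agent-based colony movie is
simulated and rendered (16-bit, Gaussian PSF, noise), every frame is
Otsu-binarized, particle areas are summed into a biomass series, and the
two-line changepoint regression returns λ. The means sit within a few
percent of the lag durations the presets encode (65.2 min control,
111.5 min for 8 layers) — the residual gap is the estimator's intrinsic
bias at these growth rates, quantified in `docs/methods.md`.

The same chains are available from the shell:

```bash
lblcellfit generate colony --preset layers8 --seed 1 --out stack/
lblcellfit analyze-stack --in stack/ --out analysis/
lblcellfit lag --in analysis/biomass.csv
lblcellfit run --seed 1 --out runs/demo     # full end-to-end report
```

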