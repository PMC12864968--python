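# pouchchar

Dissolution kinetics and powder characterization of oral nicotine pouch
products.

Nicotine pouches are oral products in which nicotine-loaded filler (usually
microcrystalline-cellulose based) sits inside a permeable pouch. How fast a
pouch releases nicotine into saliva, and why products differ, is governed by
measurable physical properties: release kinetics, particle size, bulk and
true density, crystallinity, solubility, moisture, and extract viscosity.
`pouchchar` implements the complete computational analysis for a
seven-product characterization study (*on!*, *Zyn*, *Velo*, *Dryft*,
*Rogue*, *Volt*, *Loop*) for formulation scientists and dissolution
analysts:

* **Release kinetics** — cumulative release is fitted to the first-order
  model `M_rel(t) = M0 (1 - e^(-kt))` by bounded least squares; predicted
  percent released is `100(1 - e^(-kt))`.
* **Profile equivalency** — difference factor
  `f1 = 100 Σ|R_t - T_t| / ΣR_t` and similarity factor
  `f2 = 50 log10(100 / sqrt(1 + (1/n) Σ(R_t - T_t)²))`, with equivalency
  when `f1 ≤ 15` and `f2 ≥ 50`.
* **Particle size** — count- (q0) and volume-weighted (q3) EQPC
  distributions, d10/d50/d90 intercepts, and span `(d90 - d10)/d50`.
* **Flowability/porosity** — Carr index `(ρ_TB - ρ_UB)/ρ_TB·100`, Hausner
  ratio `ρ_TB/ρ_UB`, porosity `(ρ_T - ρ_TB)/ρ_T·100`, with the USP
  tapped-density stopping rule and the pycnometer run-selection rule.
* **Physchem panel** — solubility mass balance, oven-volatiles moisture,
  water-activity calibration checks, pH records, flow-curve summaries.
* **DSC** — baseline subtraction, enthalpy integration (`dt = dT·60/ramp`),
  tangent onset, peak and glass-transition temperatures.
* **Synthetic data** — deterministic generators for every input kind, so
  the whole pipeline runs without instrument data.

The study's raw instrument data are not publicly deposited; the package
ships the published per-product summary values (`pouchchar.study`) as
inputs and validates everything else generatively. See `docs/methods.md`
for the models, conventions, and limitations.

## Worked example

```python
import numpy as np
from pouchchar.dissolution import fit_first_order, predict_percent_released, first_order_release
from pouchchar.equivalence import compare_profiles
from pouchchar.powder import summarize_density
from pouchchar.study import DENSITIES, KINETICS, TIME_GRID_MIN

# fit the first-order model to a cumulative release curve (Loop regime)
t = np.array(TIME_GRID_MIN)
cum = first_order_release(t, *KINETICS["Loop"])
fit = fit_first_order(t, cum)
print(round(fit.M0, 3), round(fit.k, 4))    # 4.74 0.021
print(round(predict_percent_released(fit, 60)))  # 72  (% released in 60 min)

# flowability from the published densities
d = DENSITIES["Loop"]
s = summarize_density("Loop", d["rho_UB"], d["rho_TB"], d["rho_T"])
print(round(s.carr_index, 2), round(s.hausner_ratio, 3), s.flow_class.label)
# 36.91 1.585 poor
```

The fitted `(M0, k)` reproduce the generating parameters exactly on
noise-free data; 72% is the model's predicted release in 60 minutes for the
slowest product, and a Carr index of 36.9 with Hausner ratio 1.585 classify
its filler as poorly flowing (CI > 25, HR > 1.25, concordant).

## Analysis scripts

The numbered drivers under `analysis/` reproduce the study's derived tables
step by step, writing CSVs under `results/` (synthetic inputs land under
`scratch/`):

```bash
python analysis/01_simulate_study.py      # generate all synthetic inputs
python analysis/02_dissolution_kinetics.py
python analysis/03_profile_equivalence.py
python analysis/04_particle_size.py
python analysis/05_powder_metrics.py
python analysis/06_physchem_panel.py
python analysis/07_thermal_events.py
python analysis/08_full_report.py         # one-call pipeline + manifest
```

`pouchchar.pipeline.run_pipeline(StudyConfig(...), out_dir)` is the
library entry point behind `08`; it chains dissolution fits → equivalence
matrix → PSD stats → density metrics → physchem table and writes a JSON
manifest with versions, seed, input checksums, and the operation that
produced each table.

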