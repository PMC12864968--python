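# Methods

`pouchchar` implements the computational side of a physical/dissolution
characterization of seven commercial oral nicotine pouch products (*on!*,
*Zyn*, *Velo*, *Dryft*, *Rogue*, *Volt*, *Loop*): release-kinetics fitting,
profile-equivalency testing, particle-size statistics, density-derived
flowability/porosity, solubility/moisture bookkeeping, and DSC thermal-event
extraction. The raw instrument data are not deposited anywhere public; the
package therefore ships (a) the published per-product summary values as its
reference dataset (`pouchchar.study`) and (b) a synthetic-data generator
that emulates every input kind, so every stage is exercised end to end
without instrument files.

## Dissolution kinetics

Cumulative release into artificial saliva is modelled as first order in the
remaining releasable amount:

    M_rel(t) = M0 * (1 - exp(-k t))

with `M0` the total releasable nicotine (mg/pouch) and `k` the release rate
constant (1/min). Fractions are collected on the 9-point grid
4, 8, 12, 16, 20, 30, 40, 50, 60 min. Fitting is bounded nonlinear least
squares (`scipy.optimize.least_squares`, trust-region reflective,
unweighted loss):

* initialization: `M0` at the final cumulative value; `k` from the
  closed-form one-point inversion `-ln(1 - c(t1)/M0) / t1`, clipped to
  [1e-4, 1] — robust on any monotone profile;
* bounds: `M0 ∈ (0, 10x final]`, `k ∈ [1e-6, 10]`;
* both every replicate and the mean curve are fitted; the mean-curve `k` is
  the headline constant (one `k` per product), per-replicate fits are kept
  for dispersion.

A fit is flagged non-converged when the optimizer fails, when `k`
terminates on a bound, or when `exp(-k t1) < 1e-9` — the latter marks the
degenerate case where release completed before the first sample, so the
data carry no rate information (a constant series is fit equally well by
any large `k`; the optimizer stops wherever the gradient vanishes rather
than at the bound, so the bound check alone would miss it).

Three normalizations are provided: percent of total release (divide by the
60-min cumulative; the last point is exactly 100 — the division is done
before the scaling by 100 so this holds in floating point), percent of the
fitted `M0` (may end below 100), and percent of the independently measured
nicotine content.

Predicted percent released at time t is `100(1 - exp(-k t))`. Of the
published per-product predictions only the slowest product's cell (k =
0.021/min → 72% at 60 min) is reproducible from the printed `k`; the other
cells do not equal `100(1-exp(-60k))` at the printed precision and the
computation behind them is ambiguous, so they are not asserted.

## Profile equivalency (f1/f2)

    f1 = 100 * Σ|R_t - T_t| / ΣR_t
    f2 = 50 * log10(100 / sqrt(1 + (1/n) Σ(R_t - T_t)^2))

Equivalent when `f1 ≤ 15` and `f2 ≥ 50`, both inclusive. `f2` is symmetric
in (R, T); `f1` is not (reference sum in the denominator) — both facts are
tested. Profiles compared are the mean percent-of-total-release curves
across replicates. All common measured points are used by default; the
regulatory convention of truncating after the reference passes 85% release
is available (`cap_85=True`, keeping one point beyond 85%) but off by
default, because the published f1/f2 values could not be reproduced under
either convention from printed parameters alone — they require the
unpublished 12-replicate curves. Numeric reproduction of that table is
therefore out of scope; only the decision rule applied to the printed pairs
is validated.

## Particle-size statistics

Particles are EQPC diameters (`d = 2 sqrt(A/π)` from projected area).
Count weighting (q0) gives each particle weight 1; volume weighting (q3)
weights by `d³`. Statistics: weighted arithmetic mean; d10/d50/d90 as
linear interpolation of the cumulative weighted CDF between consecutive
sorted unique diameters (ties aggregated first; levels at or below the
first cumulative value clamp to the smallest diameter); span
`(d90-d10)/d50`. The instrument's own quantile convention is not published;
interpolation on the sorted CDF was chosen because it is deterministic and
directly checkable against a brute-force scan oracle, which the tests do
exhaustively for all sample sizes up to 6 with randomized weights. Binned
distributions default to 31 geometric bins over the 10–6820 µm lens range;
the binned quantile path interpolates between bin edges and is only used
when the raw sample is unavailable.

Recomputing span from the published mean intercepts reproduces the
published span only in the self-consistent rows (the published span is a
mean of per-replicate spans); `analysis/04_particle_size.py` tabulates
which rows agree at printed precision.

## Density, flowability, porosity

* Untapped bulk density: mass freely poured into the 25 mL volumeter cup,
  divided by 25 mL.
* Tapped bulk density: block volumes after 500, 750, then 500-tap blocks;
  stop at the first consecutive pair changing by < 2% (denominator = the
  earlier block's volume); an exhausted series raises a needs-more-taps
  error rather than silently truncating.
* True density: per-run sample volume
  `V_sample = V_chamber + V_reference (1 - P1/P2)`; the run-selection rule
  takes the earliest three successive run densities whose percent
  coefficient of variation (100·sd/mean, sample sd) is below 0.05%,
  else the final three of five. "Percent variance" is not defined
  mathematically in the source description; percent CV is the standard
  pycnometer-firmware reading of it and is the implemented default.
* Derived: `CI = (ρ_TB - ρ_UB)/ρ_TB × 100`, `HR = ρ_TB/ρ_UB`,
  `P% = (ρ_T - ρ_TB)/ρ_T × 100`. CI > 25 or HR > 1.25 labels the filler
  poor-flowing; the two criteria are cross-checked and discordance is
  flagged, not resolved. The identity `CI = (1 - 1/HR)·100` is tested to
  1e-9. Inverted inputs (ρ_UB > ρ_TB) warn and yield a negative CI rather
  than raising, tolerating instrument noise.
* Report rounding: 4 dp untapped, 3 dp tapped/true, 2 dp CI, 3 dp HR,
  3 dp porosity; all table rounding is round-half-up.

One published cell is a rounding boundary: recomputing Volt's porosity from
the printed densities gives 39.049 vs the printed 38.999 (gap 0.0501); the
tests list it explicitly instead of widening the global tolerance.

## Physicochemical panel

The solubility mass balance `(m_final - m_paper)/m_filler × 100` computes
the *insoluble* fraction literally; the per-product "percent soluble"
reported values are its complement, and the package exposes both
operations explicitly (`percent_insoluble`, `percent_soluble`) because the
source text labels the literal equation "% Solubles" while quoting
complement-scale values — the complement matches every quoted magnitude.
Unfiltrable samples (Loop) propagate as missing ("N/A"), never 0. Oven
volatiles: `100·(m_before - m_after)/m_before` at 80 °C/10 min. Water
activity instrument checks compare readings at the 0.250/0.500/0.760/0.920
standards within ±0.005 (typical instrument spec; configurable). Flow
curves over 1–100 1/s are summarized by mean viscosity and the power-law
flow index (least-squares slope of log η vs log γ̇; 0 = Newtonian,
negative = shear-thinning).

## DSC analysis

Thermograms are heat flow (W/g) on a 0–160 °C sweep at 10 °C/min.
Enthalpy is a time integral, so quadrature uses `dt = dT·60/ramp`.
Baseline: a line through the signal centroids of two user-chosen anchor
windows flanking the event; a window whose own residual curvature exceeds
5x a robust noise estimate (MAD of first differences) is flagged as likely
sitting on the event. Melting events: peak at the extremum of the
corrected signal; onset by the tangent construction at the steepest
leading-edge point extrapolated to the zero baseline (the standard
thermal-analysis reading; no algorithm is published for the source data).
Orientation is set by an endo-down/endo-up flag (default endo-down) and
enthalpy is reported as a magnitude. Glass transitions: lines fitted to
the outer 20% of the window on each side, step height = their separation
at the window centre, T_g = first crossing of the midline (midpoint
convention); steps below 5x the noise floor return no event. Event regions
are user-specified windows; an automatic detector is deliberately not
acceptance-bearing. The published DSC table is not asserted numerically —
the raw thermograms are unavailable — so the module is validated
generatively: synthetic Gaussian peaks of stated area close to within
0.5%, triangle-pulse onsets to one grid step, sigmoid steps to one grid
step.

## Synthetic-data generator

What it emulates, and the defaults (which are the study conditions):

* Dissolution: 12 replicates per product on the 9-point grid at the
  product's reference (M0, k); replicate-level variability is lognormal on
  M0 and k (positivity) with default CV 5% — the study publishes only
  means, so the CVs are free scenario parameters, not calibrated values;
  additive Gaussian noise on the cumulative series (2% of M0 in the
  recovery experiments), then differenced with negative fraction masses
  clipped to zero so cumulative profiles stay non-decreasing. Noise-free
  output satisfies the model exactly.
* Particles: lognormal mixtures — unimodal for the Gaussian-like products
  (*on!*, *Zyn*, *Rogue*), bimodal (fines + granule mode) for the rest,
  with medians anchored at the published d50 values.
* Thermograms: linear baseline + Gaussian peaks whose time integral equals
  the specified area in J/g + optional sigmoid steps, sampled at 0.1 °C.
* Tap series: exponential compaction toward `V_inf` with meniscus-reading
  jitter and graduated-cylinder rounding, monotonized.
* Pycnometer runs: implied densities settling onto the target with
  geometrically decaying scatter (early purges equilibrate the cell).
* Flow curves: power-law fluid on a log-spaced sweep.

Randomness: one `numpy` Generator per scenario seed; dissolution replicates
use `SeedSequence.spawn` child streams in replicate order. Equal seeds give
bit-identical outputs, including CSV bytes.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: no transport physics of the flow-through cell (the
first-order model is imposed, not emergent), no correlated or
heteroscedastic assay error, no particle-shape effects beyond EQPC, no
instrument drift beyond a linear DSC baseline, no saliva chemistry.
Parameter-recovery results certify the estimator under the stated noise
model only.

## Problem sizes

Default analysis runs use 12 dissolution replicates per product (4 in the
pipeline tests), 20 000 particles per product (500–2000 in tests), 0.1 °C
thermogram sampling, and 5 pycnometer runs — the study's own scales, which
also keep the full suite and the acceptance script fast.

## Known limitations

* The published model-estimated release-percent and f1/f2 tables are not
  reproducible from the printed parameters alone (ambiguous underlying
  computation / unpublished replicate curves); the package reproduces the
  self-consistent cells and the decision rule, and documents the rest.
* The quantile convention is one defensible choice among several; absolute
  d-values from other software will differ slightly near sparse tails.
* Automatic DSC event detection is best-effort; quantitative results
  assume user-specified event windows.
* High apparent melting enthalpies of wet fillers conflate water
  evaporation with melting; no deconvolution is attempted.
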