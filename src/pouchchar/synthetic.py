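"""Synthetic study-data generators.

Every input kind the analysis consumes can be generated here with the
statistical structure the downstream stages assume, so the full pipeline is
exercisable without instrument data:

* dissolution replicates following the first-order release model with
  replicate-level lognormal variability on (M0, k) and additive Gaussian
  noise on the cumulative series (clipped so fraction masses stay
  non-negative);
* unimodal/bimodal lognormal particle diameter populations;
* tap-volume sequences with exponential compaction;
* repeated pycnometer expansions converging on a target true density;
* thermograms as a linear baseline plus Gaussian peaks of specified area
  (J/g, converted through the ramp) with optional sigmoid glass-transition
  steps;
* power-law flow curves.

Determinism: each generator derives all randomness from the scenario's seed
through one numpy Generator; dissolution replicates use per-replicate
child streams in replicate order, so output is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissolution import DissolutionProfile, cumulate_fractions, first_order_release
from .errors import ValidationError
from .physchem import FlowCurve
from .powder import PycnometerRun, TappedSeries
from .study import TIME_GRID_MIN
from .thermal import Thermogram

__all__ = [
    "DissolutionScenario",
    "ParticleScenario",
    "ThermogramScenario",
    "TapScenario",
    "PycnometerScenario",
    "FlowCurveScenario",
    "gen_dissolution",
    "gen_particles",
    "gen_thermogram",
    "gen_tap_series",
    "gen_pycnometer_runs",
    "gen_flow_curve",
    "write_dissolution_csv",
    "read_dissolution_csv",
    "write_particles_csv",
    "write_thermogram_csv",
    "write_flow_curve_csv",
]


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


@dataclass(frozen=True)
class DissolutionScenario:
    """Replicate dissolution runs of one product under first-order release."""

    product_name: str
    M0_mean: float                 # mg
    k_mean: float                  # 1/min
    M0_cv: float = 0.05
    k_cv: float = 0.05
    times: tuple = TIME_GRID_MIN   # minutes
    noise_sd: float = 0.0          # mg, additive on the cumulative series
    n_replicates: int = 12
    seed: int = 0

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        if len(t) == 0 or t[0] <= 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("times must be strictly increasing and positive")
        if self.M0_mean <= 0 or self.k_mean <= 0:
            raise ValidationError("M0_mean and k_mean must be positive")
        if self.M0_cv < 0 or self.k_cv < 0 or self.noise_sd < 0:
            raise ValidationError("dispersion parameters must be non-negative")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")
        object.__setattr__(self, "times", t)


@dataclass(frozen=True)
class ParticleScenario:
    """Mixture-of-lognormals diameter population.

    modes: list of (median_um, geometric_sd, weight); weights must sum to 1.
    """

    modes: tuple
    n_particles: int = 10_000
    seed: int = 0

    def __post_init__(self):
        modes = tuple((float(m), float(g), float(w)) for m, g, w in self.modes)
        if not modes:
            raise ValidationError("at least one mode required")
        if any(m <= 0 for m, _, _ in modes):
            raise ValidationError("mode medians must be positive")
        if any(g <= 1.0 for _, g, _ in modes):
            raise ValidationError("geometric sd must exceed 1")
        if abs(sum(w for _, _, w in modes) - 1.0) > 1e-9:
            raise ValidationError("mode weights must sum to 1")
        if self.n_particles < 0:
            raise ValidationError("n_particles must be non-negative")
        object.__setattr__(self, "modes", modes)


@dataclass(frozen=True)
class ThermogramScenario:
    """Linear baseline plus Gaussian peaks of specified time-integral area.

    peaks: list of (center_C, width_C, area_J_per_g, sign) where sign is +1
    or -1 (endotherm-down convention uses -1). steps: optional list of
    (center_C, width_C, height_W_per_g) sigmoid baseline shifts emulating a
    glass transition.
    """

    T_start: float = 0.0
    T_end: float = 160.0
    ramp: float = 10.0            # °C/min
    baseline_slope: float = 0.0   # W/g per °C
    baseline_intercept: float = 0.0
    peaks: tuple = ()
    steps: tuple = ()
    noise_sd: float = 0.0         # W/g
    sample_step: float = 0.1      # °C
    seed: int = 0

    def __post_init__(self):
        if self.T_start >= self.T_end:
            raise ValidationError("T_start must be below T_end")
        if self.ramp <= 0:
            raise ValidationError("ramp must be positive")
        if self.sample_step <= 0:
            raise ValidationError("sample_step must be positive")
        peaks = tuple((float(c), float(w), float(a), int(s)) for c, w, a, s in self.peaks)
        if any(w <= 0 for _, w, _, _ in peaks):
            raise ValidationError("peak widths must be positive")
        if any(a < 0 for _, _, a, _ in peaks):
            raise ValidationError("peak areas must be non-negative")
        if any(s not in (-1, 1) for _, _, _, s in peaks):
            raise ValidationError("peak sign must be +1 or -1")
        steps = tuple((float(c), float(w), float(h)) for c, w, h in self.steps)
        if any(w <= 0 for _, w, _ in steps):
            raise ValidationError("step widths must be positive")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "steps", steps)


@dataclass(frozen=True)
class TapScenario:
    """Tap-volume sequence with exponential compaction toward V_inf."""

    filler_mass: float = 100.0  # g
    V0: float = 160.0           # mL before compaction settles
    V_inf: float = 125.0        # mL asymptote
    tau_taps: float = 400.0     # compaction time constant in taps
    max_blocks: int = 8
    read_resolution: float = 1.0  # graduated-cylinder reading step, mL
    seed: int = 0

    def __post_init__(self):
        if self.filler_mass <= 0 or self.V0 <= 0 or self.V_inf <= 0:
            raise ValidationError("masses and volumes must be positive")
        if self.V_inf > self.V0:
            raise ValidationError("V_inf cannot exceed V0")
        if self.tau_taps <= 0 or self.max_blocks < 2:
            raise ValidationError("tau_taps > 0 and at least 2 blocks required")


@dataclass(frozen=True)
class PycnometerScenario:
    """Repeated expansions for a sample of known true density."""

    true_density: float          # g/cm^3
    sample_mass: float = 7.5     # g (~75% fill of a 10 cm^3 cell)
    V_chamber: float = 10.0      # cm^3
    V_reference: float = 10.0    # cm^3
    P1: float = 10.0             # instrument units (predefined charge)
    n_runs: int = 5
    drift_cv: float = 5e-4       # run-to-run relative scatter, decaying
    seed: int = 0

    def __post_init__(self):
        if self.true_density <= 0 or self.sample_mass <= 0:
            raise ValidationError("density and mass must be positive")
        if self.V_chamber <= 0 or self.V_reference <= 0 or self.P1 <= 0:
            raise ValidationError("volumes and P1 must be positive")
        if not 3 <= self.n_runs <= 5:
            raise ValidationError("n_runs must be between 3 and 5")
        if self.sample_mass / self.true_density >= self.V_chamber:
            raise ValidationError("sample volume must fit inside the chamber")


@dataclass(frozen=True)
class FlowCurveScenario:
    """Power-law fluid eta = K * gamma^n over a 1-100 1/s sweep."""

    K: float = 2.25              # cP at 1 1/s
    n_exponent: float = 0.0      # 0 = Newtonian, negative = shear-thinning
    shear_min: float = 1.0
    shear_max: float = 100.0
    n_points: int = 20
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.K <= 0:
            raise ValidationError("K must be positive")
        if not 0 < self.shear_min < self.shear_max:
            raise ValidationError("need 0 < shear_min < shear_max")
        if self.n_points < 3:
            raise ValidationError("need at least 3 points")


def gen_dissolution(scenario: DissolutionScenario) -> list[DissolutionProfile]:
    """Draw replicate cumulative release curves under the scenario.

    Per replicate, (M0, k) are drawn from lognormals with the stated means
    and CVs (degenerate at the mean when CV=0), the clean first-order curve
    is evaluated on the grid, Gaussian noise is added to the cumulative
    series, and monotonicity is restored by clipping negative successive
    differences to zero before re-accumulating.
    """
    t = np.asarray(scenario.times)
    streams = np.random.SeedSequence(scenario.seed).spawn(scenario.n_replicates)
    profiles = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if scenario.M0_cv > 0:
            mu, sig = _lognormal_params(scenario.M0_mean, scenario.M0_cv)
            M0 = rng.lognormal(mu, sig)
        else:
            M0 = scenario.M0_mean
        if scenario.k_cv > 0:
            mu, sig = _lognormal_params(scenario.k_mean, scenario.k_cv)
            k = rng.lognormal(mu, sig)
        else:
            k = scenario.k_mean
        cum = first_order_release(t, M0, k)
        if scenario.noise_sd > 0:
            cum = cum + rng.normal(0.0, scenario.noise_sd, size=t.shape)
        fractions = np.clip(np.diff(np.concatenate([[0.0], cum])), 0.0, None)
        profiles.append(
            cumulate_fractions(scenario.product_name, rep, t, fractions)
        )
    return profiles


def gen_particles(scenario: ParticleScenario) -> np.ndarray:
    """Sample EQPC diameters (µm) from the lognormal mixture."""
    rng = np.random.default_rng(scenario.seed)
    if scenario.n_particles == 0:
        return np.empty(0)
    medians = np.array([m for m, _, _ in scenario.modes])
    gsds = np.array([g for _, g, _ in scenario.modes])
    weights = np.array([w for _, _, w in scenario.modes])
    which = rng.choice(len(medians), size=scenario.n_particles, p=weights)
    return rng.lognormal(np.log(medians[which]), np.log(gsds[which]))


def gen_thermogram(scenario: ThermogramScenario) -> Thermogram:
    """Synthesize a heat-flow trace on an even temperature grid.

    Each Gaussian peak's *time* integral equals its specified area (J/g): a
    peak of area A and width sigma gets temperature-domain amplitude
    A * ramp / (60 * sigma * sqrt(2 pi)).
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(round((scenario.T_end - scenario.T_start) / scenario.sample_step)) + 1
    T = np.linspace(scenario.T_start, scenario.T_end, n)
    signal = scenario.baseline_slope * T + scenario.baseline_intercept
    for center, width, area, sign in scenario.peaks:
        amp = sign * area * scenario.ramp / (60.0 * width * np.sqrt(2.0 * np.pi))
        signal = signal + amp * np.exp(-0.5 * ((T - center) / width) ** 2)
    for center, width, height in scenario.steps:
        signal = signal + height / (1.0 + np.exp(-(T - center) / width))
    if scenario.noise_sd > 0:
        signal = signal + rng.normal(0.0, scenario.noise_sd, size=T.shape)
    return Thermogram(temperatures=T, heat_flow=signal, ramp=scenario.ramp)


def gen_tap_series(scenario: TapScenario) -> TappedSeries:
    """Volumes after each USP tap block (500, 750, then 500-tap blocks)."""
    rng = np.random.default_rng(scenario.seed)
    taps_per_block = (500, 750) + (500,) * (scenario.max_blocks - 2)
    cum_taps = np.cumsum(taps_per_block)
    v = scenario.V_inf + (scenario.V0 - scenario.V_inf) * np.exp(-cum_taps / scenario.tau_taps)
    v = v + rng.normal(0.0, 0.05, size=v.shape)  # small meniscus-reading jitter
    res = scenario.read_resolution
    v = np.round(v / res) * res
    v = np.minimum.accumulate(v)  # a tapped bed cannot re-expand
    return TappedSeries(
        filler_mass=scenario.filler_mass,
        volumes=tuple(v),
        taps_per_block=taps_per_block,
    )


def gen_pycnometer_runs(scenario: PycnometerScenario) -> list[PycnometerRun]:
    """Expansion runs whose implied densities settle onto the target.

    Run-to-run scatter decays geometrically (early purges equilibrate the
    cell), emulating the convergence the 0.05% selection rule looks for.
    """
    rng = np.random.default_rng(scenario.seed)
    v_true = scenario.sample_mass / scenario.true_density
    runs = []
    for i in range(scenario.n_runs):
        eps = rng.normal(0.0, scenario.drift_cv * (0.5 ** i))
        v_sample = v_true * (1.0 + eps)
        # invert V_sample = V_chamber + V_reference*(1 - P1/P2) for P2
        p2 = scenario.P1 / (1.0 + (scenario.V_chamber - v_sample) / scenario.V_reference)
        runs.append(PycnometerRun(
            P1=scenario.P1, P2=p2,
            V_chamber=scenario.V_chamber, V_reference=scenario.V_reference,
            sample_mass=scenario.sample_mass,
        ))
    return runs


def gen_flow_curve(scenario: FlowCurveScenario) -> FlowCurve:
    """Log-spaced shear sweep of a power-law fluid with multiplicative noise."""
    rng = np.random.default_rng(scenario.seed)
    gamma = np.geomspace(scenario.shear_min, scenario.shear_max, scenario.n_points)
    eta = scenario.K * gamma**scenario.n_exponent
    if scenario.noise_cv > 0:
        eta = eta * np.exp(rng.normal(0.0, scenario.noise_cv, size=eta.shape))
    return FlowCurve(shear_rates=gamma, viscosities=eta)


# ---------------------------------------------------------------------------
# CSV round-trip helpers (plain-text interchange for the pipeline stages)

def write_dissolution_csv(profiles, path) -> None:
    rows = []
    for p in profiles:
        for t, f, c in zip(p.times, p.fraction_mg, p.cumulative_mg):
            rows.append((p.product_name, p.replicate_id, t, f, c))
    pd.DataFrame(
        rows, columns=["product", "replicate", "time_min", "fraction_mg", "cumulative_mg"]
    ).to_csv(path, index=False, float_format="%.9g")


def read_dissolution_csv(path) -> dict[str, list[DissolutionProfile]]:
    """Profiles grouped by product, rebuilt through cumulate_fractions."""
    df = pd.read_csv(path)
    out: dict[str, list[DissolutionProfile]] = {}
    for (product, rep), grp in df.groupby(["product", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.setdefault(str(product), []).append(
            cumulate_fractions(str(product), int(rep),
                               grp["time_min"].to_numpy(),
                               grp["fraction_mg"].to_numpy())
        )
    return out


def write_particles_csv(diameters, path) -> None:
    pd.DataFrame({"diameter_um": np.asarray(diameters, dtype=float)}).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_thermogram_csv(thermogram: Thermogram, path) -> None:
    pd.DataFrame({
        "temperature_C": thermogram.temperatures,
        "heat_flow_W_per_g": thermogram.heat_flow,
    }).to_csv(path, index=False, float_format="%.9g")


def write_flow_curve_csv(curve: FlowCurve, path) -> None:
    pd.DataFrame({
        "shear_rate_per_s": curve.shear_rates,
        "viscosity_cP": curve.viscosities,
    }).to_csv(path, index=False, float_format="%.9g")
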