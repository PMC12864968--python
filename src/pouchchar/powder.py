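"""Density stack and derived flowability/porosity metrics.

Three densities are measured per filler: untapped bulk (loose pour into a
25 mL cup), tapped bulk (USP tapped-density procedure with a 2% volume
stopping rule), and true density (helium pycnometry with a run-selection
rule). From these:

    Carr index      CI = (rho_TB - rho_UB) / rho_TB * 100
    Hausner ratio   HR = rho_TB / rho_UB
    Porosity        P% = (rho_T - rho_TB) / rho_T * 100

CI > 25 or HR > 1.25 indicates a poorly flowing powder; the two criteria are
cross-checked and discordance is flagged. Note the exact algebraic identity
CI = (1 - 1/HR) * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NeedsMoreTapsError, ValidationError

__all__ = [
    "TappedSeries",
    "PycnometerRun",
    "DensitySummary",
    "FlowClassification",
    "untapped_bulk_density",
    "tapped_density_converge",
    "pycnometer_sample_volume",
    "select_pycnometer_runs",
    "carr_index",
    "hausner_ratio",
    "porosity_percent",
    "classify_flow",
    "summarize_density",
]

CI_POOR_THRESHOLD = 25.0
HR_POOR_THRESHOLD = 1.25
TAP_RULE_PCT = 2.0
PYC_CV_PCT = 0.05


@dataclass(frozen=True)
class TappedSeries:
    """Volumes read after each tap block (first blocks: 500 then 750 taps)."""

    filler_mass: float          # g
    volumes: tuple              # mL after each block
    taps_per_block: tuple = ()  # defaults to (500, 750, 500, 500, ...)

    def __post_init__(self):
        v = tuple(float(x) for x in self.volumes)
        if self.filler_mass <= 0:
            raise ValidationError("filler mass must be positive")
        if any(x <= 0 for x in v):
            raise ValidationError("volumes must be positive")
        if any(b > a for a, b in zip(v, v[1:])):
            raise ValidationError("tapped volumes must be non-increasing")
        taps = self.taps_per_block or (500, 750) + (500,) * max(0, len(v) - 2)
        if len(taps) < len(v):
            raise ValidationError("taps_per_block shorter than volumes")
        if tuple(taps[:2]) != (500, 750):
            raise ValidationError("first two blocks must be 500 then 750 taps")
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "taps_per_block", tuple(taps))


@dataclass(frozen=True)
class PycnometerRun:
    """One gas-pycnometer expansion: reference pressure P1 relaxing to P2."""

    P1: float
    P2: float
    V_chamber: float   # cm^3
    V_reference: float # cm^3
    sample_mass: float # g

    def __post_init__(self):
        # P1 == P2 is the no-displacement formula limit (V_sample = V_chamber)
        if not (self.P1 >= self.P2 > 0):
            raise ValidationError("pressures must satisfy P1 >= P2 > 0")
        if self.V_chamber <= 0 or self.V_reference <= 0:
            raise ValidationError("chamber and reference volumes must be positive")
        if self.sample_mass <= 0:
            raise ValidationError("sample mass must be positive")


@dataclass(frozen=True)
class FlowClassification:
    label: str            # "poor" | "free-flowing"
    poor_by_ci: bool
    poor_by_hr: bool
    concordant: bool


@dataclass(frozen=True)
class DensitySummary:
    product_name: str
    rho_UB: float
    rho_TB: float
    rho_T: float
    carr_index: float
    hausner_ratio: float
    porosity: float
    flow_class: FlowClassification
    ordering_ok: bool  # rho_UB <= rho_TB <= rho_T


def untapped_bulk_density(mass: float, cup_volume: float = 25.0) -> float:
    """Loose bulk density: filler mass over the fixed volumeter cup volume."""
    if mass <= 0:
        raise ValidationError("mass must be positive")
    if cup_volume <= 0:
        raise ValidationError("cup volume must be positive")
    return mass / cup_volume


def tapped_density_converge(series: TappedSeries):
    """Walk the tap blocks until the 2% volume-change stopping rule is met.

    The rule compares consecutive block volumes: stop at the first pair with
    |V_prev - V_cur| / V_prev < 2% (denominator = earlier block). If the
    recorded series ends before the rule is satisfied a NeedsMoreTapsError is
    raised — the measurement needs additional 500-tap blocks, and silent
    truncation would bias the density high.

    Returns (final_volume_mL, rho_TB_g_per_mL).
    """
    v = series.volumes
    if len(v) < 2:
        raise ValidationError("need at least two recorded block volumes")
    for prev, cur in zip(v, v[1:]):
        if 100.0 * abs(prev - cur) / prev < TAP_RULE_PCT:
            return cur, series.filler_mass / cur
    raise NeedsMoreTapsError(
        f"volume change still >= {TAP_RULE_PCT}% after {len(v)} blocks; "
        "perform additional 500-tap blocks"
    )


def pycnometer_sample_volume(run: PycnometerRun) -> float:
    """Sample volume from the two-chamber expansion:
    V_sample = V_chamber + V_reference * (1 - P1/P2)."""
    if run.P2 == 0:
        raise ValidationError("P2 must be nonzero")
    return run.V_chamber + run.V_reference * (1.0 - run.P1 / run.P2)


def run_density(run: PycnometerRun) -> float:
    """True density of one run: sample mass over Eq.-derived sample volume."""
    v = pycnometer_sample_volume(run)
    if v <= 0:
        raise ValidationError("non-physical sample volume (check pressures)")
    return run.sample_mass / v


def select_pycnometer_runs(densities, max_runs: int = 5):
    """Pick the earliest triple of successive run densities with CV% < 0.05.

    'Percent variance' is implemented as the percent coefficient of variation
    100*sd/mean with sample sd. If no triple of a full five-run series
    passes, the final three of the five are used (flagged non-converged).

    Returns (chosen_triple, rho_T, converged).
    """
    vals = [float(x) for x in densities]
    if len(vals) < 3:
        raise ValidationError("need at least 3 pycnometer runs")
    if len(vals) > max_runs:
        raise ValidationError(f"at most {max_runs} runs expected")
    for i in range(len(vals) - 2):
        triple = vals[i:i + 3]
        cv = 100.0 * np.std(triple, ddof=1) / np.mean(triple)
        if cv < PYC_CV_PCT:
            return tuple(triple), float(np.mean(triple)), True
    if len(vals) == max_runs:
        triple = vals[-3:]
        return tuple(triple), float(np.mean(triple)), False
    raise ValidationError(
        "no successive triple met the 0.05% criterion; record further runs"
    )


def carr_index(rho_UB: float, rho_TB: float) -> float:
    """Carr compressibility index (%): (rho_TB - rho_UB)/rho_TB * 100."""
    if rho_TB <= 0:
        raise ValidationError("tapped density must be positive")
    if rho_UB > rho_TB:
        warnings.warn("rho_UB exceeds rho_TB; Carr index will be negative", stacklevel=2)
    return (rho_TB - rho_UB) / rho_TB * 100.0


def hausner_ratio(rho_UB: float, rho_TB: float) -> float:
    """Hausner ratio: rho_TB / rho_UB."""
    if rho_UB <= 0:
        raise ValidationError("untapped density must be positive")
    return rho_TB / rho_UB


def porosity_percent(rho_TB: float, rho_T: float) -> float:
    """Void fraction (%) from tapped bulk and skeletal (true) densities."""
    if rho_T <= 0:
        raise ValidationError("true density must be positive")
    return (rho_T - rho_TB) / rho_T * 100.0


def classify_flow(ci: float, hr: float) -> FlowClassification:
    """Poor-flow call from CI (>25) and HR (>1.25) with concordance check."""
    if not (np.isfinite(ci) and np.isfinite(hr)):
        raise ValidationError("CI and HR must be finite")
    poor_ci = ci > CI_POOR_THRESHOLD
    poor_hr = hr > HR_POOR_THRESHOLD
    label = "poor" if (poor_ci or poor_hr) else "free-flowing"
    return FlowClassification(
        label=label,
        poor_by_ci=poor_ci,
        poor_by_hr=poor_hr,
        concordant=poor_ci == poor_hr,
    )


def summarize_density(product_name: str, rho_UB: float, rho_TB: float,
                      rho_T: float) -> DensitySummary:
    """Assemble the derived-metric summary for one product."""
    ci = carr_index(rho_UB, rho_TB)
    hr = hausner_ratio(rho_UB, rho_TB)
    por = porosity_percent(rho_TB, rho_T)
    ordering_ok = rho_UB <= rho_TB <= rho_T
    if not ordering_ok:
        warnings.warn(
            f"{product_name}: density ordering rho_UB <= rho_TB <= rho_T violated",
            stacklevel=2,
        )
    return DensitySummary(
        product_name=product_name,
        rho_UB=rho_UB, rho_TB=rho_TB, rho_T=rho_T,
        carr_index=ci, hausner_ratio=hr, porosity=por,
        flow_class=classify_flow(ci, hr),
        ordering_ok=ordering_ok,
    )
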