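"""Solubility, moisture (oven volatiles), water activity, pH, and viscosity
summaries for pouch fillers.

The solubility assay shakes 1 g of filler in artificial saliva, filters, and
weighs the dried insoluble residue on a pre-weighed filter paper. The mass
balance

    insoluble% = (m_final - m_paper) / m_filler * 100

gives the insoluble fraction directly; the soluble fraction is its
complement. Both are exposed: the reported per-product "percent soluble"
column is the complement, matching how the panel values are quoted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "SolubilityMeasurement",
    "ExtractRecord",
    "FlowCurve",
    "WaterActivityCheck",
    "percent_insoluble",
    "percent_soluble",
    "oven_volatiles_pct",
    "validate_water_activity_calibration",
    "flow_curve_summary",
    "WATER_ACTIVITY_STANDARDS",
]

WATER_ACTIVITY_STANDARDS = (0.250, 0.500, 0.760, 0.920)


@dataclass(frozen=True)
class SolubilityMeasurement:
    m_filler: float  # g of filler shaken in saliva
    m_paper: float   # g, pre-weighed filter paper
    m_final: float   # g, paper + dried insoluble residue

    def __post_init__(self):
        if self.m_filler <= 0:
            raise ValidationError("filler mass must be positive")
        if self.m_final < self.m_paper:
            raise ValidationError("final mass cannot be below the paper mass")


@dataclass(frozen=True)
class ExtractRecord:
    product_name: str
    ov_mass_before: float
    ov_mass_after: float
    pH: float
    water_activity: float
    temperature: float = 25.0

    def __post_init__(self):
        if not 0.0 <= self.water_activity <= 1.0:
            raise ValidationError("water activity must lie in [0, 1]")
        if not 0.0 <= self.pH <= 14.0:
            raise ValidationError("pH must lie in [0, 14]")
        if self.ov_mass_after > self.ov_mass_before:
            raise ValidationError("mass cannot increase during oven volatiles run")


@dataclass(frozen=True)
class FlowCurve:
    """Viscosity vs shear-rate sweep (1-100 1/s window for extracts)."""

    shear_rates: np.ndarray  # 1/s
    viscosities: np.ndarray  # cP

    def __post_init__(self):
        g = np.asarray(self.shear_rates, dtype=float)
        v = np.asarray(self.viscosities, dtype=float)
        if g.shape != v.shape:
            raise ValidationError("shear rates and viscosities must align")
        if g.size and np.any(np.diff(g) <= 0):
            raise ValidationError("shear rates must be strictly increasing")
        if np.any(v <= 0):
            raise ValidationError("viscosities must be positive")
        object.__setattr__(self, "shear_rates", g)
        object.__setattr__(self, "viscosities", v)


@dataclass(frozen=True)
class WaterActivityCheck:
    passed: bool
    deviations: dict
    tolerance: float


def percent_insoluble(m: SolubilityMeasurement) -> float:
    """Dried residue mass as percent of the filler mass (literal mass balance)."""
    return 100.0 * (m.m_final - m.m_paper) / m.m_filler


def percent_soluble(m: SolubilityMeasurement) -> float:
    """Soluble fraction: complement of the insoluble mass balance."""
    return 100.0 - percent_insoluble(m)


def oven_volatiles_pct(before: float, after: float) -> float:
    """Percent moisture content proxy: mass loss over initial mass * 100."""
    if before <= 0:
        raise ValidationError("initial mass must be positive")
    if after > before:
        raise ValidationError("mass cannot increase during the run")
    if after < 0:
        raise ValidationError("final mass cannot be negative")
    return 100.0 * (before - after) / before


def validate_water_activity_calibration(readings: dict, tolerance: float = 0.005) -> WaterActivityCheck:
    """Check instrument readings at the four verification standards.

    `readings` maps nominal standard value -> observed reading. Every
    standard must be present; pass requires |observed - nominal| <= tolerance
    at each one.
    """
    deviations = {}
    for nominal in WATER_ACTIVITY_STANDARDS:
        if nominal not in readings:
            raise ValidationError(f"missing reading for standard {nominal}")
        deviations[nominal] = float(readings[nominal]) - nominal
    passed = all(abs(d) <= tolerance for d in deviations.values())
    return WaterActivityCheck(passed=passed, deviations=deviations, tolerance=tolerance)


def flow_curve_summary(curve: FlowCurve):
    """Mean viscosity over the sweep and the power-law flow index.

    The flow index is the least-squares slope of log(viscosity) vs
    log(shear rate): 0 for a Newtonian fluid, negative for shear-thinning.
    Returns (mean_viscosity_cP, flow_index).
    """
    if curve.shear_rates.size < 3:
        raise ValidationError("need at least 3 points on the flow curve")
    slope = np.polyfit(np.log(curve.shear_rates), np.log(curve.viscosities), 1)[0]
    return float(curve.viscosities.mean()), float(slope)
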