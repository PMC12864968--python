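"""DSC thermogram analysis: baseline subtraction, enthalpy integration,
melting-event extraction, and glass-transition location.

A thermogram is heat flow (W/g) on an ascending temperature grid recorded at
a constant ramp (°C/min). Enthalpies are time integrals, so the quadrature
uses dt = dT * 60 / ramp seconds per °C. Melting peaks may point up or down
depending on the instrument's endotherm convention (default endo-down);
enthalpy is always reported as a magnitude. Onset temperature follows the
standard tangent construction: the tangent at the steepest point of the
leading edge is extrapolated to the (subtracted) zero baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "Thermogram",
    "ThermalEvent",
    "BaselineResult",
    "subtract_baseline",
    "integrate_enthalpy",
    "melting_event",
    "glass_transition",
]


@dataclass(frozen=True)
class Thermogram:
    temperatures: np.ndarray  # °C, strictly increasing
    heat_flow: np.ndarray     # W/g
    ramp: float               # °C/min
    sample_mass: float | None = None  # mg, if the signal is un-normalized

    def __post_init__(self):
        T = np.asarray(self.temperatures, dtype=float)
        h = np.asarray(self.heat_flow, dtype=float)
        if T.shape != h.shape:
            raise ValidationError("temperature and heat-flow arrays must align")
        if T.size < 2 or np.any(np.diff(T) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if self.ramp <= 0:
            raise ValidationError("ramp must be positive")
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "heat_flow", h)


@dataclass(frozen=True)
class ThermalEvent:
    onset_T: float
    peak_T: float
    enthalpy: float  # J/g, magnitude
    kind: str        # "melting" | "glass_transition"

    def __post_init__(self):
        if self.kind == "melting" and self.onset_T > self.peak_T + 1e-9:
            raise ValidationError("onset must not exceed the peak temperature")
        if self.kind == "melting" and self.enthalpy < 0:
            raise ValidationError("melting enthalpy reported as magnitude")


@dataclass(frozen=True)
class BaselineResult:
    corrected: np.ndarray
    slope: float
    intercept: float
    contaminated: bool  # anchors appear to sit on the event itself


def _window_mask(T: np.ndarray, window) -> np.ndarray:
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValidationError("window must be (low, high) with low < high")
    if hi < T[0] or lo > T[-1]:
        raise ValidationError("window lies outside the recorded temperature range")
    mask = (T >= lo) & (T <= hi)
    if mask.sum() < 2:
        raise ValidationError("window must contain at least 2 points")
    return mask


def _robust_noise_sd(x: np.ndarray) -> float:
    # MAD of first differences; /sqrt(2) maps back to per-sample sd
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def subtract_baseline(t: Thermogram, anchor_low, anchor_high) -> BaselineResult:
    """Remove a linear baseline anchored in two event-free windows.

    The line passes through the centroid of the signal within each anchor
    window. If either window itself shows curvature far above the noise
    floor, the anchors likely sit on the event and the result is flagged
    contaminated (a warning, not an error).
    """
    T, h = t.temperatures, t.heat_flow
    m1, m2 = _window_mask(T, anchor_low), _window_mask(T, anchor_high)
    x1, y1 = T[m1].mean(), h[m1].mean()
    x2, y2 = T[m2].mean(), h[m2].mean()
    if x1 == x2:
        raise ValidationError("anchor windows must be at distinct temperatures")
    slope = (y2 - y1) / (x2 - x1)
    intercept = y1 - slope * x1
    corrected = h - (slope * T + intercept)

    # an anchor window sitting on the event shows curvature (residual from its
    # own local line fit) far above the robust noise floor
    noise = _robust_noise_sd(h)
    scale = max(float(np.abs(h).max()), 1e-30)
    contaminated = False
    for m in (m1, m2):
        resid = h[m] - np.polyval(np.polyfit(T[m], h[m], 1), T[m])
        if np.abs(resid).max() > max(5.0 * noise, 1e-9 * scale):
            contaminated = True
    if contaminated:
        warnings.warn("anchor windows deviate strongly from the fitted baseline; "
                      "they may overlap the thermal event", stacklevel=2)
    return BaselineResult(corrected=corrected, slope=slope,
                          intercept=intercept, contaminated=contaminated)


def integrate_enthalpy(temperatures, corrected, region, ramp: float) -> float:
    """Trapezoidal |signal| area over the region, converted to J/g via the ramp.

    dt = dT * 60 / ramp (seconds per °C at `ramp` °C/min), so the area under
    a W/g signal in the temperature domain integrates to J/g.
    """
    if ramp <= 0:
        raise ValidationError("ramp must be positive")
    T = np.asarray(temperatures, dtype=float)
    mask = _window_mask(T, region)
    return float(np.trapezoid(np.abs(np.asarray(corrected)[mask]), T[mask]) * 60.0 / ramp)


def melting_event(temperatures, corrected, region, ramp: float,
                  endo_down: bool = True, noise_floor: float | None = None) -> ThermalEvent | None:
    """Extract one melting transition from a baseline-corrected region.

    peak_T is the temperature of the extremum of the oriented signal in the
    region; onset_T is the zero-baseline intercept of the tangent at the
    steepest point of the leading edge. Returns None when no extremum rises
    above the noise floor (default 5x a robust noise estimate).
    """
    T = np.asarray(temperatures, dtype=float)
    s = np.asarray(corrected, dtype=float)
    mask = _window_mask(T, region)
    Tr, sr = T[mask], s[mask]
    oriented = -sr if endo_down else sr
    # the dominant extremum may still be on the other side (sign convention
    # mismatch); use magnitude to find it, oriented sign only for the tangent
    ipk = int(np.argmax(np.abs(sr)))
    if np.abs(sr[ipk]) <= 0:
        return None
    floor = noise_floor if noise_floor is not None else 5.0 * _robust_noise_sd(s)
    if np.abs(sr[ipk]) < max(floor, 1e-15):
        return None
    sign = np.sign(sr[ipk])
    up = sign * sr  # event now points up
    peak_T = float(Tr[ipk])

    if ipk == 0:
        onset_T = peak_T
    else:
        grad = np.gradient(up[: ipk + 1], Tr[: ipk + 1])
        imax = int(np.argmax(grad))
        slope = grad[imax]
        if slope <= 0:
            onset_T = float(Tr[0])
        else:
            onset_T = float(Tr[imax] - up[imax] / slope)
            onset_T = min(max(onset_T, float(Tr[0])), peak_T)
    dH = integrate_enthalpy(T, s, region, ramp)
    return ThermalEvent(onset_T=onset_T, peak_T=peak_T, enthalpy=dH, kind="melting")


def glass_transition(t: Thermogram, window, min_step: float | None = None) -> ThermalEvent | None:
    """Locate a glass transition as the midpoint of a baseline step.

    Lines are fitted to the outer 20% of the window on each side (so a
    sloped instrument baseline does not bias the construction); the step
    height is their separation at the window centre, and T_g is where the
    signal first crosses the midline between the two fitted baselines
    (linear interpolation between samples). Returns None when the step
    height does not exceed `min_step` (default 5x a robust noise estimate).
    """
    T, h = t.temperatures, t.heat_flow
    mask = _window_mask(T, window)
    Tw, hw = T[mask], h[mask]
    n = len(Tw)
    edge = max(2, n // 5)
    pre_line = np.polyfit(Tw[:edge], hw[:edge], 1)
    post_line = np.polyfit(Tw[-edge:], hw[-edge:], 1)
    center = 0.5 * (Tw[0] + Tw[-1])
    step = float(np.polyval(post_line, center) - np.polyval(pre_line, center))
    floor = min_step if min_step is not None else 5.0 * _robust_noise_sd(h)
    if abs(step) < max(floor, 1e-15):
        return None
    midline = 0.5 * (np.polyval(pre_line, Tw) + np.polyval(post_line, Tw))
    resid = hw - midline
    sgn = np.sign(step)
    crossed = np.nonzero(sgn * resid >= 0)[0]
    crossed = crossed[crossed >= edge - 1]
    if crossed.size == 0:
        return None
    j = int(crossed[0])
    if j == 0:
        Tg = float(Tw[0])
    else:
        y0, y1 = resid[j - 1], resid[j]
        frac = (0.0 - y0) / (y1 - y0) if y1 != y0 else 0.0
        Tg = float(Tw[j - 1] + frac * (Tw[j] - Tw[j - 1]))
    return ThermalEvent(onset_T=Tg, peak_T=Tg, enthalpy=0.0, kind="glass_transition")
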