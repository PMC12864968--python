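"""First-order dissolution kinetics.

Cumulative nicotine release from a pouch into artificial saliva is modelled
as first-order in the remaining releasable amount,

    M_rel(t) = M0 * (1 - exp(-k t)),

with M0 the total releasable nicotine (mg) and k the release rate constant
(1/min). This module builds cumulative profiles from collected fractions,
normalizes them (percent of total release, percent of M0), fits the model by
bounded nonlinear least squares, and predicts release percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import AlignmentError, UndefinedNormalizationError, ValidationError

__all__ = [
    "DissolutionProfile",
    "KineticFit",
    "ProductRecord",
    "MeanProfile",
    "first_order_release",
    "cumulate_fractions",
    "percent_of_total_release",
    "percent_of_M0",
    "fit_first_order",
    "predict_percent_released",
    "percent_released_from_content",
    "average_profile",
]

K_LOWER = 1e-6
K_UPPER = 10.0


def first_order_release(t, M0: float, k: float):
    """Evaluate M0*(1-exp(-k t)) elementwise."""
    return M0 * (1.0 - np.exp(-k * np.asarray(t, dtype=float)))


@dataclass(frozen=True)
class DissolutionProfile:
    """One replicate's fraction-level and cumulative release time series."""

    product_name: str
    replicate_id: int
    times: np.ndarray
    fraction_mg: np.ndarray
    cumulative_mg: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_mg, dtype=float)
        c = np.asarray(self.cumulative_mg, dtype=float)
        if not (len(t) == len(f) == len(c)):
            raise ValidationError("times, fraction_mg, cumulative_mg must have equal length")
        if len(t) == 0:
            raise ValidationError("empty profile")
        if np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValidationError("times must be strictly increasing and positive")
        if np.any(f < 0):
            raise ValidationError("fraction masses must be non-negative")
        if np.max(np.abs(c - np.cumsum(f))) > 1e-9:
            raise ValidationError("cumulative_mg must be the prefix sum of fraction_mg")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_mg", f)
        object.__setattr__(self, "cumulative_mg", c)


@dataclass(frozen=True)
class KineticFit:
    """Estimated (M0, k) with least-squares diagnostics for one profile."""

    M0: float
    k: float
    rss: float
    converged: bool
    n_points: int

    def __post_init__(self):
        if self.M0 <= 0:
            raise ValidationError("M0 must be positive")
        if self.converged and self.k <= 0:
            raise ValidationError("k must be positive for a converged fit")
        if self.rss < 0:
            raise ValidationError("rss must be non-negative")


@dataclass(frozen=True)
class ProductRecord:
    """Scalar per-product quantities used to normalize release."""

    product_name: str
    pouch_weight_g: float
    labeled_nicotine_mg: float
    experimental_nicotine_mg: float

    def __post_init__(self):
        for name in ("pouch_weight_g", "labeled_nicotine_mg", "experimental_nicotine_mg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class MeanProfile:
    """Pointwise mean and 1-sigma sample sd across replicates."""

    product_name: str
    times: np.ndarray
    mean_mg: np.ndarray
    sd_mg: np.ndarray
    n_replicates: int
    sd_defined: bool = field(default=True)


def cumulate_fractions(product_name, replicate_id, times, fraction_mg) -> DissolutionProfile:
    """Build a DissolutionProfile from per-fraction masses via prefix sum."""
    f = np.asarray(fraction_mg, dtype=float)
    if np.any(f < 0):
        raise ValidationError("fraction masses must be non-negative")
    return DissolutionProfile(
        product_name=product_name,
        replicate_id=int(replicate_id),
        times=np.asarray(times, dtype=float),
        fraction_mg=f,
        cumulative_mg=np.cumsum(f),
    )


def percent_of_total_release(profile: DissolutionProfile) -> np.ndarray:
    """Cumulative release as percent of the 60-min (final) cumulative amount.

    The last element is exactly 100 by construction.
    """
    total = profile.cumulative_mg[-1]
    if total <= 0:
        raise UndefinedNormalizationError("total release is zero; cannot normalize")
    # divide first: the final element is then exactly 100.0
    return 100.0 * (profile.cumulative_mg / total)


def percent_of_M0(profile: DissolutionProfile, fit: KineticFit) -> np.ndarray:
    """Cumulative release as percent of the fitted releasable amount M0."""
    if fit.M0 <= 0:
        raise ValidationError("fit.M0 must be positive")
    return 100.0 * profile.cumulative_mg / fit.M0


def fit_first_order(times, cumulative_mg=None) -> KineticFit:
    """Fit M0*(1-exp(-k t)) to a cumulative profile by bounded least squares.

    Accepts either a DissolutionProfile or explicit (times, cumulative) arrays.
    Initialization: M0 at the final cumulative value, k from a one-point
    closed-form inversion at the first time point clipped to [1e-4, 1].
    Bounds: M0 in (0, 10*final], k in [1e-6, 10]. Unweighted loss. A fit that
    terminates at a k bound (degenerate shape, e.g. an already-flat series)
    is flagged converged=False rather than silently reported.
    """
    if cumulative_mg is None:
        profile = times
        t = profile.times
        c = profile.cumulative_mg
    else:
        t = np.asarray(times, dtype=float)
        c = np.asarray(cumulative_mg, dtype=float)
    if len(t) < 3:
        raise ValidationError("need at least 3 time points to fit")
    if c[-1] <= 0:
        raise ValidationError("no release to fit")

    M0_0 = float(c[-1])
    ratio = c[0] / M0_0
    if 0.0 < ratio < 1.0:
        k0 = -np.log1p(-ratio) / t[0]
    else:
        k0 = 1.0
    k0 = float(np.clip(k0, 1e-4, 1.0))

    def residuals(p):
        return first_order_release(t, p[0], p[1]) - c

    sol = least_squares(
        residuals,
        x0=[M0_0, k0],
        bounds=([1e-12, K_LOWER], [10.0 * M0_0, K_UPPER]),
        method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    M0_hat, k_hat = float(sol.x[0]), float(sol.x[1])
    at_bound = k_hat <= K_LOWER * (1 + 1e-6) or k_hat >= K_UPPER * (1 - 1e-6)
    # rate unresolved when the rise completed before the first sample
    # (constant series: any sufficiently large k fits equally well)
    unresolved = np.exp(-k_hat * t[0]) < 1e-9
    return KineticFit(
        M0=M0_hat,
        k=k_hat,
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success and not at_bound and not unresolved),
        n_points=len(t),
    )


def predict_percent_released(fit, t: float) -> float:
    """Percent of M0 released by time t under the fitted model: 100(1-e^(-kt))."""
    k = fit.k if isinstance(fit, KineticFit) else float(fit)
    if t < 0:
        raise ValidationError("t must be non-negative")
    return float(100.0 * (1.0 - np.exp(-k * t)))


def percent_released_from_content(profile: DissolutionProfile, record: ProductRecord) -> float:
    """Final cumulative release as percent of the measured nicotine content."""
    if record.experimental_nicotine_mg <= 0:
        raise ValidationError("experimental nicotine content must be positive")
    return float(100.0 * profile.cumulative_mg[-1] / record.experimental_nicotine_mg)


def average_profile(replicates) -> MeanProfile:
    """Pointwise mean and sample sd (ddof=1) of replicate cumulative curves.

    All replicates must share the same time grid. With a single replicate the
    sd is reported as zero and flagged sd_defined=False.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValidationError("no replicates")
    t0 = replicates[0].times
    for r in replicates[1:]:
        if len(r.times) != len(t0) or np.any(r.times != t0):
            raise AlignmentError("replicates do not share a common time grid")
    stack = np.vstack([r.cumulative_mg for r in replicates])
    mean = stack.mean(axis=0)
    if len(replicates) == 1:
        sd = np.zeros_like(mean)
        sd_defined = False
    else:
        sd = stack.std(axis=0, ddof=1)
        sd_defined = True
    return MeanProfile(
        product_name=replicates[0].product_name,
        times=t0,
        mean_mg=mean,
        sd_mg=sd,
        n_replicates=len(replicates),
        sd_defined=sd_defined,
    )
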