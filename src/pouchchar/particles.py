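"""Particle-size distribution statistics for EQPC diameter samples.

Dynamic image analysis reports each particle as the diameter of the circle
with the same projected area (EQPC). Distributions are weighted either by
count (q0: every particle weight 1) or by volume (q3: weight proportional to
d^3). For each weighting we report the weighted arithmetic mean, the d10,
d50, d90 intercepts of the cumulative curve, and the span (d90-d10)/d50.

Quantile convention: linear interpolation of the cumulative weighted CDF
between consecutive sorted unique diameters; levels at or below the first
cumulative value map to the smallest diameter. Ties are aggregated before
interpolation. The same convention is applied between bin edges on the
binned path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .study import DIA_RANGE_UM

__all__ = [
    "ParticleSample",
    "SizeDistribution",
    "DistributionStats",
    "eqpc_from_area",
    "area_from_eqpc",
    "geometric_edges",
    "build_distribution",
    "distribution_stats",
    "sample_stats",
    "span",
    "weighted_quantile",
]


def eqpc_from_area(projected_area):
    """Diameter of the circle with the given projected area: d = 2*sqrt(A/pi)."""
    a = np.asarray(projected_area, dtype=float)
    if np.any(a <= 0):
        raise ValidationError("projected area must be positive")
    return 2.0 * np.sqrt(a / np.pi)


def area_from_eqpc(diameter):
    """Projected circle area for a given EQPC diameter (inverse of eqpc_from_area)."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("diameter must be positive")
    return np.pi * (d / 2.0) ** 2


@dataclass(frozen=True)
class ParticleSample:
    """A set of EQPC diameters (µm), optionally checked against the lens range."""

    diameters: np.ndarray
    instrument_like: bool = False
    out_of_range: np.ndarray = field(init=False)

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=float)
        if d.size and np.any(d <= 0):
            raise ValidationError("diameters must be positive")
        object.__setattr__(self, "diameters", d)
        lo, hi = DIA_RANGE_UM
        oor = (d < lo) | (d > hi)
        object.__setattr__(self, "out_of_range", oor)
        if self.instrument_like and oor.any():
            warnings.warn(
                f"{int(oor.sum())} particle(s) outside the {lo}-{hi} um instrument range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SizeDistribution:
    """Binned weighted distribution with the generating sample retained."""

    bin_edges: np.ndarray
    density: np.ndarray        # per-bin weight fraction, sums to 1
    cumulative: np.ndarray     # at upper edges, ends at 1
    weighting: str             # "q0" | "q3"
    diameters: np.ndarray = None
    weights: np.ndarray = None

    def __post_init__(self):
        if abs(float(np.sum(self.density)) - 1.0) > 1e-9:
            raise ValidationError("density must sum to 1")
        if np.any(np.diff(self.cumulative) < -1e-12):
            raise ValidationError("cumulative must be non-decreasing")
        if abs(float(self.cumulative[-1]) - 1.0) > 1e-9:
            raise ValidationError("cumulative must end at 1")


@dataclass(frozen=True)
class DistributionStats:
    mean: float
    d10: float
    d50: float
    d90: float
    span: float

    def __post_init__(self):
        if not (self.d10 <= self.d50 <= self.d90):
            raise ValidationError("quantiles must be ordered d10 <= d50 <= d90")


def geometric_edges(lo: float = DIA_RANGE_UM[0], hi: float = DIA_RANGE_UM[1],
                    n_bins: int = 31) -> np.ndarray:
    """Geometric (log-spaced) bin edges; default covers the M8 lens range."""
    if lo <= 0 or hi <= lo or n_bins < 1:
        raise ValidationError("need 0 < lo < hi and n_bins >= 1")
    return np.geomspace(lo, hi, n_bins + 1)


def _weights_for(diameters: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "q0":
        w = np.ones_like(diameters)
    elif weighting == "q3":
        w = diameters**3
    else:
        raise ValidationError(f"unknown weighting {weighting!r} (use 'q0' or 'q3')")
    return w / w.sum()


def build_distribution(sample, weighting: str = "q0", bin_edges=None) -> SizeDistribution:
    """Bin a particle sample under the requested weighting.

    The raw diameters and normalized weights ride along on the result so that
    statistics can use exact (bin-free) interpolation.
    """
    d = sample.diameters if isinstance(sample, ParticleSample) else np.asarray(sample, float)
    if d.size == 0:
        raise ValidationError("empty particle sample")
    if np.any(d <= 0):
        raise ValidationError("diameters must be positive")
    w = _weights_for(d, weighting)
    if bin_edges is None:
        lo = min(d.min() * 0.999, DIA_RANGE_UM[0])
        hi = max(d.max() * 1.001, DIA_RANGE_UM[1])
        edges = geometric_edges(lo, hi)
    else:
        edges = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
    hist, _ = np.histogram(d, bins=edges, weights=w)
    total = hist.sum()
    if total <= 0:
        raise ValidationError("all particles fall outside the given bins")
    density = hist / total
    return SizeDistribution(
        bin_edges=edges,
        density=density,
        cumulative=np.cumsum(density),
        weighting=weighting,
        diameters=d,
        weights=w,
    )


def weighted_quantile(diameters, weights, levels) -> np.ndarray:
    """Interpolated quantiles of a weighted empirical CDF (ties aggregated)."""
    d = np.asarray(diameters, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.size == 0:
        raise ValidationError("empty sample")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValidationError("weights must be non-negative with positive sum")
    order = np.argsort(d, kind="stable")
    d, w = d[order], w[order]
    uniq, inverse = np.unique(d, return_inverse=True)
    agg = np.zeros_like(uniq)
    np.add.at(agg, inverse, w)
    cdf = np.cumsum(agg) / agg.sum()
    levels = np.asarray(levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValidationError("quantile levels must lie in [0, 1]")
    # np.interp clamps below cdf[0] to uniq[0] and above 1 to uniq[-1]
    return np.interp(levels, cdf, uniq)


def sample_stats(sample, weighting: str = "q0") -> DistributionStats:
    """Weighted mean, d10/d50/d90 intercepts, and span of a diameter sample."""
    d = sample.diameters if isinstance(sample, ParticleSample) else np.asarray(sample, float)
    if d.size == 0:
        raise ValidationError("empty particle sample")
    w = _weights_for(d, weighting)
    q10, q50, q90 = weighted_quantile(d, w, [0.10, 0.50, 0.90])
    return DistributionStats(
        mean=float(np.sum(w * d)),
        d10=float(q10), d50=float(q50), d90=float(q90),
        span=span(float(q10), float(q50), float(q90)),
    )


def distribution_stats(dist: SizeDistribution) -> DistributionStats:
    """Statistics of a SizeDistribution.

    Uses the attached raw sample (exact path) when available; otherwise
    interpolates the binned cumulative curve between edges and takes the mean
    over bin geometric midpoints.
    """
    if dist.diameters is not None:
        return sample_stats(dist.diameters, dist.weighting)
    edges = dist.bin_edges
    cum = np.concatenate([[0.0], dist.cumulative])
    if cum[-1] < 0.9:
        raise ValidationError("cumulative distribution does not reach the 90% level")
    q10, q50, q90 = np.interp([0.10, 0.50, 0.90], cum, edges)
    mids = np.sqrt(edges[:-1] * edges[1:])
    return DistributionStats(
        mean=float(np.sum(dist.density * mids)),
        d10=float(q10), d50=float(q50), d90=float(q90),
        span=span(float(q10), float(q50), float(q90)),
    )


def span(d10: float, d50: float, d90: float) -> float:
    """Distribution span (d90 - d10) / d50; 0 means a perfectly uniform size."""
    if d50 <= 0:
        raise ValidationError("d50 must be positive")
    return float((d90 - d10) / d50)
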