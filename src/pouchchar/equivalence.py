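"""Dissolution profile equivalency: difference factor f1 and similarity factor f2.

Two percent-release profiles R (reference) and T (test) on a common time grid
are compared with the regulatory model-independent factors

    f1 = 100 * sum|R_t - T_t| / sum(R_t)
    f2 = 50 * log10( 100 / sqrt(1 + (1/n) * sum (R_t - T_t)^2) )

Profiles are declared equivalent when f1 <= 15 and f2 >= 50 (both bounds
inclusive). f2 is symmetric in its arguments; f1 is not (the reference sum is
the denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, UndefinedNormalizationError, ValidationError

__all__ = [
    "EquivalenceResult",
    "difference_factor_f1",
    "similarity_factor_f2",
    "assess_equivalence",
    "F1_MAX",
    "F2_MIN",
]

F1_MAX = 15.0
F2_MIN = 50.0


@dataclass(frozen=True)
class EquivalenceResult:
    f1: float
    f2: float
    equivalent: bool
    n_timepoints_used: int
    reference_name: str = "reference"
    test_name: str = "test"


def _aligned(reference, test):
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.shape != t.shape:
        raise AlignmentError("reference and test series must share a common grid")
    if r.size == 0:
        raise ValidationError("empty series")
    return r, t


def difference_factor_f1(reference, test) -> float:
    """Percent cumulative absolute difference relative to the reference sum."""
    r, t = _aligned(reference, test)
    denom = r.sum()
    if denom <= 0:
        raise UndefinedNormalizationError("reference series sums to zero")
    return float(100.0 * np.abs(r - t).sum() / denom)


def similarity_factor_f2(reference, test) -> float:
    """Logarithmic reciprocal-transformed mean squared difference; 100 iff R=T."""
    r, t = _aligned(reference, test)
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def assess_equivalence(
    f1: float,
    f2: float,
    *,
    n_timepoints_used: int = 0,
    reference_name: str = "reference",
    test_name: str = "test",
) -> EquivalenceResult:
    """Apply the inclusive decision rule f1 <= 15 and f2 >= 50."""
    if not (np.isfinite(f1) and np.isfinite(f2)):
        raise ValidationError("f1 and f2 must be finite")
    return EquivalenceResult(
        f1=float(f1),
        f2=float(f2),
        equivalent=bool(f1 <= F1_MAX and f2 >= F2_MIN),
        n_timepoints_used=int(n_timepoints_used),
        reference_name=reference_name,
        test_name=test_name,
    )


def compare_profiles(
    reference,
    test,
    *,
    reference_name: str = "reference",
    test_name: str = "test",
    cap_85: bool = False,
) -> EquivalenceResult:
    """Compute f1, f2 and the decision for two percent-release series.

    With cap_85=True, points after the first at which the reference exceeds
    85% release are dropped (one point beyond 85% is retained), following the
    common regulatory truncation convention. Default keeps every common point.
    """
    r, t = _aligned(reference, test)
    if cap_85:
        over = np.nonzero(r > 85.0)[0]
        if over.size:
            r, t = r[: over[0] + 1], t[: over[0] + 1]
    f1 = difference_factor_f1(r, t)
    f2 = similarity_factor_f2(r, t)
    return assess_equivalence(
        f1, f2, n_timepoints_used=r.size,
        reference_name=reference_name, test_name=test_name,
    )
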