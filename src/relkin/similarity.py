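"""Model-independent dissolution-profile comparison: f1 and f2 factors.

The difference factor f1 and similarity factor f2 (Moore-Flanner, as adopted
by the FDA/CDER dissolution guidance) compare a test release profile T
against a reference R over paired time points:

    f1 = 100 * sum|R_t - T_t| / sum(R_t)
    f2 = 50 * log10( 100 / sqrt(1 + mean((R_t - T_t)^2)) )

Two profiles are declared similar when f1 <= 15 and f2 >= 50.  Note f1 is
not symmetric in (R, T) — its denominator uses the reference only — while f2
is symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import ReleaseProfile

__all__ = [
    "ComparisonResult",
    "difference_factor",
    "similarity_factor",
    "compare",
    "F1_SIMILAR_MAX",
    "F2_SIMILAR_MIN",
]

F1_SIMILAR_MAX = 15.0
F2_SIMILAR_MIN = 50.0


@dataclass(frozen=True)
class ComparisonResult:
    """f1/f2 comparison of a test profile against a reference."""

    reference_id: str
    test_id: str
    f1: float
    f2: float
    n_points: int
    verdict: str  # "similar" | "not_similar"
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _paired(R, T) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(R, dtype=float)
    t = np.asarray(T, dtype=float)
    if r.shape != t.shape or r.ndim != 1:
        raise ValueError("reference and test vectors must be 1-D and equal length")
    if len(r) < 1:
        raise ValueError("at least one paired time point required")
    return r, t


def difference_factor(R: Sequence[float], T: Sequence[float]) -> float:
    """f1 = 100 * sum|R - T| / sum(R); undefined when sum(R) = 0."""
    r, t = _paired(R, T)
    denom = float(np.sum(r))
    if denom == 0.0:
        raise ValueError("f1 undefined: reference releases sum to zero")
    return float(100.0 * np.sum(np.abs(r - t)) / denom)


def similarity_factor(R: Sequence[float], T: Sequence[float]) -> float:
    """f2 = 50 * log10(100 / sqrt(1 + mean squared difference))."""
    r, t = _paired(R, T)
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * math.log10(100.0 / math.sqrt(1.0 + msd)))


def verdict_from_factors(f1: float, f2: float) -> str:
    """Similar iff f1 in [0, 15] and f2 in [50, 100]."""
    return "similar" if (f1 <= F1_SIMILAR_MAX and f2 >= F2_SIMILAR_MIN) else "not_similar"


def compare(
    reference: ReleaseProfile,
    test: ReleaseProfile,
    interpolate: bool = False,
) -> ComparisonResult:
    """Compare two release profiles on their common time grid.

    By default the profiles must share sampling times exactly; with
    ``interpolate`` the test profile is linearly interpolated onto the
    reference grid.  Fewer than 3 common points and the high-release caution
    (more than one reference point above 85 %) are reported as warnings, not
    errors.
    """
    warnings_: list[str] = []
    if interpolate:
        r_t = reference.times
        r_y = reference.release_mean
        t_y = np.interp(r_t, test.times, test.release_mean)
    else:
        common, r_idx, t_idx = np.intersect1d(
            reference.times, test.times, return_indices=True
        )
        if len(common) == 0:
            raise ValueError(
                "profiles share no sampling times; pass interpolate=True to "
                "compare on the reference grid"
            )
        r_y = reference.release_mean[r_idx]
        t_y = test.release_mean[t_idx]
    if len(r_y) < 3:
        warnings_.append(f"only {len(r_y)} common time points (fewer than 3)")
    if int(np.sum(r_y > 85.0)) > 1:
        warnings_.append("more than one reference point above 85 % release")
    f1 = difference_factor(r_y, t_y)
    f2 = similarity_factor(r_y, t_y)
    return ComparisonResult(
        reference_id=reference.formulation_id,
        test_id=test.formulation_id,
        f1=f1,
        f2=f2,
        n_points=len(r_y),
        verdict=verdict_from_factors(f1, f2),
        warnings=tuple(warnings_),
    )
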