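"""Cell-assay arithmetic: viability %, doubling time and IC50 estimation.

Viability is the treated/control optical-density ratio on a percent scale
(WST-1 style readout).  Doubling time comes from a two-point exponential
growth fit:

    t_d = duration * log(2) / (log(N_final) - log(N_initial))

which is invariant to the logarithm base and to rescaling both counts.  IC50
is estimated from a dose-response table by a four-parameter logistic (4PL)
fit on log-concentration:

    v(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

with hill > 0 giving the usual decreasing viability curve.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GrowthObservation",
    "DoseResponseTable",
    "IC50Result",
    "viability_percent",
    "normalize_to_vehicle",
    "doubling_time",
    "four_param_logistic",
    "fit_ic50",
    "PAPER_CONCENTRATIONS_UM",
]

#: Two-fold dilution series used in the dose-response design, in µM.
PAPER_CONCENTRATIONS_UM = (0.4, 0.8, 1.6, 3.2, 6.4, 12.8)


@dataclass(frozen=True)
class GrowthObservation:
    """Paired cell counts (same basis, e.g. per well) over a duration in hours."""

    initial_count: float
    final_count: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.initial_count > 0 and self.final_count > 0):
            raise ValueError("cell counts must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class DoseResponseTable:
    """Viability (percent of control) versus drug concentration (µM)."""

    concentrations: np.ndarray
    viability: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        v = np.asarray(self.viability, dtype=float)
        order = np.argsort(c)
        c, v = c[order], v[order]
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "viability", v)
        if c.ndim != 1 or v.shape != c.shape:
            raise ValueError("concentrations and viability must be 1-D, equal length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if len(np.unique(c)) != len(c):
            raise ValueError("duplicate concentrations; aggregate replicates first")
        if not np.all(np.isfinite(v)):
            raise ValueError("viability must be finite")


@dataclass(frozen=True)
class IC50Result:
    """4PL fit summary; ``extrapolated`` flags an IC50 outside the tested range."""

    ic50: float
    hill_slope: float
    top: float
    bottom: float
    converged: bool
    extrapolated: bool = False
    ss_res: float = math.nan
    message: str = ""


def viability_percent(od_treated: float, od_control: float) -> float:
    """Cell viability (%) = 100 * OD(treated) / OD(control)."""
    if not od_control > 0:
        raise ValueError(f"control optical density must be positive, got {od_control}")
    return 100.0 * od_treated / od_control


def normalize_to_vehicle(
    viability: Sequence[float] | np.ndarray, vehicle_viability: float
) -> np.ndarray:
    """Re-express viabilities relative to a vehicle (e.g. DMSO) group."""
    if not vehicle_viability > 0:
        raise ValueError(
            f"vehicle viability must be positive, got {vehicle_viability}"
        )
    return 100.0 * np.asarray(viability, dtype=float) / vehicle_viability


def doubling_time(obs: GrowthObservation) -> float:
    """Population doubling time in hours.

    Negative values indicate a shrinking population (final < initial count).
    Equal counts leave the formula undefined and raise.
    """
    if obs.final_count == obs.initial_count:
        raise ValueError("equal initial and final counts: doubling time undefined")
    return (
        obs.duration
        * math.log(2.0)
        / (math.log(obs.final_count) - math.log(obs.initial_count))
    )


def four_param_logistic(
    c: np.ndarray | Sequence[float],
    top: float,
    bottom: float,
    ic50: float,
    hill: float,
) -> np.ndarray:
    """4PL viability curve on the µM concentration scale (hill > 0 decreasing)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.power(c / ic50, hill))


def fit_ic50(
    table: DoseResponseTable,
    constraints: Mapping[str, float] | None = None,
) -> IC50Result:
    """Estimate IC50 by deterministic multi-start 4PL least squares.

    Parameters are (top, bottom, log10 IC50, hill).  Default constraints keep
    top <= 110 %, bottom >= -5 % and hill in (0.1, 10); the log10-IC50 search
    window extends two decades beyond the tested concentrations.  Degenerate
    tables (all viabilities identical) return a non-converged result with a
    diagnostic message.
    """
    c = table.concentrations
    v = table.viability
    if len(np.unique(c)) < 4:
        raise ValueError("IC50 fitting needs at least 4 distinct concentrations")
    if np.allclose(v, v[0]):
        return IC50Result(
            ic50=math.nan,
            hill_slope=math.nan,
            top=math.nan,
            bottom=math.nan,
            converged=False,
            message="degenerate dose-response: all viabilities identical",
        )
    cons = {"top_max": 110.0, "bottom_min": -5.0, "hill_min": 0.1, "hill_max": 10.0}
    cons.update(constraints or {})
    log_c = np.log10(c)
    lo = np.array([max(v.min() - 20, cons["bottom_min"]), cons["bottom_min"],
                   log_c.min() - 2.0, cons["hill_min"]])
    hi = np.array([cons["top_max"], cons["top_max"], log_c.max() + 2.0, cons["hill_max"]])

    def residuals(x: np.ndarray) -> np.ndarray:
        top, bottom, log_ic50, hill = x
        return four_param_logistic(c, top, bottom, 10.0**log_ic50, hill) - v

    # fixed multi-start: asymptotes from the data, IC50 across the tested
    # decades, a few hill slopes
    top0 = float(np.clip(v.max(), lo[0] + 1e-6, cons["top_max"]))
    bot0 = float(np.clip(v.min(), cons["bottom_min"], cons["top_max"] - 1e-6))
    ic50_starts = np.linspace(log_c.min(), log_c.max(), 4)
    hill_starts = (0.7, 1.0, 2.0)
    best, best_ssr = None, math.inf
    for lg, h in itertools.product(ic50_starts, hill_starts):
        x0 = np.clip([top0, bot0, lg, h], lo, hi)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:  # noqa: BLE001
            continue
        ssr = 2.0 * res.cost
        if best is None or ssr < best_ssr:
            best, best_ssr = res, ssr
    if best is None:
        return IC50Result(
            ic50=math.nan, hill_slope=math.nan, top=math.nan, bottom=math.nan,
            converged=False, message="all optimisation starts failed",
        )
    top, bottom, log_ic50, hill = best.x
    ic50 = float(10.0**log_ic50)
    return IC50Result(
        ic50=ic50,
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        converged=bool(best.success),
        extrapolated=not (c.min() <= ic50 <= c.max()),
        ss_res=float(best_ssr),
    )
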