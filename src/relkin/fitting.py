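"""Nonlinear least-squares fitting of release models with R2/AIC/MSC.

The goodness stack follows the convention popularised by dissolution-modelling
add-ins: with unit weights,

    AIC = n*ln(SS_res) + 2*p
    MSC = ln(SS_tot/SS_res) - 2*p/n

so that, for a fixed dataset, ranking models by lowest AIC is identical to
ranking by highest MSC (MSC = ln(SS_tot) - AIC/n).

Fitting is deterministic: initial values come from model-specific heuristics
(log-log linearisation for power laws, exponential linearisation for
saturating models) plus a fixed logarithmic grid, and the best final SSR over
all starts is kept.  No randomness enters the optimiser.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import (
    MODEL_NAMES,
    KineticModelSpec,
    ParamVector,
    evaluate,
    get_model,
    registry,
)
from .profiles import GISegmentation, ReleaseProfile, default_gi_segmentation, segment_profile

__all__ = [
    "GoodnessStats",
    "FitOptions",
    "FitResult",
    "FitGrid",
    "TooFewPointsError",
    "goodness",
    "fit",
    "fit_all",
]


class TooFewPointsError(ValueError):
    """Fewer observations than the model needs (n must exceed p)."""


class GoodnessStats(NamedTuple):
    r_squared: float
    aic: float
    msc: float
    ss_res: float
    ss_tot: float
    perfect_fit: bool


def goodness(
    observed: Sequence[float] | np.ndarray,
    predicted: Sequence[float] | np.ndarray,
    n_params: int,
) -> GoodnessStats:
    """Compute the R2 / AIC / MSC goodness-of-fit stack.

    SS_res = sum((obs - pred)^2), SS_tot = sum((obs - mean(obs))^2),
    R2 = 1 - SS_res/SS_tot, AIC = n*ln(SS_res) + 2p,
    MSC = ln(SS_tot/SS_res) - 2p/n.

    A perfect fit -- SS_res = 0, or below double-precision resolution of the
    data (SS_res <= 1e-12 * SS_tot) -- yields AIC = -inf and MSC = +inf with
    the ``perfect_fit`` flag set, so that ties between perfect fits are
    decided by parameter count rather than by rounding noise.  Constant
    observations (SS_tot = 0) are degenerate and raise.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D vectors of equal length")
    n = len(obs)
    if n < 2:
        raise ValueError("goodness needs at least two observations")
    if n <= n_params:
        raise TooFewPointsError(f"n = {n} observations for p = {n_params} parameters")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("degenerate data: all observations identical (SS_tot = 0)")
    if ss_res <= 1e-12 * ss_tot:
        return GoodnessStats(1.0, -math.inf, math.inf, ss_res, ss_tot, True)
    r2 = 1.0 - ss_res / ss_tot
    aic = n * math.log(ss_res) + 2.0 * n_params
    msc = math.log(ss_tot / ss_res) - 2.0 * n_params / n
    return GoodnessStats(r2, aic, msc, ss_res, ss_tot, False)


@dataclass(frozen=True)
class FitOptions:
    """Options shared by :func:`fit` and :func:`fit_all`.

    ``fix_params`` pins parameters at given values on top of the spec's own
    ``fixed_params`` (use ``{"m": 0.45}`` for the constrained Peppas-Sahlin
    variant, or ``{"Ti": None}`` to free a spec-fixed Weibull lag).
    ``weight_by_sd`` switches to 1/SD^2 weighting of residuals where replicate
    SDs are available (unweighted by default).
    """

    fix_params: Mapping[str, float | None] = field(default_factory=dict)
    weight_by_sd: bool = False
    max_starts: int = 40
    xtol: float = 1e-14
    ftol: float = 1e-14


@dataclass(frozen=True)
class FitResult:
    """Parameter estimates plus goodness stack for one model on one segment."""

    model_name: str
    params: ParamVector
    n_obs: int
    n_params: int
    ss_res: float
    ss_tot: float
    r_squared: float
    aic: float
    msc: float
    converged: bool
    perfect_fit: bool = False
    segment_label: str | None = None
    message: str = ""

    def exponent(self) -> tuple[str, float] | None:
        """The mechanism-bearing exponent of this model, if it has one."""
        symbol = {"korsmeyer_peppas": "n", "peppas_sahlin": "m", "weibull": "beta"}.get(
            self.model_name
        )
        if symbol is None:
            return None
        return symbol, self.params[symbol]


def _resolve_fixed(
    spec: KineticModelSpec, options: FitOptions
) -> tuple[dict[str, float], list[str]]:
    fixed = dict(spec.fixed_params)
    for p, v in options.fix_params.items():
        if p not in spec.param_names:
            continue
        if v is None:
            fixed.pop(p, None)
        else:
            fixed[p] = float(v)
    free = [p for p in spec.param_names if p not in fixed]
    return fixed, free


def _effective_bounds(
    spec: KineticModelSpec, free: list[str], t_max: float
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for p in free:
        b_lo, b_hi = spec.default_bounds[p]
        # keep 1 - k*t non-negative over the fitted window
        if spec.name in ("hopfenberg", "hixson_crowell") and p in ("kHB", "kHC") and t_max > 0:
            b_hi = min(b_hi, (1.0 - 1e-12) / t_max)
        if spec.name == "weibull" and p == "Ti":
            b_hi = min(b_hi, t_max)
        lo.append(b_lo)
        hi.append(b_hi)
    return np.array(lo), np.array(hi)


def _predict(spec: KineticModelSpec, params: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    """Model curve for fitting; a free Weibull lag clamps F to 0 before Ti
    (the physical no-release-yet reading) instead of raising."""
    if spec.name == "weibull":
        shifted = np.clip(t - params.get("Ti", 0.0), 0.0, None)
        return 100.0 * (1.0 - np.exp(-np.power(shifted, params["beta"]) / params["alpha"]))
    return evaluate(spec, params, t)


def _loglog_slope_intercept(t: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """OLS of ln(y) on ln(t) over strictly positive pairs (slope, exp(icept))."""
    mask = (t > 0) & (y > 0)
    if mask.sum() < 2:
        return None
    lt, ly = np.log(t[mask]), np.log(y[mask])
    slope, icept = np.polyfit(lt, ly, 1)
    return float(slope), float(np.exp(icept))


def _heuristic_starts(
    spec: KineticModelSpec, free: list[str], t: np.ndarray, y: np.ndarray
) -> list[dict[str, float]]:
    """Data-driven starting points per model (may be empty)."""
    starts: list[dict[str, float]] = []
    t_pos = t[t > 0]
    t_max = float(t.max()) if len(t) else 1.0
    y_max = float(np.clip(y.max(initial=0.0), 1.0, 99.0))
    if spec.name == "zero_order" and len(t_pos):
        starts.append({"k0": max(float(np.median(y[t > 0] / t_pos)), 1e-5)})
    elif spec.name == "first_order":
        k = -math.log(1.0 - y_max / 100.0) / t_max
        starts.append({"k1": max(k, 1e-5)})
    elif spec.name == "higuchi" and len(t_pos):
        starts.append({"kH": max(float(np.median(y[t > 0] / np.sqrt(t_pos))), 1e-5)})
    elif spec.name == "korsmeyer_peppas":
        ll = _loglog_slope_intercept(t, y)
        if ll is not None:
            n0 = float(np.clip(ll[0], 0.02, 2.9))
            starts.append({"kKP": max(ll[1], 1e-5), "n": n0})
    elif spec.name == "peppas_sahlin":
        ll = _loglog_slope_intercept(t, y)
        if ll is not None:
            m0 = float(np.clip(ll[0], 0.02, 1.45))
            starts.append({"k1": max(ll[1], 1e-5), "k2": 1e-3, "m": m0})
            starts.append({"k1": max(ll[1], 1e-5), "k2": -1e-3, "m": m0})
    elif spec.name in ("hopfenberg", "hixson_crowell"):
        sym = "kHB" if spec.name == "hopfenberg" else "kHC"
        # F(t_max) = 100*(1-(1-k*t_max)^n) solved at n = 3
        base = (1.0 - y_max / 100.0) ** (1.0 / 3.0)
        k = (1.0 - base) / t_max
        s = {sym: float(np.clip(k, 1e-6, 0.9 / t_max))}
        if spec.name == "hopfenberg":
            for n0 in (1.0, 3.0):
                starts.append({**s, "n": n0})
        else:
            starts.append(s)
    elif spec.name == "weibull":
        # ln(-ln(1 - F/100)) = beta*ln t - ln alpha
        mask = (t > 0) & (y > 0.5) & (y < 99.5)
        if mask.sum() >= 2:
            lt = np.log(t[mask])
            lz = np.log(-np.log(1.0 - y[mask] / 100.0))
            beta0, icept = np.polyfit(lt, lz, 1)
            beta0 = float(np.clip(beta0, 0.02, 4.5))
            alpha0 = float(np.clip(np.exp(-icept), 1e-5, 1e5))
            starts.append({"alpha": alpha0, "beta": beta0})
    return [{p: s[p] for p in free if p in s} for s in starts if all(p in s for p in free)]


_GRID_POINTS = {
    "rate": (1e-3, 1e-2, 0.1, 1.0),
    "exponent": (0.3, 0.85, 1.5),
    "k2": (-1.0, 1e-3, 1.0),
    "alpha": (0.5, 5.0, 50.0),
    "beta": (0.4, 1.0, 2.0),
    "Ti": (0.0,),
    "hopf_n": (1.0, 3.0),
}


def _grid_starts(spec: KineticModelSpec, free: list[str]) -> list[dict[str, float]]:
    axes = []
    for p in free:
        if p in ("n", "m") and spec.name != "hopfenberg":
            axes.append(_GRID_POINTS["exponent"])
        elif p == "n":
            axes.append(_GRID_POINTS["hopf_n"])
        elif p == "k2":
            axes.append(_GRID_POINTS["k2"])
        elif p == "alpha":
            axes.append(_GRID_POINTS["alpha"])
        elif p == "beta":
            axes.append(_GRID_POINTS["beta"])
        elif p == "Ti":
            axes.append(_GRID_POINTS["Ti"])
        else:
            axes.append(_GRID_POINTS["rate"])
    return [dict(zip(free, combo)) for combo in itertools.product(*axes)]


def fit(
    model: KineticModelSpec | str,
    segment: ReleaseProfile,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one kinetic model to one (segment of a) release profile.

    Minimises the (optionally 1/SD^2-weighted) residual sum of squares between
    observed mean release and the model curve, using deterministic multi-start
    trust-region least squares within the model's bounds.  The reported
    R2/AIC/MSC stack is always computed on unweighted residuals.
    """
    spec = get_model(model) if isinstance(model, str) else model
    opts = options or FitOptions()
    fixed, free = _resolve_fixed(spec, opts)
    t = segment.times
    y = segment.release_mean
    if len(t) < len(free) + 1:
        raise TooFewPointsError(
            f"{spec.name}: {len(t)} observations cannot support {len(free)} parameters"
        )
    lo, hi = _effective_bounds(spec, free, float(t.max()) if len(t) else 0.0)

    w = None
    if opts.weight_by_sd and segment.release_sd is not None:
        sd = np.where(segment.release_sd > 0, segment.release_sd, np.nan)
        fallback = np.nanmedian(sd) if np.isfinite(sd).any() else 1.0
        w = 1.0 / np.where(np.isfinite(sd), sd, fallback)

    def residuals(x: np.ndarray) -> np.ndarray:
        params = dict(fixed)
        params.update(zip(free, x))
        pred = _predict(spec, params, t)
        r = pred - y
        return r * w if w is not None else r

    starts = _heuristic_starts(spec, free, t, y) + _grid_starts(spec, free)
    starts = starts[: opts.max_starts]
    best_x, best_ssr, best_ok = None, math.inf, False
    for s in starts:
        x0 = np.clip([s[p] for p in free], lo, hi)
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=opts.xtol,
                ftol=opts.ftol,
                gtol=1e-14,
                max_nfev=3000,
            )
        except Exception:  # noqa: BLE001 - a bad start must not kill the fit
            continue
        ssr = 2.0 * res.cost
        if ssr < best_ssr - 1e-15 or (best_x is None):
            best_x, best_ssr, best_ok = res.x, ssr, bool(res.success)

    if best_x is None:
        raise RuntimeError(f"{spec.name}: no optimisation start succeeded")

    params = dict(fixed)
    params.update(zip(free, best_x))
    pred = _predict(spec, params, t)
    stats = goodness(y, pred, n_params=len(free))
    return FitResult(
        model_name=spec.name,
        params=ParamVector(spec.name, params),
        n_obs=len(t),
        n_params=len(free),
        ss_res=stats.ss_res,
        ss_tot=stats.ss_tot,
        r_squared=stats.r_squared,
        aic=stats.aic,
        msc=stats.msc,
        converged=best_ok,
        perfect_fit=stats.perfect_fit,
        segment_label=segment.segment_label,
    )


@dataclass(frozen=True)
class FitGrid:
    """Model x segment grid of fit results, mirroring a kinetics report table."""

    formulation_id: str
    results: tuple[FitResult, ...]
    failures: tuple[tuple[str, str, str], ...] = ()  # (model, segment, reason)

    def segments(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.results:
            seen.setdefault(r.segment_label or "", None)
        return list(seen)

    def for_segment(self, label: str) -> list[FitResult]:
        return [r for r in self.results if r.segment_label == label]

    def to_frame(self):
        """Long-format pandas DataFrame (one row per model x segment cell)."""
        import pandas as pd

        rows = []
        for r in self.results:
            exp = r.exponent()
            rows.append(
                {
                    "formulation": self.formulation_id,
                    "segment": r.segment_label,
                    "model": r.model_name,
                    "r_squared": r.r_squared,
                    "aic": r.aic,
                    "msc": r.msc,
                    "exponent": exp[1] if exp else np.nan,
                    "converged": r.converged,
                    **{f"param_{k}": v for k, v in r.params.values.items()},
                }
            )
        for model, seg_label, reason in self.failures:
            rows.append(
                {
                    "formulation": self.formulation_id,
                    "segment": seg_label,
                    "model": model,
                    "r_squared": np.nan,
                    "aic": np.nan,
                    "msc": np.nan,
                    "exponent": np.nan,
                    "converged": False,
                    "error": reason,
                }
            )
        return pd.DataFrame(rows)


def fit_all(
    profile: ReleaseProfile,
    segmentation: GISegmentation | None = None,
    models: Iterable[KineticModelSpec | str] | None = None,
    options: FitOptions | None = None,
    rezero: bool = True,
) -> FitGrid:
    """Fit every model to every medium segment of a release profile.

    Per-cell failures (too few points, optimiser breakdown) are recorded as
    flagged cells; the grid itself never aborts.
    """
    specs = [get_model(m) if isinstance(m, str) else m for m in (models or registry())]
    segs = segment_profile(profile, segmentation, rezero=rezero)
    results: list[FitResult] = []
    failures: list[tuple[str, str, str]] = []
    for sub in segs:
        for spec in specs:
            try:
                results.append(fit(spec, sub, options))
            except (TooFewPointsError, RuntimeError, ValueError) as exc:
                failures.append((spec.name, sub.segment_label or "", str(exc)))
    return FitGrid(
        formulation_id=profile.formulation_id,
        results=tuple(results),
        failures=tuple(failures),
    )
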