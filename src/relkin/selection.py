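"""Best-model selection and release-mechanism classification.

Model ranking uses the AIC (lowest wins; equivalently highest MSC — the two
orders coincide on a shared dataset).  Models within ``co_best_delta_aic``
(default 2) of the minimum are reported as co-best, reflecting the common
situation where a release profile is compatible with more than one model.

Mechanism labels follow the slab-geometry diffusional-exponent rules for the
power-law models and the shape-parameter rules for the Weibull model:

* Korsmeyer-Peppas n / Peppas-Sahlin m:
  n <= 0.45 Fickian diffusion; 0.45 < n < 0.85 anomalous (non-Fickian)
  transport; n = 0.85 case II transport; n > 0.85 super case II transport.
* Weibull beta: beta <= 0.75 Fickian diffusion; 0.75 < beta < 1 combined
  Fickian diffusion + controlled release; beta = 1 first-order release;
  beta > 1 complex mechanism.

Equality at the measure-zero thresholds (0.85, 1) is taken within a small
tolerance ``eps`` (default 0.005) because fitted exponents are reported to
three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .fitting import FitGrid, FitResult
from .models import MODEL_NAMES

__all__ = [
    "MechanismLabel",
    "MechanismCall",
    "ModelRanking",
    "NoConvergedFitError",
    "rank",
    "classify_exponent",
    "classify_weibull_beta",
    "classify_fit",
    "mechanism_report",
    "DEFAULT_CO_BEST_DELTA_AIC",
    "EXPONENT_EPS",
]

DEFAULT_CO_BEST_DELTA_AIC = 2.0
EXPONENT_EPS = 0.005

#: Mechanism vocabulary, ordered from diffusion- to relaxation-dominated.
MechanismLabel = str
FICKIAN = "fickian"
NON_FICKIAN = "non_fickian"
CASE_II = "case_II"
SUPER_CASE_II = "super_case_II"
COMBINED = "combined_fickian_controlled"
FIRST_ORDER_LIKE = "first_order_like"
COMPLEX = "complex"

_EXPONENT_ORDER = (FICKIAN, NON_FICKIAN, CASE_II, SUPER_CASE_II)


class NoConvergedFitError(RuntimeError):
    """Ranking was requested but no fit in the set converged."""


@dataclass(frozen=True)
class MechanismCall:
    """Mechanism label derived from one fitted exponent."""

    model_name: str
    exponent_symbol: str
    exponent_value: float
    label: MechanismLabel


@dataclass(frozen=True)
class ModelRanking:
    """Models ordered by AIC for one segment, with co-best set."""

    segment_label: str | None
    order: tuple[tuple[str, float, float, float], ...]  # (model, R2, AIC, MSC)
    best: tuple[str, ...]
    co_best_delta_aic: float


def _registry_index(name: str) -> int:
    return MODEL_NAMES.index(name) if name in MODEL_NAMES else len(MODEL_NAMES)


def rank(
    fits: Iterable[FitResult],
    co_best_delta_aic: float = DEFAULT_CO_BEST_DELTA_AIC,
) -> ModelRanking:
    """Order converged fits by ascending AIC; report the co-best set.

    Ties (|dAIC| < 1e-9) break toward fewer parameters, then registry order.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise NoConvergedFitError("no converged fit to rank")
    ordered = sorted(
        converged,
        key=lambda f: (f.aic, f.n_params, _registry_index(f.model_name)),
    )
    min_aic = ordered[0].aic
    best = tuple(
        f.model_name for f in ordered if f.aic <= min_aic + co_best_delta_aic
    )
    return ModelRanking(
        segment_label=ordered[0].segment_label,
        order=tuple((f.model_name, f.r_squared, f.aic, f.msc) for f in ordered),
        best=best,
        co_best_delta_aic=co_best_delta_aic,
    )


def classify_exponent(
    model_name: str, exponent: float, eps: float = EXPONENT_EPS
) -> MechanismCall:
    """Map a power-law diffusional exponent (n or m) to its mechanism label."""
    if model_name not in ("korsmeyer_peppas", "peppas_sahlin"):
        raise ValueError(
            "diffusional-exponent classification applies to korsmeyer_peppas "
            f"(n) and peppas_sahlin (m), not {model_name!r}"
        )
    if not exponent > 0:
        raise ValueError(f"exponent must be positive, got {exponent}")
    if exponent <= 0.45:
        label = FICKIAN
    elif abs(exponent - 0.85) <= eps:
        label = CASE_II
    elif exponent < 0.85:
        label = NON_FICKIAN
    else:
        label = SUPER_CASE_II
    symbol = "n" if model_name == "korsmeyer_peppas" else "m"
    return MechanismCall(model_name, symbol, float(exponent), label)


def classify_weibull_beta(beta: float, eps: float = EXPONENT_EPS) -> MechanismCall:
    """Map a Weibull shape parameter beta to its mechanism label."""
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if abs(beta - 1.0) <= eps:
        label = FIRST_ORDER_LIKE
    elif beta <= 0.75:
        label = FICKIAN
    elif beta < 1.0:
        label = COMBINED
    else:
        label = COMPLEX
    return MechanismCall("weibull", "beta", float(beta), label)


def classify_fit(result: FitResult, eps: float = EXPONENT_EPS) -> MechanismCall | None:
    """Mechanism call for a fit result, where the model supports one.

    Power-law models classify by diffusional exponent, the Weibull model by
    its shape parameter, and a plain first-order fit is labelled as such;
    the remaining models carry no mechanism-bearing exponent (returns None).
    """
    if result.model_name in ("korsmeyer_peppas", "peppas_sahlin"):
        sym, val = result.exponent()  # type: ignore[misc]
        return classify_exponent(result.model_name, val, eps)
    if result.model_name == "weibull":
        _, beta = result.exponent()  # type: ignore[misc]
        return classify_weibull_beta(beta, eps)
    if result.model_name == "first_order":
        return MechanismCall("first_order", "k1", result.params["k1"], FIRST_ORDER_LIKE)
    return None


def mechanism_report(
    grid: FitGrid,
    co_best_delta_aic: float = DEFAULT_CO_BEST_DELTA_AIC,
    eps: float = EXPONENT_EPS,
):
    """Per-segment narrative table: best model(s), exponent(s), mechanism(s).

    Returns a pandas DataFrame with one row per segment; segments where no
    fit converged are flagged ``no call``.
    """
    import pandas as pd

    rows = []
    for seg_label in grid.segments():
        fits = {f.model_name: f for f in grid.for_segment(seg_label)}
        try:
            ranking = rank(fits.values(), co_best_delta_aic)
        except NoConvergedFitError:
            rows.append(
                {
                    "formulation": grid.formulation_id,
                    "segment": seg_label,
                    "best_models": "no call",
                    "exponents": "",
                    "mechanisms": "no call",
                }
            )
            continue
        calls = [classify_fit(fits[m], eps) for m in ranking.best]
        rows.append(
            {
                "formulation": grid.formulation_id,
                "segment": seg_label,
                "best_models": ";".join(ranking.best),
                "exponents": ";".join(
                    f"{c.exponent_symbol}={c.exponent_value:.3f}"
                    for c in calls
                    if c is not None and c.exponent_symbol != "k1"
                ),
                "mechanisms": ";".join(c.label if c else "-" for c in calls),
            }
        )
    return pd.DataFrame(rows)
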