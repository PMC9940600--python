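"""Registry of drug-release kinetic models and their evaluation.

Each model predicts cumulative release F(t) as a percentage of loaded drug
(0-100 scale) versus time in hours.  The registry covers the eight classical
empirical dissolution models: zero order, first order, Higuchi,
Korsmeyer-Peppas, Peppas-Sahlin, Hopfenberg, Hixson-Crowell and Weibull.

Conventions
-----------
* Time ``t`` is in hours; rate constants carry units of h^-exponent.
* Saturating models (first order, Hopfenberg, Hixson-Crowell, Weibull)
  asymptote at 100 %; power-law models (Higuchi, Korsmeyer-Peppas) pass
  through the origin and are unbounded.
* The Weibull lag time ``Ti`` is fixed at 0 by default; pass
  ``fixed_params={}`` overrides through the fitting layer to free it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MODEL_NAMES",
    "DomainError",
    "KineticModelSpec",
    "ParamVector",
    "registry",
    "get_model",
    "evaluate",
    "reduce_weibull_to_first_order",
    "registry_json",
]

MODEL_NAMES = (
    "zero_order",
    "first_order",
    "higuchi",
    "korsmeyer_peppas",
    "peppas_sahlin",
    "hopfenberg",
    "hixson_crowell",
    "weibull",
)

# Default parameter bounds.  Rate-like constants span (1e-6, 1e3); power-law
# exponents are kept in (0.01, 3); the Hopfenberg geometry exponent is
# continuous in [0.5, 5]; the Peppas-Sahlin relaxation coefficient k2 may be
# negative; the Weibull scale alpha may reach 1e6 so that alpha = 1/k1 stays
# representable for the slowest first-order rates.
_RATE_BOUNDS = (1e-6, 1e3)


class DomainError(ValueError):
    """A parameter/time combination leaves the model's mathematical domain."""

    def __init__(self, model_name: str, param: str, message: str):
        self.model_name = model_name
        self.param = param
        super().__init__(f"{model_name}: {message} (parameter {param!r})")


@dataclass(frozen=True)
class KineticModelSpec:
    """A named release equation with its parameters and default bounds."""

    name: str
    param_names: tuple[str, ...]
    default_bounds: Mapping[str, tuple[float, float]]
    equation: str
    fixed_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.param_names)) != len(self.param_names):
            raise ValueError(f"{self.name}: duplicate parameter names")
        for p, (lo, hi) in self.default_bounds.items():
            if p not in self.param_names:
                raise ValueError(f"{self.name}: bound for unknown parameter {p!r}")
            if not lo < hi:
                raise ValueError(f"{self.name}: bound for {p!r} has lower >= upper")
        for p in self.fixed_params:
            if p not in self.param_names:
                raise ValueError(f"{self.name}: fixed value for unknown parameter {p!r}")

    @property
    def free_param_names(self) -> tuple[str, ...]:
        return tuple(p for p in self.param_names if p not in self.fixed_params)


@dataclass(frozen=True)
class ParamVector:
    """Concrete parameter values for one model (symbol -> float)."""

    model_name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        spec = get_model(self.model_name)
        missing = set(spec.param_names) - set(self.values)
        if missing:
            raise ValueError(f"{self.model_name}: missing parameters {sorted(missing)}")

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])


def _zero_order(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return p["k0"] * t


def _first_order(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return 100.0 * (1.0 - np.exp(-p["k1"] * t))


def _higuchi(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return p["kH"] * np.sqrt(t)


def _korsmeyer_peppas(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    return p["kKP"] * np.power(t, p["n"])


def _peppas_sahlin(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    m = p["m"]
    tm = np.power(t, m)
    return p["k1"] * tm + p["k2"] * tm * tm


def _hopfenberg(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    base = 1.0 - p["kHB"] * t
    if np.any(base < 0):
        raise DomainError("hopfenberg", "kHB", "1 - kHB*t < 0 in the evaluated range")
    return 100.0 * (1.0 - np.power(base, p["n"]))


def _hixson_crowell(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    base = 1.0 - p["kHC"] * t
    if np.any(base < 0):
        raise DomainError("hixson_crowell", "kHC", "1 - kHC*t < 0 in the evaluated range")
    return 100.0 * (1.0 - base**3)


def _weibull(t: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    ti = p.get("Ti", 0.0)
    if np.any(t < ti):
        raise DomainError("weibull", "Ti", "evaluation time precedes the lag time Ti")
    shifted = t - ti
    return 100.0 * (1.0 - np.exp(-np.power(shifted, p["beta"]) / p["alpha"]))


_EVALUATORS = {
    "zero_order": _zero_order,
    "first_order": _first_order,
    "higuchi": _higuchi,
    "korsmeyer_peppas": _korsmeyer_peppas,
    "peppas_sahlin": _peppas_sahlin,
    "hopfenberg": _hopfenberg,
    "hixson_crowell": _hixson_crowell,
    "weibull": _weibull,
}

_REGISTRY: dict[str, KineticModelSpec] = {
    "zero_order": KineticModelSpec(
        name="zero_order",
        param_names=("k0",),
        default_bounds={"k0": _RATE_BOUNDS},
        equation="F = k0*t",
    ),
    "first_order": KineticModelSpec(
        name="first_order",
        param_names=("k1",),
        default_bounds={"k1": _RATE_BOUNDS},
        equation="F = 100*(1 - exp(-k1*t))",
    ),
    "higuchi": KineticModelSpec(
        name="higuchi",
        param_names=("kH",),
        default_bounds={"kH": _RATE_BOUNDS},
        equation="F = kH*t^0.5",
    ),
    "korsmeyer_peppas": KineticModelSpec(
        name="korsmeyer_peppas",
        param_names=("kKP", "n"),
        default_bounds={"kKP": _RATE_BOUNDS, "n": (0.01, 3.0)},
        equation="F = kKP*t^n",
    ),
    "peppas_sahlin": KineticModelSpec(
        name="peppas_sahlin",
        param_names=("k1", "k2", "m"),
        default_bounds={
            "k1": _RATE_BOUNDS,
            "k2": (-1e3, 1e3),
            "m": (0.01, 3.0),
        },
        equation="F = k1*t^m + k2*t^(2*m)",
    ),
    "hopfenberg": KineticModelSpec(
        name="hopfenberg",
        param_names=("kHB", "n"),
        default_bounds={"kHB": _RATE_BOUNDS, "n": (0.5, 5.0)},
        equation="F = 100*(1 - (1 - kHB*t)^n)",
    ),
    "hixson_crowell": KineticModelSpec(
        name="hixson_crowell",
        param_names=("kHC",),
        default_bounds={"kHC": _RATE_BOUNDS},
        equation="F = 100*(1 - (1 - kHC*t)^3)",
    ),
    "weibull": KineticModelSpec(
        name="weibull",
        param_names=("alpha", "beta", "Ti"),
        default_bounds={"alpha": (1e-6, 1e6), "beta": (0.01, 5.0), "Ti": (0.0, 48.0)},
        equation="F = 100*(1 - exp(-((t - Ti)^beta)/alpha))",
        fixed_params={"Ti": 0.0},
    ),
}


def registry() -> list[KineticModelSpec]:
    """Return the eight release-model specifications, in canonical order."""
    return [_REGISTRY[name] for name in MODEL_NAMES]


def get_model(name: str) -> KineticModelSpec:
    """Look up a model spec by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}"
        ) from None


def evaluate(
    model: KineticModelSpec | str,
    params: ParamVector | Mapping[str, float],
    times: Iterable[float] | np.ndarray,
) -> np.ndarray:
    """Evaluate predicted cumulative release F(t) elementwise.

    Parameters
    ----------
    model : spec or model name.
    params : mapping symbol -> value (a :class:`ParamVector` or plain dict).
        Parameters fixed in the spec (e.g. Weibull ``Ti``) fall back to their
        fixed value when absent.
    times : times in hours, all >= 0.

    Returns
    -------
    ndarray of percent released, same length as ``times``.
    """
    spec = get_model(model) if isinstance(model, str) else model
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    values = params.values if isinstance(params, ParamVector) else params
    merged = dict(spec.fixed_params)
    merged.update(values)
    missing = set(spec.param_names) - set(merged)
    if missing:
        raise ValueError(f"{spec.name}: missing parameters {sorted(missing)}")
    return np.asarray(_EVALUATORS[spec.name](t, merged), dtype=float)


def reduce_weibull_to_first_order(k1: float) -> ParamVector:
    """Weibull parameters equivalent to first-order release with rate ``k1``.

    With shape beta = 1 and lag Ti = 0 the Weibull curve
    100*(1 - exp(-t/alpha)) coincides with first order when alpha = 1/k1.
    """
    if not k1 > 0:
        raise ValueError(f"first-order rate must be positive, got {k1}")
    return ParamVector("weibull", {"alpha": 1.0 / k1, "beta": 1.0, "Ti": 0.0})


def registry_json() -> str:
    """Serialize the registry (name, equation, parameters, bounds) to JSON."""
    payload = [
        {
            "name": spec.name,
            "equation": spec.equation,
            "parameters": list(spec.param_names),
            "bounds": {p: list(b) for p, b in spec.default_bounds.items()},
            "fixed_params": dict(spec.fixed_params),
        }
        for spec in registry()
    ]
    return json.dumps(payload, indent=2)
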