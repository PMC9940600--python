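"""Synthetic data generators for release profiles, dose-response tables and
growth counts.

These emulate the structure of a gastrointestinal-transit release study:
cumulative %-release sampled at 0.5-48 h across three sequential media, with
three replicates and additive Gaussian noise (reported as mean +/- SD), plus
4PL-shaped viability tables and exponential growth counts.  The generating
curve is continuous across medium boundaries — each segment's model starts
from the cumulative release reached at the switch — matching the physics of
a cumulative measurement, independent of how the fitting side re-zeroes
segments.

All stochastic generators require an explicit seed and are bit-reproducible.
What these simulations do not emulate: sink-condition drift, sampling-volume
correction errors, inter-batch formulation variability, or non-Gaussian
replicate scatter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assays import DoseResponseTable, GrowthObservation, four_param_logistic
from .models import evaluate, get_model
from .profiles import (
    GISegmentation,
    PAPER_SCHEDULE_H,
    ReleaseProfile,
    default_gi_segmentation,
)

__all__ = [
    "SegmentModel",
    "ReleaseSimConfig",
    "release_curve",
    "simulate_release",
    "simulate_dose_response",
    "simulate_growth",
]


@dataclass(frozen=True)
class SegmentModel:
    """Generating model for one medium window."""

    model: str
    params: Mapping[str, float]


@dataclass(frozen=True)
class ReleaseSimConfig:
    """Configuration for one simulated release profile.

    Defaults mirror the study design: the 9-point 0.5-48 h schedule, the
    SGF/SIF/SCoF segmentation, 3 replicates and 2 % replicate SD.
    """

    segment_models: tuple[SegmentModel, ...]
    seed: int
    segmentation: GISegmentation = field(default_factory=default_gi_segmentation)
    times: tuple[float, ...] = PAPER_SCHEDULE_H
    noise_sd: float = 2.0
    n_replicates: int = 3
    monotone_enforce: bool = True
    formulation_id: str = "simulated"

    def __post_init__(self) -> None:
        if len(self.segment_models) != len(self.segmentation.segments):
            raise ValueError(
                f"{len(self.segment_models)} segment models for "
                f"{len(self.segmentation.segments)} segments"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        lo, hi = self.segmentation.span
        t = np.asarray(self.times, dtype=float)
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError("sampling times fall outside the segmentation span")


def release_curve(config: ReleaseSimConfig, times: np.ndarray | None = None) -> np.ndarray:
    """Noise-free stitched release curve F(t) for a simulation config.

    Each segment's model is evaluated in segment-local time and offset by the
    cumulative release reached at the segment switch, so the curve is
    continuous across medium boundaries.
    """
    t = np.asarray(config.times if times is None else times, dtype=float)
    segs = config.segmentation.segments
    # cumulative offset at each segment start
    offsets = [0.0]
    for seg, sm in zip(segs[:-1], config.segment_models[:-1]):
        local_end = np.array([seg.end - seg.start])
        f_end = evaluate(sm.model, dict(sm.params), local_end)[0]
        offsets.append(offsets[-1] + f_end)
    out = np.empty_like(t)
    for i, ti in enumerate(t):
        # t on a boundary belongs to the earlier segment
        idx = 0
        for j, seg in enumerate(segs):
            if (ti > seg.start or (j == 0 and ti >= seg.start)) and ti <= seg.end:
                idx = j
                break
        seg, sm = segs[idx], config.segment_models[idx]
        local = np.array([ti - seg.start])
        out[i] = offsets[idx] + evaluate(sm.model, dict(sm.params), local)[0]
    if np.any(out > 100.0):
        if config.monotone_enforce:
            warnings.warn(
                "generating curve exceeds 100 % cumulative release; clipping",
                stacklevel=2,
            )
            out = np.clip(out, None, 100.0)
    return out


def simulate_release(config: ReleaseSimConfig) -> ReleaseProfile:
    """Simulate a replicate-averaged release profile (mean +/- SD).

    Independent Gaussian noise (SD ``noise_sd``) is added per replicate and
    time point, truncated at 0 (cumulative release cannot be negative); the
    same seed gives bit-identical output.
    """
    curve = release_curve(config)
    rng = np.random.default_rng(config.seed)
    reps = curve[None, :] + rng.normal(
        0.0, config.noise_sd, size=(config.n_replicates, len(curve))
    )
    reps = np.clip(reps, 0.0, None)
    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if config.n_replicates > 1 else np.zeros_like(mean)
    return ReleaseProfile(
        formulation_id=config.formulation_id,
        times=np.asarray(config.times, dtype=float),
        release_mean=np.clip(mean, -10.0, 110.0),
        release_sd=sd,
        n_replicates=config.n_replicates,
    )


def simulate_dose_response(
    ic50: float,
    hill: float,
    top: float,
    bottom: float,
    concentrations: Sequence[float] = (0.4, 0.8, 1.6, 3.2, 6.4, 12.8),
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 6,
) -> DoseResponseTable:
    """Simulate a viability-vs-concentration table from a 4PL curve.

    Gaussian noise of SD ``noise_sd`` (viability %) is added per replicate;
    the table holds the replicate mean at each concentration.
    """
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    mean_curve = four_param_logistic(c, top, bottom, ic50, hill)
    if noise_sd == 0.0:
        v = mean_curve
    else:
        rng = np.random.default_rng(seed)
        reps = mean_curve[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, len(c)))
        v = reps.mean(axis=0)
    return DoseResponseTable(concentrations=c, viability=v, n_replicates=n_replicates)


def simulate_growth(
    initial: float,
    doubling_time_h: float,
    duration: float,
    seed: int = 0,
    cv: float = 0.0,
) -> GrowthObservation:
    """Simulate exponential growth: final = initial * 2^(duration/t_d).

    Multiplicative lognormal noise with coefficient of variation ``cv``
    (median-unbiased, so the median recovered doubling time is the truth);
    cv = 0 gives the exact deterministic count.
    """
    if initial <= 0 or doubling_time_h <= 0 or duration <= 0 or cv < 0:
        raise ValueError("initial, doubling_time_h and duration must be positive, cv >= 0")
    final = initial * 2.0 ** (duration / doubling_time_h)
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + cv**2))
        final *= math.exp(rng.normal(0.0, sigma))
    return GrowthObservation(initial_count=initial, final_count=final, duration=duration)
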