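"""Release-profile containers and gastrointestinal-transit segmentation.

A :class:`ReleaseProfile` holds a cumulative %-released time series (replicate
mean with optional SD).  A :class:`GISegmentation` splits the 0-48 h release
window into the sequential media of a gastrointestinal transit experiment:
simulated gastric fluid (SGF, pH 1.2, 0-2 h), simulated intestinal fluid
(SIF, pH 4.5, 2-5 h) and simulated colonic fluid (SCoF, pH 7.4, 5-48 h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ReleaseProfile",
    "Segment",
    "GISegmentation",
    "default_gi_segmentation",
    "segment_profile",
    "PAPER_SCHEDULE_H",
]

#: Sampling schedule used throughout: 0.5-24 h draws plus the 48 h endpoint.
PAPER_SCHEDULE_H = (0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 24.0, 48.0)


@dataclass(frozen=True)
class ReleaseProfile:
    """Time-stamped cumulative release series for one formulation.

    ``release_mean`` is in percent of loaded drug; small negative values and
    values slightly above 100 are tolerated (replicate noise).
    """

    formulation_id: str
    times: np.ndarray
    release_mean: np.ndarray
    release_sd: np.ndarray | None = None
    n_replicates: int = 3
    segment_label: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.release_mean, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "release_mean", y)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("times and release_mean must be 1-D and equal length")
        if len(t) and np.any(t < 0):
            raise ValueError("times must be non-negative")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(y) and (np.any(y < -10.0) or np.any(y > 110.0)):
            raise ValueError("release_mean outside the plausible [-10, 110] %% range")
        if self.release_sd is not None:
            sd = np.asarray(self.release_sd, dtype=float)
            object.__setattr__(self, "release_sd", sd)
            if len(sd) != len(t):
                raise ValueError("release_sd length must match times")
            if np.any(sd < 0):
                raise ValueError("release_sd must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Segment:
    """One medium window of a transit experiment."""

    label: str
    medium: str
    start: float
    end: float
    pH: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment {self.label}: start must precede end")


@dataclass(frozen=True)
class GISegmentation:
    """Ordered, contiguous, non-overlapping media windows starting at t = 0."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("segmentation needs at least one segment")
        if segs[0].start != 0:
            raise ValueError("first segment must start at t = 0")
        for prev, cur in zip(segs, segs[1:]):
            if cur.start != prev.end:
                raise ValueError(
                    f"segments {prev.label!r} and {cur.label!r} are not contiguous"
                )

    @property
    def span(self) -> tuple[float, float]:
        return (self.segments[0].start, self.segments[-1].end)


def default_gi_segmentation() -> GISegmentation:
    """SGF 0-2 h (pH 1.2), SIF 2-5 h (pH 4.5), SCoF 5-48 h (pH 7.4)."""
    return GISegmentation(
        (
            Segment("SGF", "SGF", 0.0, 2.0, 1.2),
            Segment("SIF", "SIF", 2.0, 5.0, 4.5),
            Segment("SCoF", "SCoF", 5.0, 48.0, 7.4),
        )
    )


def _anchor_release(profile: ReleaseProfile, t0: float) -> float:
    """Release at the segment boundary: exact sample if present, else linear
    interpolation (t0 = 0 anchors at zero release)."""
    if t0 == 0:
        exact = np.flatnonzero(profile.times == 0)
        return float(profile.release_mean[exact[0]]) if len(exact) else 0.0
    exact = np.flatnonzero(profile.times == t0)
    if len(exact):
        return float(profile.release_mean[exact[0]])
    return float(np.interp(t0, profile.times, profile.release_mean))


def segment_profile(
    profile: ReleaseProfile,
    segmentation: GISegmentation | None = None,
    rezero: bool = True,
) -> list[ReleaseProfile]:
    """Split a release profile into per-medium sub-profiles.

    A sample exactly at a boundary belongs to the earlier segment and is
    replicated as the anchor (time origin) of the next.  With ``rezero``
    (default) each sub-profile is re-expressed relative to its anchor so the
    segment starts at (0, 0); otherwise absolute times and releases are kept,
    with the anchor point prepended.

    Segments containing no samples are omitted with a warning.
    """
    seg = segmentation or default_gi_segmentation()
    lo, hi = seg.span
    if np.any(profile.times > hi) or np.any(profile.times < lo):
        raise ValueError(
            f"profile {profile.formulation_id!r} has samples outside the "
            f"segmentation span [{lo}, {hi}] h"
        )
    out: list[ReleaseProfile] = []
    for s in seg.segments:
        mask = (profile.times > s.start) & (profile.times <= s.end)
        if not mask.any():
            warnings.warn(
                f"segment {s.label!r} of {profile.formulation_id!r} contains "
                "no samples and is omitted",
                stacklevel=2,
            )
            continue
        t_loc = profile.times[mask]
        y_loc = profile.release_mean[mask]
        sd_loc = profile.release_sd[mask] if profile.release_sd is not None else None
        # the boundary sample itself (t == start) sits in the earlier segment;
        # it re-enters here only as the anchor point
        anchor_t = s.start
        anchor_y = _anchor_release(profile, anchor_t)
        if rezero:
            t_new = np.concatenate(([0.0], t_loc - anchor_t))
            y_new = np.concatenate(([0.0], y_loc - anchor_y))
        else:
            t_new = np.concatenate(([anchor_t], t_loc))
            y_new = np.concatenate(([anchor_y], y_loc))
        if sd_loc is not None:
            pad = len(t_new) - len(sd_loc)
            sd_new = np.concatenate((np.zeros(pad), sd_loc))
        else:
            sd_new = None
        out.append(
            ReleaseProfile(
                formulation_id=profile.formulation_id,
                times=t_new,
                release_mean=np.clip(y_new, -10.0, 110.0),
                release_sd=sd_new,
                n_replicates=profile.n_replicates,
                segment_label=s.label,
            )
        )
    return out
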