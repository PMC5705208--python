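"""Blockage detection from lumen intensity profiles and the observed
blockage-to-soma distance distribution.

A perfusion blockage appears as an abrupt termination of the intravascular
tracer (FITC-albumin) signal along a capillary centreline: an upstream
plateau of full intensity dropping to background over a few micrometres.
``detect_block`` localizes the drop on a background-subtracted,
plateau-normalized profile; ``aggregate_profiles`` aligns and averages
profiles at their block positions; ``observed_distances`` turns annotated
images into the empirical distance-to-nearest-soma distribution, and
``compare_to_null`` tests it against a random-placement null CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CapillaryGraph, NoSomaError, nearest_soma_distance
from .null_model import DistanceCDF, equiprobability_sample
from .stats import ks_compare

__all__ = [
    "LumenProfile",
    "BlockCall",
    "DetectionParams",
    "ProfileAverage",
    "ObservedDistances",
    "detect_block",
    "aggregate_profiles",
    "observed_distances",
    "compare_to_null",
]

log = logging.getLogger(__name__)


@dataclass
class LumenProfile:
    """Tracer intensity sampled at uniform steps along a capillary
    centreline.  ``background`` is the off-vessel intensity offset that is
    subtracted before normalization."""

    arc_positions: np.ndarray
    intensities: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.arc_positions.size != self.intensities.size:
            raise ValueError("positions and intensities differ in length")
        if self.arc_positions.size < 10:
            raise ValueError("profile needs at least 10 samples")
        steps = np.diff(self.arc_positions)
        if (steps <= 0).any():
            raise ValueError("arc positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("arc positions must have a constant step")

    @property
    def step(self) -> float:
        return float(self.arc_positions[1] - self.arc_positions[0])


@dataclass
class BlockCall:
    """A localized perfusion block: the arc position of the half-maximum
    crossing plus the plateau levels on either side and the width of the
    transition (all in profile units / μm)."""

    position: float
    upstream_level: float
    downstream_level: float
    width: float

    def __post_init__(self) -> None:
        if not self.upstream_level > self.downstream_level:
            raise ValueError("upstream level must exceed downstream level")
        if not self.width > 0:
            raise ValueError("transition width must be positive")


@dataclass
class DetectionParams:
    """Operational criterion for an "abrupt termination".

    The profile (background-subtracted, clamped at 0 and normalized to the
    upstream plateau, taken as the median of the first ``plateau_frac`` of
    samples) must fall from at least ``hi`` to at most ``lo`` within
    ``max_width_um``; the block is placed at the first (most upstream)
    ``cross`` crossing by linear interpolation.  A short moving-average
    smoothing (``smooth_um``) suppresses single-sample noise crossings.
    """

    hi: float = 0.8
    lo: float = 0.2
    cross: float = 0.5
    max_width_um: float = 5.0
    plateau_frac: float = 0.25
    smooth_um: float = 0.6


def _normalize(profile: LumenProfile, params: DetectionParams) -> np.ndarray | None:
    y = np.clip(profile.intensities - profile.background, 0.0, None)
    n_plateau = max(1, int(round(params.plateau_frac * y.size)))
    plateau = float(np.median(y[:n_plateau]))
    if plateau <= 0:
        return None
    return y / plateau


def _smooth(z: np.ndarray, step: float, smooth_um: float) -> np.ndarray:
    w = int(round(smooth_um / step))
    if w < 2:
        return z
    kernel = np.ones(w) / w
    pad = np.pad(z, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_block(profile: LumenProfile,
                 params: DetectionParams | None = None) -> BlockCall | None:
    """Call a perfusion block on a lumen profile, or ``None``.

    Returns the most upstream qualifying drop; further candidate drops are
    logged as a warning.
    """
    params = params or DetectionParams()
    z = _normalize(profile, params)
    if z is None:
        return None
    zs = _smooth(z, profile.step, params.smooth_um)
    x = profile.arc_positions

    crossings = np.flatnonzero((zs[:-1] >= params.cross) & (zs[1:] < params.cross))
    calls = []
    for i in crossings:
        above = np.flatnonzero(zs[: i + 1] >= params.hi)
        below = np.flatnonzero(zs[i + 1:] <= params.lo)
        if above.size == 0 or below.size == 0:
            continue
        i_hi = above[-1]
        i_lo = i + 1 + below[0]
        width = x[i_lo] - x[i_hi]
        if width > params.max_width_um:
            continue
        frac = (zs[i] - params.cross) / (zs[i] - zs[i + 1])
        pos = x[i] + frac * (x[i + 1] - x[i])
        upstream = float(np.median(z[: i_hi + 1])) if i_hi >= 0 else float(z[0])
        downstream = float(np.median(z[i_lo:]))
        calls.append(BlockCall(pos, max(upstream, params.hi),
                               min(downstream, params.lo), float(width)))
    if not calls:
        return None
    if len(calls) > 1:
        log.warning("profile has %d candidate drops; returning the most upstream",
                    len(calls))
    return calls[0]


@dataclass
class ProfileAverage:
    """Block-aligned average profile: normalized intensity vs arc offset
    from the block position (offset 0 = half-maximum crossing)."""

    offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


def aggregate_profiles(profiles: Sequence[LumenProfile],
                       calls: Sequence[BlockCall],
                       params: DetectionParams | None = None,
                       grid_step: float | None = None) -> ProfileAverage:
    """Align normalized profiles at their block positions and average.

    Profiles are background-subtracted, normalized to their upstream
    plateau, shifted so that the block sits at offset 0, resampled onto
    the common overlapping grid, and averaged with a per-point standard
    error.  With a single profile the s.e.m. is NaN.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to aggregate")
    if len(profiles) != len(calls):
        raise ValueError("profiles and calls must pair up")
    params = params or DetectionParams()
    step = grid_step or min(p.step for p in profiles)
    lo = max(p.arc_positions[0] - c.position for p, c in zip(profiles, calls))
    hi = min(p.arc_positions[-1] - c.position for p, c in zip(profiles, calls))
    if hi <= lo:
        raise ValueError("profiles share no common offset range")
    grid = np.arange(lo, hi + step / 2, step)
    stack = np.empty((len(profiles), grid.size))
    for k, (p, c) in enumerate(zip(profiles, calls)):
        z = _normalize(p, params)
        if z is None:
            raise ValueError(f"profile {k} is all background")
        stack[k] = np.interp(grid, p.arc_positions - c.position, z)
    mean = stack.mean(axis=0)
    if len(profiles) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(profiles))
    else:
        sem = np.full(grid.size, np.nan)
    return ProfileAverage(grid, mean, sem, len(profiles))


@dataclass
class ObservedDistances:
    """Observed blockage-to-nearest-soma distances with their empirical CDF
    (step of 1/n) and mid-rank median."""

    distances: np.ndarray
    median: float
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return int(self.distances.size)

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.sort(self.distances)
        return x, np.arange(1, x.size + 1) / x.size


def observed_distances(graphs: Sequence[CapillaryGraph],
                       restrict_to_capillary: bool = True) -> ObservedDistances:
    """One nearest-soma distance per annotated blockage, pooled over images.

    Blockages with no reachable visible soma are excluded (and counted in
    ``n_excluded``); the median uses the mid-rank convention.
    """
    dists: list[float] = []
    excluded = 0
    for g in graphs:
        for b in g.blockages:
            try:
                d, _ = nearest_soma_distance(g, b, restrict_to_capillary)
            except NoSomaError:
                excluded += 1
                continue
            dists.append(d)
    if excluded:
        log.warning("excluded %d blockage(s) with no reachable visible soma",
                    excluded)
    arr = np.sort(np.asarray(dists, dtype=float))
    if arr.size == 0:
        raise ValueError("no measurable blockages")
    return ObservedDistances(arr, float(np.median(arr)), excluded)


def compare_to_null(observed, null: DistanceCDF,
                    n_sample: int | None = None) -> dict:
    """Compare observed distances with a random-placement null CDF.

    The primary comparison is a one-sample KS test of the observed sample
    against the continuous null; a two-sample KS of the observed sample
    against ``n_sample`` equi-probability points drawn from the null is
    co-reported for parity with figure-style comparisons of two n-point
    distributions.
    """
    if isinstance(observed, ObservedDistances):
        obs = observed.distances
    else:
        obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise ValueError("no observed distances")
    one = ks_compare(obs, null)
    out = {
        "KS_D": one.statistic,
        "p_one_sample": one.p_raw,
        "p_two_sample": np.nan,
        "D_two_sample": np.nan,
        "observed_median": float(np.median(obs)),
        "predicted_median": null.median,
        "n_observed": int(obs.size),
    }
    n = n_sample if n_sample is not None else obs.size
    if n < 2:
        log.warning("two-sample KS skipped: n_sample < 2")
    else:
        two = ks_compare(obs, equiprobability_sample(null, n))
        out["p_two_sample"] = two.p_raw
        out["D_two_sample"] = two.statistic
    return out
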