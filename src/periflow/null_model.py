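"""Random-placement null distributions of blockage-to-nearest-soma distance.

If capillary blockages occurred at positions independent of pericyte
locations, a blockage would be uniformly distributed over the imaged arc
length of its capillary.  The induced distribution of the distance to the
nearest visible pericyte soma is then fully determined by the capillary
geometry and can be computed exactly: the nearest-soma distance is a
piecewise-affine function of arc position with slope ±1, so each affine
stretch of length ``l`` on a capillary of total imaged length ``L``
contributes probability mass ``l / L`` spread uniformly over the distance
range it sweeps.  Summing those contributions yields an exact
piecewise-linear cumulative distribution (CDF).

For the textbook geometry -- a single unbranched capillary of length ``L``
with one soma a distance ``A`` from one end -- this reduces to the density
``p(x) = 2/L`` for ``x < A``, ``1/L`` for ``A < x < L - A`` and ``0``
beyond, and the idealized limit of evenly spaced somata every ``2h`` gives
a CDF rising linearly to 1 at the half-spacing ``h``.

Per-image CDFs are pooled by (weighted) pointwise averaging and can be
reduced to ``n`` representative equi-probability sample points for
comparison with an observed ``n``-point distribution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import CapillaryGraph, _soma_via_map

__all__ = [
    "DistanceCDF",
    "NullModelResult",
    "DegenerateGeometryError",
    "image_null_cdf",
    "pool_cdfs",
    "equiprobability_sample",
    "linear_null",
    "build_null_model",
]


class DegenerateGeometryError(ValueError):
    """Capillary has no imaged length or no visible soma to measure from."""


@dataclass
class DistanceCDF:
    """Piecewise-linear CDF of a non-negative distance (μm).

    ``cum_probs`` are the CDF values at ``breakpoints``; between
    breakpoints the CDF interpolates linearly, it is 0 to the left of the
    first breakpoint and 1 to the right of the last.
    """

    breakpoints: np.ndarray
    cum_probs: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.cum_probs = np.asarray(self.cum_probs, dtype=float)
        if self.breakpoints.ndim != 1 or self.breakpoints.size < 2:
            raise ValueError("need at least two breakpoints")
        if self.breakpoints.size != self.cum_probs.size:
            raise ValueError("breakpoints and cum_probs differ in length")
        if not (np.diff(self.breakpoints) > 0).all():
            raise ValueError("breakpoints must be strictly increasing")
        if (np.diff(self.cum_probs) < -1e-12).any():
            raise ValueError("cum_probs must be non-decreasing")
        if abs(self.cum_probs[0]) > 1e-9:
            raise ValueError("CDF must start at 0")
        last = self.cum_probs[-1]
        if not (abs(last - 1.0) < 1e-6):
            raise ValueError(f"CDF must end at 1 (got {last})")
        # remove floating residue so the distribution integrates to exactly 1
        self.cum_probs = np.clip(self.cum_probs / last, 0.0, 1.0)
        self.cum_probs[0] = 0.0
        self.cum_probs[-1] = 1.0

    def __call__(self, x) -> np.ndarray | float:
        return np.interp(x, self.breakpoints, self.cum_probs, left=0.0, right=1.0)

    def quantile(self, q) -> np.ndarray | float:
        """Leftmost distance at which the CDF reaches probability ``q``."""
        q_arr = np.atleast_1d(np.asarray(q, dtype=float))
        if (q_arr < 0).any() or (q_arr > 1).any():
            raise ValueError("quantile levels must lie in [0, 1]")
        idx = np.searchsorted(self.cum_probs, q_arr, side="left")
        idx = np.clip(idx, 0, self.cum_probs.size - 1)
        out = np.empty_like(q_arr)
        for k, (qi, i) in enumerate(zip(q_arr, idx)):
            if self.cum_probs[i] <= qi or i == 0:
                out[k] = self.breakpoints[i]
            else:
                p0, p1 = self.cum_probs[i - 1], self.cum_probs[i]
                b0, b1 = self.breakpoints[i - 1], self.breakpoints[i]
                out[k] = b0 + (qi - p0) / (p1 - p0) * (b1 - b0)
        return out if np.ndim(q) else float(out[0])

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    @property
    def support_max(self) -> float:
        return float(self.breakpoints[-1])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["distance_um", "cum_prob"])
            for b, p in zip(self.breakpoints, self.cum_probs):
                w.writerow([repr(float(b)), repr(float(p))])

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceCDF":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1])


@dataclass
class NullModelResult:
    """Null model over a set of images: per-image CDFs, pooled CDF and the
    equi-probability sample used for figure-style comparisons."""

    per_image_cdfs: list[DistanceCDF]
    pooled: DistanceCDF
    samples: np.ndarray
    predicted_median: float


def _capillary_distance_pieces(graph: CapillaryGraph, segs: Sequence[int],
                               somata: Sequence[tuple[int, float]],
                               segset: frozenset[int] | None,
                               total_length: float):
    """Decompose nearest-soma distance along a capillary into affine pieces.

    Yields ``(mass, lo, hi)`` triples: probability mass ``mass`` spread
    uniformly over the distance interval ``[lo, hi]``.
    """
    for seg in segs:
        Ls = graph.segment_length(seg)
        if Ls <= 0:
            continue
        du, dv = graph.end_distance_maps(seg, segset)
        # distance-to-each-soma along this segment is the min of affine
        # candidates a + s*t with slope s = ±1
        ups: list[float] = []    # intercepts of slope +1 candidates
        downs: list[float] = []  # intercepts of slope -1 candidates
        kinks = {0.0, Ls}
        on_seg: list[float] = []
        for sid, arc in somata:
            d0 = _soma_via_map(graph, du, sid, arc)
            d1 = _soma_via_map(graph, dv, sid, arc)
            if np.isfinite(d0):
                ups.append(d0)
            if np.isfinite(d1):
                downs.append(d1 + Ls)
            if sid == seg:
                on_seg.append(arc)
                kinks.add(float(arc))
                ups.append(-arc)   # branch of |t - arc| valid for t >= arc
                downs.append(arc)  # branch valid for t <= arc
        if not ups and not downs and not on_seg:
            continue
        for a_up in ups:
            for a_dn in downs:
                t = 0.5 * (a_dn - a_up)
                if 0.0 < t < Ls:
                    kinks.add(float(t))

        def dist_at(t: float) -> float:
            best = np.inf
            for sid, arc in somata:
                d = min(t + _soma_via_map(graph, du, sid, arc),
                        (Ls - t) + _soma_via_map(graph, dv, sid, arc))
                if sid == seg:
                    d = min(d, abs(t - arc))
                best = min(best, d)
            return best

        ts = sorted(k for k in kinks if -1e-12 <= k <= Ls + 1e-12)
        dvals = [dist_at(t) for t in ts]
        for (t0, d0), (t1, d1) in zip(zip(ts, dvals), zip(ts[1:], dvals[1:])):
            if t1 - t0 <= 1e-12:
                continue
            if not (np.isfinite(d0) and np.isfinite(d1)):
                continue
            lo, hi = (d0, d1) if d0 <= d1 else (d1, d0)
            yield (t1 - t0) / total_length, lo, hi


def image_null_cdf(graph: CapillaryGraph, blocked_capillary_id: str,
                   restrict_to_capillary: bool = True) -> DistanceCDF:
    """Exact CDF of nearest-soma distance for a uniformly placed blockage.

    The blockage position is uniform over the imaged arc length of the
    named capillary; the nearest *visible* soma is searched on the same
    capillary (default) or over the whole reachable network.

    Raises :class:`DegenerateGeometryError` for a zero-length capillary or
    when no visible soma is available.
    """
    segs = graph.capillary_segments(blocked_capillary_id)
    if not segs:
        raise DegenerateGeometryError(
            f"capillary {blocked_capillary_id!r} has no segments")
    L = graph.capillary_length(blocked_capillary_id)
    if L <= 0:
        raise DegenerateGeometryError("zero-length capillary")
    segset = frozenset(segs) if restrict_to_capillary else None
    somata = [(s.segment_id, float(s.arc_pos)) for s in graph.somata
              if s.visible and (segset is None or s.segment_id in segset)]
    if not somata:
        raise DegenerateGeometryError("no visible soma on capillary")

    pieces = list(_capillary_distance_pieces(graph, segs, somata, segset, L))
    if not pieces:
        raise DegenerateGeometryError("degenerate geometry: no measurable arc")
    masses = np.array([p[0] for p in pieces])
    los = np.array([p[1] for p in pieces])
    his = np.array([p[2] for p in pieces])

    bps = np.unique(np.concatenate([los, his]))
    dens = np.zeros(bps.size - 1)
    for m, lo, hi in zip(masses, los, his):
        i0 = int(np.searchsorted(bps, lo))
        i1 = int(np.searchsorted(bps, hi))
        dens[i0:i1] += m / (hi - lo)
    cum = np.concatenate([[0.0], np.cumsum(dens * np.diff(bps))])
    if bps[0] > 1e-12:
        bps = np.concatenate([[0.0], bps])
        cum = np.concatenate([[0.0], cum])
    return DistanceCDF(bps, cum / cum[-1])


def pool_cdfs(cdfs: Sequence[DistanceCDF],
              weights: Sequence[float] | None = None) -> DistanceCDF:
    """Pointwise (weighted) average of CDFs at the union of breakpoints.

    With equal weights this is the "one image, one vote" pooling used to
    average per-image null distributions; pass per-image weights (e.g.
    blockage counts) for an observation-weighted mixture.
    """
    cdfs = list(cdfs)
    if not cdfs:
        raise ValueError("no CDFs to pool")
    if weights is None:
        w = np.full(len(cdfs), 1.0 / len(cdfs))
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(cdfs) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative, one per CDF")
        w = w / w.sum()
    bps = np.unique(np.concatenate([c.breakpoints for c in cdfs]))
    vals = np.zeros_like(bps)
    for wi, c in zip(w, cdfs):
        vals += wi * c(bps)
    return DistanceCDF(bps, vals)


def equiprobability_sample(cdf: DistanceCDF, n: int,
                           convention: str = "midpoint") -> np.ndarray:
    """Represent a continuous CDF by ``n`` quantiles at evenly spaced
    cumulative probabilities.

    ``convention="midpoint"`` (default) places them at ``(i - 0.5)/n``;
    ``convention="right"`` uses ``i/n`` (whose top point is the support
    maximum).  Returned sorted ascending.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(1, n + 1, dtype=float)
    if convention == "midpoint":
        probs = (i - 0.5) / n
    elif convention == "right":
        probs = i / n
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return np.asarray(cdf.quantile(probs), dtype=float)


def linear_null(half_spacing: float) -> DistanceCDF:
    """Idealized null for evenly spaced somata on an unbranched capillary.

    With somata every ``2 * half_spacing`` every point lies within
    ``half_spacing`` of a soma and the distance is uniform, so the CDF
    rises linearly to 1 at ``half_spacing`` (30 μm for the study's ~60 μm
    inter-soma spacing).
    """
    if half_spacing <= 0:
        raise ValueError("half_spacing must be positive")
    return DistanceCDF(np.array([0.0, half_spacing]), np.array([0.0, 1.0]))


def build_null_model(graphs: Sequence[CapillaryGraph],
                     n_sample: int | None = None,
                     weighting: str = "image",
                     restrict_to_capillary: bool = True) -> NullModelResult:
    """Pool per-image null CDFs over a set of annotated images.

    Every capillary carrying at least one blockage contributes its exact
    null CDF; blocked capillaries without a visible soma are skipped (their
    observed distances are equally unmeasurable).  Within an image the
    blocked-capillary CDFs are averaged; across images pooling is equal
    weight per image (``weighting="image"``, the study convention with one
    blockage per imaged stack) or weighted by the number of contributing
    blockages (``weighting="blockages"``, the exact generative mixture when
    images hold several blockages).
    """
    if weighting not in ("image", "blockages"):
        raise ValueError(f"unknown weighting {weighting!r}")
    per_image: list[DistanceCDF] = []
    counts: list[int] = []
    for g in graphs:
        caps: dict[str, int] = {}
        for b in g.blockages:
            cap = g.capillary_of(b.segment_id)
            caps[cap] = caps.get(cap, 0) + 1
        cdfs, k = [], 0
        for cap, nb in sorted(caps.items()):
            try:
                cdf = image_null_cdf(g, cap, restrict_to_capillary)
            except DegenerateGeometryError:
                continue
            if weighting == "blockages":
                cdfs.extend([cdf] * nb)
                k += nb
            else:
                cdfs.append(cdf)
                k += 1
        if cdfs:
            per_image.append(pool_cdfs(cdfs))
            counts.append(k)
    if not per_image:
        raise ValueError("no images with measurable blocked capillaries")
    w = np.asarray(counts, float) if weighting == "blockages" else None
    pooled = pool_cdfs(per_image, w)
    n = n_sample if n_sample is not None else len(per_image)
    samples = equiprobability_sample(pooled, n)
    return NullModelResult(per_image, pooled, samples, pooled.median)
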