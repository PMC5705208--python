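"""Vessel-graph data model and geodesic distances on capillary networks.

A capillary bed imaged in a confocal field is represented as a set of
polyline *segments* (ordered point lists in micrometres).  Segment ends may
meet at shared nodes (branch points or junctions with connector vessels);
that connectivity is recorded explicitly as an adjacency list so that no
geometric snapping is ever needed.  Segments are partitioned into named
*capillaries* -- an unbranched vessel split by junctions keeps a single
capillary id across all of its pieces.

Pericyte somata and perfusion blockages are annotated as arc-length
positions on segments.  All distances used by the analysis are geodesic
("along the vessel") path lengths; Euclidean chords are available where a
planar measurement is wanted instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Soma",
    "PointOnVessel",
    "CapillaryGraph",
    "UnreachableError",
    "NoSomaError",
    "arc_distance",
    "nearest_soma_distance",
    "intersoma_distances",
    "point_coords",
    "save_graph",
    "load_graph",
]


class UnreachableError(ValueError):
    """The two query points lie on disconnected parts of the network."""


class NoSomaError(ValueError):
    """No visible pericyte soma is reachable from the query point."""


@dataclass(frozen=True)
class Soma:
    """A pericyte soma mid-point, anchored on a segment by arc position."""

    segment_id: int
    arc_pos: float
    visible: bool = True


@dataclass(frozen=True)
class PointOnVessel:
    """An arbitrary on-vessel location (e.g. a perfusion blockage)."""

    segment_id: int
    arc_pos: float


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


@dataclass
class CapillaryGraph:
    """Per-image capillary network with soma and blockage annotations.

    Parameters
    ----------
    segments
        List of ``(n_i, d)`` float arrays (``d`` = 2 or 3), coordinates in
        micrometres.  Each polyline needs at least two points and positive
        arc length.
    adjacency
        Pairs ``((seg_a, end_a), (seg_b, end_b))`` of segment ends
        (``end`` is 0 for the first point, 1 for the last) that coincide
        at a shared node.
    field_bounds
        ``(2, d)`` array of axis-aligned min/max corners of the imaged
        field.  Defaults to the bounding box of all points.
    capillary_ids
        Mapping of segment index to capillary name.  Unnamed segments get
        a per-segment default name.
    somata, blockages
        Annotation lists; arc positions must lie within their segment.
    """

    segments: list[np.ndarray]
    adjacency: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    field_bounds: np.ndarray | None = None
    capillary_ids: dict[int, str] = field(default_factory=dict)
    somata: list[Soma] = field(default_factory=list)
    blockages: list[PointOnVessel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        self._lengths = [_polyline_length(s) for s in self.segments]
        if self.field_bounds is None:
            pts = np.vstack(self.segments)
            self.field_bounds = np.vstack([pts.min(axis=0), pts.max(axis=0)])
        else:
            self.field_bounds = np.asarray(self.field_bounds, dtype=float)
        self.capillary_ids = dict(self.capillary_ids)
        for i in range(len(self.segments)):
            self.capillary_ids.setdefault(i, f"cap{i:02d}")
        self._node_of: dict[tuple[int, int], tuple[int, int]] | None = None
        self._graphs: dict = {}
        self._maps: dict = {}
        self._caps: dict[str, list[int]] | None = None
        self.validate()

    # ------------------------------------------------------------------ #
    # invariants

    def validate(self) -> None:
        n = len(self.segments)
        if n == 0:
            raise ValueError("graph needs at least one segment")
        dim = self.segments[0].shape[1]
        lo, hi = self.field_bounds
        for i, seg in enumerate(self.segments):
            if seg.ndim != 2 or seg.shape[0] < 2 or seg.shape[1] != dim:
                raise ValueError(f"segment {i}: polyline needs >=2 points of dim {dim}")
            if self._lengths[i] <= 0:
                raise ValueError(f"segment {i}: zero arc length")
            if (seg < lo - 1e-9).any() or (seg > hi + 1e-9).any():
                raise ValueError(f"segment {i}: points outside field_bounds")
        for (a, b) in self.adjacency:
            for (s, e) in (a, b):
                if not (0 <= s < n and e in (0, 1)):
                    raise ValueError(f"adjacency references invalid end {(s, e)}")
        for s in self.somata:
            self._check_on_segment(s.segment_id, s.arc_pos, "soma")
        for b in self.blockages:
            self._check_on_segment(b.segment_id, b.arc_pos, "blockage")

    def _check_on_segment(self, seg: int, arc: float, what: str) -> None:
        if not (0 <= seg < len(self.segments)):
            raise ValueError(f"{what}: unknown segment {seg}")
        if not (-1e-9 <= arc <= self._lengths[seg] + 1e-9):
            raise ValueError(f"{what}: arc position {arc} outside segment {seg}")

    # ------------------------------------------------------------------ #
    # derived structure

    def segment_length(self, seg: int) -> float:
        return self._lengths[seg]

    def capillary_of(self, seg: int) -> str:
        return self.capillary_ids[seg]

    def capillary_segments(self, name: str) -> list[int]:
        if self._caps is None:
            caps: dict[str, list[int]] = {}
            for i, c in self.capillary_ids.items():
                caps.setdefault(c, []).append(i)
            self._caps = {c: sorted(v) for c, v in caps.items()}
        return self._caps.get(name, [])

    def capillary_names(self) -> list[str]:
        return sorted({c for c in self.capillary_ids.values()})

    def capillary_length(self, name: str) -> float:
        return float(sum(self._lengths[i] for i in self.capillary_segments(name)))

    def node(self, seg: int, end: int) -> tuple[int, int]:
        """Canonical node id of a segment end after merging adjacent ends."""
        if self._node_of is None:
            parent: dict[tuple[int, int], tuple[int, int]] = {
                (i, e): (i, e) for i in range(len(self.segments)) for e in (0, 1)
            }

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for a, b in self.adjacency:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
            self._node_of = {k: find(k) for k in parent}
        return self._node_of[(seg, end)]

    def network(self, segset: frozenset[int] | None = None) -> nx.Graph:
        """Weighted node graph; optionally restricted to a segment subset."""
        key = segset
        if key not in self._graphs:
            G = nx.Graph()
            segs = range(len(self.segments)) if segset is None else sorted(segset)
            for i in segs:
                u, v = self.node(i, 0), self.node(i, 1)
                L = self._lengths[i]
                G.add_node(u)
                G.add_node(v)
                if G.has_edge(u, v):
                    if L < G[u][v]["weight"]:
                        G[u][v]["weight"] = L
                else:
                    G.add_edge(u, v, weight=L)
            self._graphs[key] = G
        return self._graphs[key]

    def end_distance_maps(self, seg: int, segset: frozenset[int] | None = None):
        """Shortest-path distance maps from both ends of ``seg``.

        Returns two dicts keyed by node id; missing nodes are unreachable.
        """
        key = (seg, segset)
        if key not in self._maps:
            G = self.network(segset)
            du = nx.single_source_dijkstra_path_length(G, self.node(seg, 0))
            dv = nx.single_source_dijkstra_path_length(G, self.node(seg, 1))
            self._maps[key] = (du, dv)
        return self._maps[key]

    def invalidate_caches(self) -> None:
        self._node_of = None
        self._graphs = {}
        self._maps = {}
        self._caps = None


# ---------------------------------------------------------------------- #
# distance operations


def _soma_via_map(graph: CapillaryGraph, dmap: dict, seg: int, arc: float) -> float:
    """Distance from a map's source node to an on-vessel position."""
    L = graph.segment_length(seg)
    d0 = dmap.get(graph.node(seg, 0), np.inf)
    d1 = dmap.get(graph.node(seg, 1), np.inf)
    return min(d0 + arc, d1 + (L - arc))


def _restriction(graph: CapillaryGraph, p: PointOnVessel,
                 restrict_to_capillary: bool) -> frozenset[int] | None:
    if not restrict_to_capillary:
        return None
    return frozenset(graph.capillary_segments(graph.capillary_of(p.segment_id)))


def arc_distance(graph: CapillaryGraph, a: PointOnVessel, b: PointOnVessel,
                 restrict_to_capillary: bool = False) -> float:
    """Shortest along-vessel path length between two on-vessel points (μm).

    Raises :class:`UnreachableError` if the points lie on disconnected
    components (of the restricted subnetwork when
    ``restrict_to_capillary`` is set).
    """
    segset = _restriction(graph, a, restrict_to_capillary)
    if segset is not None and b.segment_id not in segset:
        raise UnreachableError("points lie on different capillaries")
    best = np.inf
    if a.segment_id == b.segment_id:
        best = abs(a.arc_pos - b.arc_pos)
    du, dv = graph.end_distance_maps(a.segment_id, segset)
    La = graph.segment_length(a.segment_id)
    via_u = _soma_via_map(graph, du, b.segment_id, b.arc_pos)
    via_v = _soma_via_map(graph, dv, b.segment_id, b.arc_pos)
    best = min(best, a.arc_pos + via_u, (La - a.arc_pos) + via_v)
    if not np.isfinite(best):
        raise UnreachableError("points lie on disconnected components")
    return float(best)


def nearest_soma_distance(graph: CapillaryGraph, p: PointOnVessel,
                          restrict_to_capillary: bool = True) -> tuple[float, int]:
    """Geodesic distance from ``p`` to the nearest *visible* soma.

    By default the search is restricted to somata on the same named
    capillary as ``p`` (the chain of segments sharing its capillary id),
    mirroring a measurement made "on the same capillary".  Ties are broken
    by the lowest soma index.  Returns ``(distance_um, soma_index)``.
    """
    segset = _restriction(graph, p, restrict_to_capillary)
    du, dv = graph.end_distance_maps(p.segment_id, segset)
    L = graph.segment_length(p.segment_id)
    best, best_i = np.inf, -1
    for i, s in enumerate(graph.somata):
        if not s.visible:
            continue
        if segset is not None and s.segment_id not in segset:
            continue
        d = min(p.arc_pos + _soma_via_map(graph, du, s.segment_id, s.arc_pos),
                (L - p.arc_pos) + _soma_via_map(graph, dv, s.segment_id, s.arc_pos))
        if s.segment_id == p.segment_id:
            d = min(d, abs(p.arc_pos - s.arc_pos))
        if d < best:
            best, best_i = d, i
    if not np.isfinite(best):
        raise NoSomaError("no reachable visible soma")
    return float(best), best_i


def point_coords(graph: CapillaryGraph, p: PointOnVessel) -> np.ndarray:
    """Cartesian coordinates (μm) of an on-vessel point."""
    seg = graph.segments[p.segment_id]
    d = np.linalg.norm(np.diff(seg, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    arc = min(max(p.arc_pos, 0.0), cum[-1])
    j = int(np.searchsorted(cum, arc, side="right") - 1)
    j = min(j, len(d) - 1)
    frac = 0.0 if d[j] == 0 else (arc - cum[j]) / d[j]
    return seg[j] + frac * (seg[j + 1] - seg[j])


def intersoma_distances(graph: CapillaryGraph, metric: str = "geodesic") -> np.ndarray:
    """Distances between *adjacent* visible soma pairs on each capillary.

    A pair is adjacent when no third soma lies on a shortest path between
    them.  ``metric`` selects the reported distance: ``"geodesic"``
    (along-vessel, default) or ``"euclidean"`` (straight chord, as would be
    measured within an imaging plane).
    """
    if metric not in ("geodesic", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    out: list[float] = []
    for cap in graph.capillary_names():
        segset = frozenset(graph.capillary_segments(cap))
        idx = [i for i, s in enumerate(graph.somata)
               if s.visible and s.segment_id in segset]
        if len(idx) < 2:
            continue
        pts = [PointOnVessel(graph.somata[i].segment_id, graph.somata[i].arc_pos)
               for i in idx]
        m = len(idx)
        D = np.full((m, m), np.inf)
        for a in range(m):
            for b in range(a + 1, m):
                try:
                    D[a, b] = D[b, a] = arc_distance(
                        graph, pts[a], pts[b], restrict_to_capillary=True)
                except UnreachableError:
                    pass
        for a in range(m):
            for b in range(a + 1, m):
                if not np.isfinite(D[a, b]):
                    continue
                between = any(
                    k not in (a, b)
                    and D[a, k] + D[k, b] <= D[a, b] + 1e-9
                    for k in range(m)
                )
                if between:
                    continue
                if metric == "geodesic":
                    out.append(D[a, b])
                else:
                    out.append(float(np.linalg.norm(
                        point_coords(graph, pts[a]) - point_coords(graph, pts[b]))))
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------- #
# serialization: one directory per image
#   segments.csv    segment_id, point_index, x, y[, z]
#   annotations.csv kind, segment_id, arc_pos_um, visible
#   meta.json       field bounds, capillary id map, adjacency, units


def save_graph(graph: CapillaryGraph, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dim = graph.segments[0].shape[1]
    cols = ["x", "y", "z"][:dim]
    rows = []
    for i, seg in enumerate(graph.segments):
        for j, pt in enumerate(seg):
            rows.append([i, j, *pt])
    pd.DataFrame(rows, columns=["segment_id", "point_index", *cols]).to_csv(
        path / "segments.csv", index=False)
    ann = []
    for s in graph.somata:
        ann.append(["soma", s.segment_id, s.arc_pos, s.visible])
    for b in graph.blockages:
        ann.append(["blockage", b.segment_id, b.arc_pos, True])
    pd.DataFrame(ann, columns=["kind", "segment_id", "arc_pos_um", "visible"]).to_csv(
        path / "annotations.csv", index=False)
    meta = {
        "units": "um",
        "field_bounds": graph.field_bounds.tolist(),
        "capillary_ids": {str(k): v for k, v in graph.capillary_ids.items()},
        "adjacency": [[list(a), list(b)] for a, b in graph.adjacency],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_graph(path: str | Path) -> CapillaryGraph:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    segdf = pd.read_csv(path / "segments.csv")
    cols = [c for c in ("x", "y", "z") if c in segdf.columns]
    segments = []
    for i in sorted(segdf["segment_id"].unique()):
        sub = segdf[segdf["segment_id"] == i].sort_values("point_index")
        segments.append(sub[cols].to_numpy(dtype=float))
    ann = pd.read_csv(path / "annotations.csv")
    somata = [Soma(int(r.segment_id), float(r.arc_pos_um), bool(r.visible))
              for r in ann[ann["kind"] == "soma"].itertuples()]
    blockages = [PointOnVessel(int(r.segment_id), float(r.arc_pos_um))
                 for r in ann[ann["kind"] == "blockage"].itertuples()]
    return CapillaryGraph(
        segments=segments,
        adjacency=[(tuple(a), tuple(b)) for a, b in meta["adjacency"]],
        field_bounds=np.asarray(meta["field_bounds"], dtype=float),
        capillary_ids={int(k): v for k, v in meta["capillary_ids"].items()},
        somata=somata,
        blockages=blockages,
    )
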