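"""Independent brute-force oracles used only by the test suite."""

import numpy as np

from periflow.geometry import CapillaryGraph, PointOnVessel, nearest_soma_distance


def discretized_null_cdf_values(graph: CapillaryGraph, capillary_id: str,
                                queries: np.ndarray, step: float = 0.01,
                                vectorized: bool = True) -> np.ndarray:
    """Null CDF by uniform discretization of the capillary arc.

    Samples the capillary at ``step`` μm, evaluates the nearest-visible-
    soma distance at every grid point, and spreads each cell's probability
    mass uniformly between its endpoint distances.  ``vectorized`` uses a
    numpy transliteration of the same point-distance formula for speed;
    ``vectorized=False`` calls :func:`nearest_soma_distance` point by
    point (slow, maximally independent).
    """
    segs = graph.capillary_segments(capillary_id)
    L = graph.capillary_length(capillary_id)
    segset = frozenset(segs)
    somata = [(s.segment_id, s.arc_pos) for s in graph.somata
              if s.visible and s.segment_id in segset]
    F = np.zeros_like(queries, dtype=float)
    for sid in segs:
        Ls = graph.segment_length(sid)
        ts = np.linspace(0.0, Ls, max(2, int(round(Ls / step)) + 1))
        if vectorized:
            du, dv = graph.end_distance_maps(sid, segset)
            ds = np.full(ts.size, np.inf)
            for s_sid, s_arc in somata:
                Lse = graph.segment_length(s_sid)
                d_u = min(du.get(graph.node(s_sid, 0), np.inf) + s_arc,
                          du.get(graph.node(s_sid, 1), np.inf) + (Lse - s_arc))
                d_v = min(dv.get(graph.node(s_sid, 0), np.inf) + s_arc,
                          dv.get(graph.node(s_sid, 1), np.inf) + (Lse - s_arc))
                cand = np.minimum(ts + d_u, (Ls - ts) + d_v)
                if s_sid == sid:
                    cand = np.minimum(cand, np.abs(ts - s_arc))
                ds = np.minimum(ds, cand)
        else:
            ds = np.array([nearest_soma_distance(graph, PointOnVessel(sid, t))[0]
                           for t in ts])
        lo = np.minimum(ds[:-1], ds[1:])
        hi = np.maximum(ds[:-1], ds[1:])
        mass = np.diff(ts) / L
        span = np.maximum(hi - lo, 1e-300)
        frac = np.clip((queries[None, :] - lo[:, None]) / span[:, None], 0.0, 1.0)
        F += (mass[:, None] * frac).sum(axis=0)
    return F


def mc_two_sample_t_power(n: int, delta: float, sd: float, alpha: float,
                          n_sim: int, rng: np.random.Generator) -> float:
    """Monte-Carlo power of the two-sided two-sample t-test."""
    a = rng.normal(0.0, sd, (n_sim, n))
    b = rng.normal(delta, sd, (n_sim, n))
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp = np.sqrt(((n - 1) * va + (n - 1) * vb) / (2 * n - 2))
    t = (mb - ma) / (sp * np.sqrt(2.0 / n))
    from scipy import stats as sps
    t_crit = sps.t.ppf(1 - alpha / 2, 2 * n - 2)
    return float((np.abs(t) > t_crit).mean())
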