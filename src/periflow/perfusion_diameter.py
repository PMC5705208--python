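"""Perfused-volume ROI quantification, transect counting of blocked
capillaries, and pericyte-site diameter analyses.

Perfusion maps are 12 ordered regions of interest (ROIs) drawn clockwise
around the left ventricle starting at the mid-septum; the risk zone
deprived of flow during occlusion corresponds to ROIs 7-10.  Each heart's
ROI intensities are normalized to that heart's brightest ROI, averaged per
condition, and rescaled so that the mean over ROIs 1-3 (a region outside
the risk zone) equals 1.  Blocked-capillary percentages come from counting
filled vs unfilled vessels crossing a central transect perpendicular to
the main capillary axis.  Diameter analysis compares the lumen diameter at
a pericyte soma with the diameter 10 μm upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import CapillaryGraph
from .stats import TestResult, auto_compare, one_sample_compare

__all__ = [
    "RoiTable",
    "DiameterPair",
    "TransectCount",
    "NormalizedRois",
    "N_ROIS",
    "RISK_ZONE_ROIS",
    "REFERENCE_ROIS",
    "count_transect",
    "normalize_rois",
    "risk_zone_deficit",
    "blocked_fraction",
    "diameter_ratio_analysis",
]

log = logging.getLogger(__name__)

N_ROIS = 12
RISK_ZONE_ROIS = (7, 8, 9, 10)
REFERENCE_ROIS = (1, 2, 3)


@dataclass
class RoiTable:
    """Per-heart perfusion intensities in the 12 clockwise ROIs
    (index 1 at the mid-septum)."""

    heart_id: str
    condition: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (N_ROIS,):
            raise ValueError(f"need exactly {N_ROIS} ROI intensities")
        if (self.intensities < 0).any():
            raise ValueError("ROI intensities must be non-negative")


@dataclass
class DiameterPair:
    """Lumen diameter at a pericyte soma and ~10 μm upstream (μm)."""

    heart_id: str
    condition: str
    d_soma: float
    d_upstream: float
    blockage_associated: bool = False


@dataclass
class TransectCount:
    """Filled vs unfilled capillaries crossing the central transect of one
    image stack."""

    image_id: str
    condition: str
    n_perfused: int
    n_blocked: int

    def __post_init__(self) -> None:
        if self.n_perfused < 0 or self.n_blocked < 0:
            raise ValueError("counts must be non-negative")
        if self.n_perfused + self.n_blocked < 1:
            raise ValueError("at least one capillary must cross the transect")

    @property
    def fraction_blocked(self) -> float:
        return self.n_blocked / (self.n_blocked + self.n_perfused)


def count_transect(graph: CapillaryGraph, condition: str = "",
                   image_id: str = "", main_axis: int = 0) -> TransectCount:
    """Count perfused and blocked capillaries crossing the centre transect.

    The transect is the line through the field centre perpendicular to the
    main capillary axis (coordinate ``main_axis``).  A crossing capillary
    counts as blocked when it carries a blockage annotation (its tracer
    signal terminates within the image), otherwise as perfused.
    """
    lo, hi = graph.field_bounds
    cx = 0.5 * (lo[main_axis] + hi[main_axis])
    blocked_caps = {graph.capillary_of(b.segment_id) for b in graph.blockages}
    n_perf = n_block = 0
    for cap in graph.capillary_names():
        crosses = any(
            graph.segments[i][:, main_axis].min() <= cx <= graph.segments[i][:, main_axis].max()
            for i in graph.capillary_segments(cap)
        )
        if not crosses:
            continue
        if cap in blocked_caps:
            n_block += 1
        else:
            n_perf += 1
    return TransectCount(image_id, condition, n_perf, n_block)


@dataclass
class NormalizedRois:
    """Normalized per-heart ROI curves and per-condition mean curves.

    ``per_heart`` is long-format (heart_id, condition, roi, value);
    ``condition_means`` is indexed by condition with one column per ROI;
    ``factors`` records the per-condition rescale factor applied so that
    the reference-ROI mean equals 1.
    """

    per_heart: pd.DataFrame
    condition_means: pd.DataFrame
    factors: dict[str, float]


def normalize_rois(tables: Sequence[RoiTable],
                   reference_condition: str | None = None) -> NormalizedRois:
    """Normalize ROI tables within heart, average per condition and rescale.

    Each heart is divided by its own maximum ROI intensity (making the
    result invariant to overall staining brightness), hearts are averaged
    within condition, and every curve of a condition is divided by that
    condition's mean over ROIs 1-3.  Passing ``reference_condition`` uses
    one shared rescale factor (that condition's) for every condition
    instead.
    """
    if not tables:
        raise ValueError("no ROI tables")
    rows = []
    for t in tables:
        mx = t.intensities.max()
        if mx <= 0:
            raise ValueError(f"empty perfusion map for heart {t.heart_id!r}")
        for roi, v in enumerate(t.intensities / mx, start=1):
            rows.append((t.heart_id, t.condition, roi, v))
    df = pd.DataFrame(rows, columns=["heart_id", "condition", "roi", "value"])
    means = df.groupby(["condition", "roi"])["value"].mean().unstack("roi")
    ref = list(REFERENCE_ROIS)
    factors = {c: float(means.loc[c, ref].mean()) for c in means.index}
    if reference_condition is not None:
        if reference_condition not in factors:
            raise ValueError(f"no hearts in condition {reference_condition!r}")
        factors = {c: factors[reference_condition] for c in factors}
    df["value"] = df.apply(lambda r: r["value"] / factors[r["condition"]], axis=1)
    means = df.groupby(["condition", "roi"])["value"].mean().unstack("roi")
    return NormalizedRois(df, means, factors)


def risk_zone_deficit(norm: NormalizedRois,
                      risk_rois: Sequence[int] = RISK_ZONE_ROIS) -> dict:
    """Risk-zone perfusion per condition and the headline contrasts.

    Averages the normalized values over the risk-zone ROIs for each heart,
    reports per-condition means, the percent perfusion deficit of
    ischaemia vs sham, the percent rescue by adenosine vs ischaemia, and
    the corresponding two-group tests on per-heart means (when both groups
    have >= 3 hearts).
    """
    df = norm.per_heart
    sub = df[df["roi"].isin(list(risk_rois))]
    per_heart = (sub.groupby(["condition", "heart_id"])["value"]
                 .mean().rename("risk_mean").reset_index())
    cond_means = per_heart.groupby("condition")["risk_mean"].mean().to_dict()
    out: dict = {
        "per_heart": per_heart,
        "condition_means": cond_means,
        "contrasts": {},
        "tests": {},
    }

    def contrast(name: str, num: str, den: str, sign: str) -> None:
        if num not in cond_means or den not in cond_means:
            log.warning("contrast %s skipped: missing condition", name)
            return
        change = (cond_means[num] / cond_means[den] - 1.0) * 100.0
        out["contrasts"][name] = -change if sign == "deficit" else change
        a = per_heart.loc[per_heart["condition"] == num, "risk_mean"].to_numpy()
        b = per_heart.loc[per_heart["condition"] == den, "risk_mean"].to_numpy()
        if a.size >= 3 and b.size >= 3:
            out["tests"][name] = auto_compare(a, b)

    contrast("ischaemia_vs_sham_deficit_pct", "ischaemia", "sham", "deficit")
    contrast("adenosine_vs_ischaemia_rescue_pct",
             "ischaemia_adenosine", "ischaemia", "increase")
    contrast("adenosine_vs_sham_deficit_pct",
             "ischaemia_adenosine", "sham", "deficit")
    return out


def blocked_fraction(counts: Sequence[TransectCount]) -> pd.DataFrame:
    """Percent of capillaries blocked per condition (mean ± s.e.m. over
    images, each image's per-transect fraction being one unit)."""
    if not counts:
        raise ValueError("no transect counts")
    df = pd.DataFrame(
        [(c.condition, c.image_id, 100.0 * c.fraction_blocked) for c in counts],
        columns=["condition", "image_id", "pct_blocked"],
    )
    g = df.groupby("condition")["pct_blocked"]
    out = pd.DataFrame({
        "mean_pct": g.mean(),
        "sem_pct": g.sem(ddof=1),
        "n_images": g.count(),
    })
    return out


def diameter_ratio_analysis(pairs: Sequence[DiameterPair]) -> dict:
    """Soma/upstream diameter-ratio statistics per condition and contrasts.

    For every pair the ratio r = d_soma / d_upstream is formed (pairs with
    zero upstream diameter are excluded and logged).  Reports, per
    condition: n, mean ratio ± s.e.m., mean soma diameter ± s.e.m., and a
    one-sample test of the ratio against 1.  Across conditions: percent
    change of the mean soma diameter for ischaemia vs sham and adenosine
    vs ischaemia (exact algebra on the condition means), plus two-group
    tests on the ratios.
    """
    usable = []
    excluded = 0
    for p in pairs:
        if p.d_upstream <= 0:
            excluded += 1
            continue
        usable.append(p)
    if excluded:
        log.warning("excluded %d diameter pair(s) with zero upstream diameter",
                    excluded)
    if not usable:
        raise ValueError("no usable diameter pairs")
    df = pd.DataFrame([(p.condition, p.d_soma, p.d_upstream,
                        p.d_soma / p.d_upstream) for p in usable],
                      columns=["condition", "d_soma", "d_upstream", "ratio"])
    per_condition: dict[str, dict] = {}
    for cond, sub in df.groupby("condition"):
        n = len(sub)
        entry = {
            "n": n,
            "ratio_mean": float(sub["ratio"].mean()),
            "ratio_sem": float(sub["ratio"].sem(ddof=1)) if n > 1 else np.nan,
            "d_soma_mean": float(sub["d_soma"].mean()),
            "d_soma_sem": float(sub["d_soma"].sem(ddof=1)) if n > 1 else np.nan,
        }
        if n >= 3:
            entry["test_ratio_vs_1"] = one_sample_compare(sub["ratio"], 1.0)
        per_condition[cond] = entry

    contrasts: dict[str, float] = {}
    tests: dict[str, TestResult] = {}

    def pct_change(name: str, num: str, den: str) -> None:
        if num in per_condition and den in per_condition:
            contrasts[name] = (per_condition[num]["d_soma_mean"]
                               / per_condition[den]["d_soma_mean"] - 1.0) * 100.0

    def ratio_test(name: str, a_cond: str, b_cond: str) -> None:
        if a_cond in per_condition and b_cond in per_condition:
            a = df.loc[df["condition"] == a_cond, "ratio"].to_numpy()
            b = df.loc[df["condition"] == b_cond, "ratio"].to_numpy()
            if a.size >= 3 and b.size >= 3:
                tests[name] = auto_compare(a, b)

    pct_change("d_soma_pct_change_ischaemia_vs_sham", "ischaemia", "sham")
    pct_change("d_soma_pct_change_adenosine_vs_ischaemia",
               "ischaemia_adenosine", "ischaemia")
    ratio_test("ratio_ischaemia_vs_sham", "ischaemia", "sham")
    ratio_test("ratio_adenosine_vs_ischaemia", "ischaemia_adenosine", "ischaemia")
    ratio_test("ratio_adenosine_vs_sham", "ischaemia_adenosine", "sham")
    return {"per_condition": per_condition, "contrasts": contrasts, "tests": tests}
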