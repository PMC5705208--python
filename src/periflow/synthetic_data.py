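"""Seeded generator of synthetic coronary-capillary study data.

Emulates the measured structure of the study system: confocal fields of
parallel left-ventricular capillaries (160 μm square) linked by occasional
orthogonal connectors, pericyte somata spaced ~60 μm apart along vessels
(gamma-distributed gaps), condition-dependent capillary blockage (sham 3%,
ischaemia 40%, ischaemia + adenosine 30% of capillaries), blockage
positions either clustered near pericyte somata (half-normal offset with
median 3.6 μm) or uniform along the vessel (the null's generative
counterpart), tracer-intensity profiles with a sigmoidal drop at each
block, soma-site diameters and soma/upstream diameter ratios per
condition, and 12-ROI ventricular perfusion maps with a risk-zone deficit
under ischaemia partially rescued by adenosine.

Every generated artifact is reproducible from a configuration plus a seed;
independent random streams are spawned per artifact so that, for a fixed
seed, adding one output never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .blockage_analysis import LumenProfile
from .geometry import CapillaryGraph, PointOnVessel, Soma, save_graph
from .perfusion_diameter import DiameterPair, RoiTable

__all__ = [
    "StudyConfig",
    "ConditionData",
    "CONDITIONS",
    "generate_bed",
    "assign_condition",
    "sample_diameter_pairs",
    "generate_ventricle_map",
    "generate_study",
]

CONDITIONS = ("sham", "ischaemia", "ischaemia_adenosine")

# Derived condition parameters: the ischaemic soma-site diameter is the
# sham diameter reduced by 37%, the adenosine diameter is the ischaemic
# one increased by 21%, and the adenosine ratio assumes the upstream
# diameter is unchanged from ischaemia (0.822 * 1.21).
_SHAM_D_SOMA = 5.38
_ISCH_D_SOMA = _SHAM_D_SOMA * (1.0 - 0.37)
_ADO_D_SOMA = _ISCH_D_SOMA * 1.21


def _default_p_block() -> dict[str, float]:
    return {
        "sham": 0.03,
        "ischaemia": 0.40,
        "ischaemia_adenosine": 0.30,
        "ischaemia_terazosin": 0.488,
        "ischaemia_vehicle": 0.447,
    }


@dataclass(frozen=True)
class StudyConfig:
    """All tunable parameters of the synthetic study, with defaults set to
    the study's printed values.

    Distances in μm; probabilities in [0, 1].  Standard deviations quoted
    per condition are reconstructed from printed s.e.m. values and sample
    sizes (s.d. = s.e.m. * sqrt(n)); soma-site diameters share the sham
    coefficient of variation where no spread was printed.
    """

    # imaged field and bed layout
    field_size: float = 160.0
    field_depth: float = 20.0
    capillaries_per_image: int = 26
    connector_prob: float = 0.12        # per adjacent capillary pair

    # pericyte placement
    intersoma_mean: float = 60.0
    intersoma_cv: float = 0.35
    soma_coverage_parallel: float = 0.92
    soma_coverage_connector: float = 0.66

    # blockage model
    p_block: dict[str, float] = field(default_factory=_default_p_block)
    placement_mode: str = "associated"      # or "random"
    block_offset_dist: str = "half_normal"  # or "exponential"
    block_distance_median: float = 3.6

    # diameters at pericyte somata
    d_soma_mean: dict[str, float] = field(default_factory=lambda: {
        "sham": _SHAM_D_SOMA,
        "ischaemia": _ISCH_D_SOMA,
        "ischaemia_adenosine": _ADO_D_SOMA,
    })
    d_soma_cv: float = 1.25 / _SHAM_D_SOMA   # s.d. 1.25 μm at sham (0.28 * sqrt(20))
    ratio_mean: dict[str, float] = field(default_factory=lambda: {
        "sham": 1.058,
        "ischaemia": 0.822,
        "ischaemia_adenosine": 0.822 * 1.21,
    })
    ratio_sd: dict[str, float] = field(default_factory=lambda: {
        "sham": 0.067,        # 0.015 * sqrt(20)
        "ischaemia": 0.170,   # 0.022 * sqrt(60)
        "ischaemia_adenosine": 0.170,
    })
    n_pairs: dict[str, int] = field(default_factory=lambda: {
        "sham": 20, "ischaemia": 60, "ischaemia_adenosine": 60,
    })

    # ventricular perfusion maps
    roi_posterior_elevation: float = 1.2
    roi_risk_multiplier: dict[str, float] = field(default_factory=lambda: {
        "sham": 1.0,
        "ischaemia": 0.51,          # 49% deficit vs sham
        "ischaemia_adenosine": 0.51 * 1.57,   # 57% rescue vs ischaemia
    })
    roi_noise_sd: float = 0.10      # per-ROI multiplicative log-normal
    roi_heart_sd: float = 0.10      # per-heart multiplicative log-normal
    roi_base_intensity: float = 100.0

    # cohort sizes
    hearts: dict[str, int] = field(default_factory=lambda: {
        "sham": 5, "ischaemia": 6, "ischaemia_adenosine": 8,
    })
    stacks_per_heart: int = 3

    # tracer profiles
    profile_step: float = 0.2
    profile_noise_sd: float = 0.05      # in plateau units
    profile_drop_width: float = 3.0     # 10-90% fall distance
    profile_background: float = 20.0
    profile_amplitude: float = 100.0

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        if self.field_size <= 0 or self.capillaries_per_image < 1:
            raise ValueError("field too small for one capillary")
        for name, p in self.p_block.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_block[{name}] outside [0, 1]")
        for v in (self.intersoma_mean, self.block_distance_median,
                  self.profile_step, self.roi_base_intensity):
            if v <= 0:
                raise ValueError("scale parameters must be positive")
        if self.placement_mode not in ("associated", "random"):
            raise ValueError(f"unknown placement mode {self.placement_mode!r}")
        if self.block_offset_dist not in ("half_normal", "exponential"):
            raise ValueError(f"unknown offset distribution {self.block_offset_dist!r}")

    def param_condition(self, condition: str) -> str:
        """Map a condition label to the key carrying its diameter/ROI
        parameters (terazosin-arm variants share the ischaemia values)."""
        if condition in self.d_soma_mean:
            return condition
        if condition.startswith("ischaemia"):
            return "ischaemia"
        raise ValueError(f"unknown condition {condition!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        if path.suffix == ".toml":
            import tomllib
            return cls.from_dict(tomllib.loads(text))
        return cls.from_dict(json.loads(text))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gamma_gap(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    shape = 1.0 / cv ** 2
    return float(rng.gamma(shape, mean * cv ** 2))


def _renewal_positions(rng: np.random.Generator, length: float,
                       mean: float, cv: float) -> list[float]:
    """Soma positions on a covered vessel: one seed soma placed uniformly,
    then extended in both directions with gamma-distributed gaps.  A
    covered vessel therefore always carries at least one soma."""
    s0 = float(rng.uniform(0.0, length))
    pos = [s0]
    p = s0
    while True:
        p += _gamma_gap(rng, mean, cv)
        if p > length:
            break
        pos.append(p)
    p = s0
    while True:
        p -= _gamma_gap(rng, mean, cv)
        if p < 0:
            break
        pos.append(p)
    return sorted(pos)


@dataclass
class _Chain:
    """Bookkeeping for one capillary: ordered segment ids and the global
    arc offset at which each segment starts."""

    name: str
    seg_ids: list[int]
    offsets: list[float]
    length: float
    is_connector: bool

    def locate(self, arc: float) -> tuple[int, float]:
        arc = min(max(arc, 0.0), self.length)
        for sid, off in zip(reversed(self.seg_ids), reversed(self.offsets)):
            if arc >= off - 1e-12:
                return sid, arc - off
        return self.seg_ids[0], 0.0


def _build_chains(cfg: StudyConfig, rng: np.random.Generator):
    """Lay out parallel capillaries (along x) with occasional orthogonal
    connectors, splitting parallels at junctions so that connectivity is a
    true shared node."""
    W = cfg.field_size
    n = cfg.capillaries_per_image
    spacing = W / n
    ys = [(i + 0.5) * spacing for i in range(n)]

    # connectors between adjacent parallel pairs, one at most per pair
    connectors = []  # (pair index i, x position)
    for i in range(n - 1):
        if rng.random() < cfg.connector_prob:
            connectors.append((i, float(rng.uniform(0.05 * W, 0.95 * W))))

    junctions: dict[int, list[float]] = {i: [] for i in range(n)}
    for i, x in connectors:
        junctions[i].append(x)
        junctions[i + 1].append(x)

    segments: list[np.ndarray] = []
    capillary_ids: dict[int, str] = {}
    chains: list[_Chain] = []
    # node registry: (line index, x) -> (segment, end); first registrant
    # owns the node, later arrivals are recorded as adjacency pairs
    node_owner: dict[tuple[int, float], tuple[int, int]] = {}
    adjacency: list[tuple[tuple[int, int], tuple[int, int]]] = []

    def register(line: int, x: float, seg_end: tuple[int, int]) -> None:
        key = (line, round(x, 9))
        if key in node_owner:
            adjacency.append((node_owner[key], seg_end))
        else:
            node_owner[key] = seg_end

    for i, y in enumerate(ys):
        cuts = sorted(junctions[i])
        xs = [0.0, *cuts, W]
        name = f"cap{i:02d}"
        seg_ids, offsets = [], []
        for x0, x1 in zip(xs, xs[1:]):
            sid = len(segments)
            segments.append(np.array([[x0, y], [x1, y]]))
            capillary_ids[sid] = name
            seg_ids.append(sid)
            offsets.append(x0)
            register(i, x0, (sid, 0))
            register(i, x1, (sid, 1))
        chains.append(_Chain(name, seg_ids, offsets, W, False))

    for k, (i, x) in enumerate(connectors):
        sid = len(segments)
        y0, y1 = ys[i], ys[i + 1]
        segments.append(np.array([[x, y0], [x, y1]]))
        name = f"conn{k:02d}"
        capillary_ids[sid] = name
        register(i, x, (sid, 0))
        register(i + 1, x, (sid, 1))
        chains.append(_Chain(name, [sid], [0.0], y1 - y0, True))

    return segments, capillary_ids, adjacency, chains


def generate_bed(cfg: StudyConfig, seed) -> CapillaryGraph:
    """Generate one image's capillary bed with pericyte somata.

    Parallel capillaries span the square field; sparse orthogonal
    connectors join adjacent parallels at shared nodes.  A capillary is
    "covered" by pericytes with the configured coverage probability
    (higher for parallel than for connector vessels); covered vessels
    carry somata with gamma-distributed inter-soma gaps of the configured
    mean and coefficient of variation.
    """
    cfg.validate()
    rng = _rng(seed)
    segments, capillary_ids, adjacency, chains = _build_chains(cfg, rng)
    somata: list[Soma] = []
    for ch in chains:
        coverage = (cfg.soma_coverage_connector if ch.is_connector
                    else cfg.soma_coverage_parallel)
        if rng.random() >= coverage:
            continue
        for arc in _renewal_positions(rng, ch.length, cfg.intersoma_mean,
                                      cfg.intersoma_cv):
            sid, local = ch.locate(arc)
            somata.append(Soma(sid, local, visible=True))
    graph = CapillaryGraph(
        segments=segments,
        adjacency=adjacency,
        field_bounds=np.array([[0.0, 0.0], [cfg.field_size, cfg.field_size]]),
        capillary_ids=capillary_ids,
        somata=somata,
    )
    graph._chains = chains  # cached layout for condition assignment
    return graph


def _chains_of(graph: CapillaryGraph) -> list[_Chain]:
    chains = getattr(graph, "_chains", None)
    if chains is None:
        raise ValueError("graph was not produced by generate_bed")
    return chains


def _offset_scale(cfg: StudyConfig) -> float:
    if cfg.block_offset_dist == "half_normal":
        # half-normal median = scale * z_0.75
        return cfg.block_distance_median / sps.norm.ppf(0.75)
    return cfg.block_distance_median / np.log(2.0)   # exponential


def _draw_offset(rng: np.random.Generator, cfg: StudyConfig) -> float:
    s = _offset_scale(cfg)
    if cfg.block_offset_dist == "half_normal":
        return abs(float(rng.normal(0.0, s)))
    return float(rng.exponential(s))


def _synth_profile(rng: np.random.Generator, cfg: StudyConfig,
                   length: float, block_arc: float) -> LumenProfile:
    x = np.arange(0.0, length + cfg.profile_step / 2, cfg.profile_step)
    # logistic scale from the 10-90% fall distance
    s = cfg.profile_drop_width / (2.0 * np.log(9.0))
    z = 1.0 / (1.0 + np.exp(-(block_arc - x) / s))
    noise = rng.normal(0.0, cfg.profile_noise_sd, x.size)
    intensities = cfg.profile_background + cfg.profile_amplitude * (z + noise)
    return LumenProfile(x, np.clip(intensities, 0.0, None),
                        background=cfg.profile_background)


@dataclass
class ConditionData:
    """Output of :func:`assign_condition`: the annotated graph plus the
    per-blockage tracer profiles and per-soma diameter pairs."""

    graph: CapillaryGraph
    blockages: list[PointOnVessel]
    diameter_pairs: list[DiameterPair]
    profiles: list[LumenProfile]


def sample_diameter_pairs(condition: str, n: int, cfg: StudyConfig, seed,
                          heart_id: str = "synthetic") -> list[DiameterPair]:
    """Draw ``n`` soma-site diameter pairs for a condition.

    The soma-site diameter is normal with the condition mean and a shared
    coefficient of variation; the soma/upstream ratio is normal with the
    condition mean and s.d.; the upstream diameter is d_soma / ratio.
    Draws are truncated away from non-physical values (< 0.2 μm).
    """
    rng = _rng(seed)
    key = cfg.param_condition(condition)
    mean_d = cfg.d_soma_mean[key]
    sd_d = mean_d * cfg.d_soma_cv
    pairs = []
    for _ in range(n):
        d_soma = 0.0
        while d_soma < 0.2:
            d_soma = float(rng.normal(mean_d, sd_d))
        ratio = 0.0
        while ratio < 0.2:
            ratio = float(rng.normal(cfg.ratio_mean[key], cfg.ratio_sd[key]))
        pairs.append(DiameterPair(heart_id, condition, d_soma, d_soma / ratio))
    return pairs


def assign_condition(graph: CapillaryGraph, condition: str, cfg: StudyConfig,
                     seed, placement_mode: str | None = None,
                     make_profiles: bool = True,
                     make_diameters: bool = True,
                     heart_id: str = "synthetic") -> ConditionData:
    """Apply an experimental condition to a generated bed.

    Each parallel capillary is blocked independently with the condition's
    blockage probability.  In ``"associated"`` placement the blockage sits
    at a half-normal (or exponential) arc offset from a randomly chosen
    soma of that capillary, scaled so the offset median equals the
    configured value; in ``"random"`` placement it is uniform over the
    capillary -- exactly the generative counterpart of the null model.
    Capillaries without somata fall back to uniform placement.  Every
    blocked capillary receives a synthetic tracer profile with a sigmoidal
    drop at the blockage; one diameter pair is drawn per visible soma.
    """
    cfg.validate()
    if condition not in cfg.p_block:
        raise ValueError(f"unknown condition {condition!r}")
    mode = placement_mode or cfg.placement_mode
    if mode not in ("associated", "random"):
        raise ValueError(f"unknown placement mode {mode!r}")
    rng = _rng(seed)
    chains = _chains_of(graph)
    p = cfg.p_block[condition]

    soma_arcs: dict[str, list[float]] = {}
    for s in graph.somata:
        if not s.visible:
            continue
        cap = graph.capillary_of(s.segment_id)
        for ch in chains:
            if ch.name == cap:
                for sid, off in zip(ch.seg_ids, ch.offsets):
                    if sid == s.segment_id:
                        soma_arcs.setdefault(cap, []).append(off + s.arc_pos)

    blockages: list[PointOnVessel] = []
    profiles: list[LumenProfile] = []
    for ch in chains:
        if ch.is_connector:
            continue
        if rng.random() >= p:
            continue
        arcs = soma_arcs.get(ch.name)
        if mode == "associated" and arcs:
            soma_arc = arcs[rng.integers(len(arcs))]
            offset = _draw_offset(rng, cfg)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            arc = min(max(soma_arc + sign * offset, 0.0), ch.length)
        else:
            arc = float(rng.uniform(0.0, ch.length))
        sid, local = ch.locate(arc)
        blockages.append(PointOnVessel(sid, local))
        if make_profiles:
            profiles.append(_synth_profile(rng, cfg, ch.length, arc))

    annotated = CapillaryGraph(
        segments=graph.segments,
        adjacency=graph.adjacency,
        field_bounds=graph.field_bounds,
        capillary_ids=graph.capillary_ids,
        somata=graph.somata,
        blockages=blockages,
    )
    annotated._chains = chains

    n_somata = sum(1 for s in graph.somata if s.visible)
    pairs = (sample_diameter_pairs(condition, n_somata, cfg, rng, heart_id)
             if make_diameters else [])
    return ConditionData(annotated, blockages, pairs, profiles)


def generate_ventricle_map(condition: str, cfg: StudyConfig, seed,
                           heart_id: str = "synthetic") -> RoiTable:
    """One heart's 12-ROI perfusion map.

    Baseline intensity 1 with the posterior-wall elevation on ROIs 4-6 and
    the condition's risk-zone multiplier on ROIs 7-10, times multiplicative
    log-normal heart-level and per-ROI noise.
    """
    cfg.validate()
    rng = _rng(seed)
    key = cfg.param_condition(condition)
    shape = np.ones(12)
    shape[3:6] *= cfg.roi_posterior_elevation
    shape[6:10] *= cfg.roi_risk_multiplier[key]
    heart_factor = float(np.exp(rng.normal(0.0, cfg.roi_heart_sd)))
    roi_noise = np.exp(rng.normal(0.0, cfg.roi_noise_sd, 12))
    intensities = cfg.roi_base_intensity * heart_factor * shape * roi_noise
    return RoiTable(heart_id, condition, intensities)


def generate_study(cfg: StudyConfig, seed: int, out_dir: str | Path) -> dict:
    """Write a complete on-disk study dataset and return its manifest.

    Layout (one directory per condition and heart)::

        out_dir/
          manifest.json
          <condition>/heart_<k>/
            rois.csv                      # heart_id, condition, roi_index, intensity
            diameters.csv
            images/img_<j>/{segments.csv, annotations.csv, meta.json}
            profiles/img_<j>_block_<b>.csv

    Regeneration with the same configuration and seed is byte-identical.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(seed)
    manifest: dict = {"seed": int(seed), "config": cfg.to_dict(), "hearts": []}
    heart_seeds = root_ss.spawn(sum(cfg.hearts.values()))
    idx = 0
    for condition in sorted(cfg.hearts):
        for k in range(cfg.hearts[condition]):
            heart_id = f"{condition}_heart{k:02d}"
            hdir = out / condition / f"heart_{k:02d}"
            (hdir / "images").mkdir(parents=True, exist_ok=True)
            (hdir / "profiles").mkdir(parents=True, exist_ok=True)
            ss = heart_seeds[idx]
            idx += 1
            roi_ss, *image_ss = ss.spawn(cfg.stacks_per_heart + 1)
            roi = generate_ventricle_map(condition, cfg,
                                         np.random.default_rng(roi_ss), heart_id)
            pd.DataFrame({
                "heart_id": heart_id,
                "condition": condition,
                "roi_index": np.arange(1, 13),
                "intensity": roi.intensities,
            }).to_csv(hdir / "rois.csv", index=False)

            pair_rows = []
            images = []
            for j, iss in enumerate(image_ss):
                bed_ss, cond_ss = iss.spawn(2)
                bed = generate_bed(cfg, np.random.default_rng(bed_ss))
                data = assign_condition(bed, condition, cfg,
                                        np.random.default_rng(cond_ss),
                                        heart_id=heart_id)
                img_dir = hdir / "images" / f"img_{j:02d}"
                save_graph(data.graph, img_dir)
                for b, prof in enumerate(data.profiles):
                    pd.DataFrame({
                        "arc_um": prof.arc_positions,
                        "intensity": prof.intensities,
                    }).to_csv(hdir / "profiles" / f"img_{j:02d}_block_{b:02d}.csv",
                              index=False)
                for pr in data.diameter_pairs:
                    pair_rows.append((pr.heart_id, pr.condition, pr.d_soma,
                                      pr.d_upstream, pr.blockage_associated))
                images.append({
                    "image_id": f"{heart_id}_img{j:02d}",
                    "path": str(img_dir.relative_to(out)),
                    "n_blockages": len(data.blockages),
                })
            pd.DataFrame(pair_rows, columns=[
                "heart_id", "condition", "d_soma_um", "d_upstream_um",
                "blockage_associated"]).to_csv(hdir / "diameters.csv", index=False)
            manifest["hearts"].append({
                "heart_id": heart_id,
                "condition": condition,
                "path": str(hdir.relative_to(out)),
                "images": images,
            })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
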