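"""Command-line pipeline: generate a synthetic study, analyse a dataset,
replay a manifest.

``periflow generate`` writes a seeded dataset; ``periflow analyse`` runs
the null model, blockage-distance, perfusion and diameter analyses over a
dataset directory and emits a JSON summary plus per-panel CSV tables;
``periflow replay`` regenerates a dataset byte-identically from its
manifest.  Corrected p-values are computed within each reported panel
family (the pairwise condition contrasts of a panel form one family).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .blockage_analysis import compare_to_null, observed_distances
from .geometry import load_graph
from .null_model import build_null_model
from .perfusion_diameter import (RoiTable, blocked_fraction, count_transect,
                                 diameter_ratio_analysis, normalize_rois,
                                 risk_zone_deficit)
from .stats import holm_correct
from .synthetic_data import StudyConfig, generate_study

log = logging.getLogger("periflow")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _correct_family(tests: dict) -> None:
    """Attach corrected p-values to a family of TestResults in place."""
    names = sorted(tests)
    if not names:
        return
    corrected = holm_correct([tests[n].p_raw for n in names])
    for n, pc in zip(names, corrected):
        tests[n].p_corrected = float(pc)


def load_dataset(data_dir: Path) -> dict:
    """Load a generated dataset back into analysis objects."""
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise click.ClickException(f"no manifest.json under {data_dir}")
    manifest = json.loads(manifest_path.read_text())
    graphs: dict[str, list] = {}
    rois: list[RoiTable] = []
    diameters = []
    for heart in manifest["hearts"]:
        cond = heart["condition"]
        hdir = data_dir / heart["path"]
        roidf = pd.read_csv(hdir / "rois.csv").sort_values("roi_index")
        rois.append(RoiTable(heart["heart_id"], cond,
                             roidf["intensity"].to_numpy()))
        ddf = pd.read_csv(hdir / "diameters.csv")
        diameters.append(ddf)
        for img in heart["images"]:
            graphs.setdefault(cond, []).append(
                (img["image_id"], load_graph(data_dir / img["path"])))
    return {
        "manifest": manifest,
        "graphs": graphs,
        "rois": rois,
        "diameters": pd.concat(diameters, ignore_index=True) if diameters else None,
    }


def analyse_dataset(data_dir: str | Path, out_dir: str | Path,
                    weighting: str = "blockages") -> dict:
    """Run the full analysis over a dataset directory; write summary.json
    and per-panel CSVs; return the summary dict."""
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    ds = load_dataset(data_dir)
    summary: dict = {"version": __version__, "inputs": str(data_dir)}

    # --- transect counting / blocked fraction ------------------------- #
    counts = []
    for cond, pairs in sorted(ds["graphs"].items()):
        for image_id, g in pairs:
            counts.append(count_transect(g, condition=cond, image_id=image_id))
    frac = blocked_fraction(counts)
    frac.to_csv(out_dir / "blocked_fraction.csv")
    from .stats import auto_compare
    bf_tests = {}
    conds = list(frac.index)
    per_image = pd.DataFrame(
        [(c.condition, 100.0 * c.fraction_blocked) for c in counts],
        columns=["condition", "pct"])
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            xa = per_image.loc[per_image.condition == a, "pct"].to_numpy()
            xb = per_image.loc[per_image.condition == b, "pct"].to_numpy()
            if xa.size >= 3 and xb.size >= 3:
                bf_tests[f"{a}_vs_{b}"] = auto_compare(xa, xb)
    _correct_family(bf_tests)
    summary["blocked_fraction"] = {
        "per_condition": frac.to_dict(orient="index"),
        "tests": {k: v.to_dict() for k, v in bf_tests.items()},
    }

    # --- perfusion maps ------------------------------------------------ #
    norm = normalize_rois(ds["rois"])
    norm.condition_means.to_csv(out_dir / "roi_condition_means.csv")
    deficit = risk_zone_deficit(norm)
    _correct_family(deficit["tests"])
    summary["perfusion"] = {
        "condition_means_roi7_10": deficit["condition_means"],
        "contrasts": deficit["contrasts"],
        "tests": {k: v.to_dict() for k, v in deficit["tests"].items()},
    }
    deficit["per_heart"].to_csv(out_dir / "risk_zone_per_heart.csv", index=False)

    # --- diameters ------------------------------------------------------ #
    ddf = ds["diameters"]
    if ddf is not None and len(ddf):
        from .perfusion_diameter import DiameterPair
        pairs = [DiameterPair(r.heart_id, r.condition, r.d_soma_um,
                              r.d_upstream_um, bool(r.blockage_associated))
                 for r in ddf.itertuples()]
        dia = diameter_ratio_analysis(pairs)
        _correct_family(dia["tests"])
        summary["diameters"] = {
            "per_condition": {
                c: {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                    for k, v in e.items()}
                for c, e in dia["per_condition"].items()},
            "contrasts": dia["contrasts"],
            "tests": {k: v.to_dict() for k, v in dia["tests"].items()},
        }

    # --- blockage distances vs null ------------------------------------ #
    summary["blockage_distances"] = {}
    for cond, pairs in sorted(ds["graphs"].items()):
        gs = [g for _, g in pairs]
        if not any(g.blockages for g in gs):
            continue
        try:
            obs = observed_distances(gs)
            null = build_null_model(gs, n_sample=obs.n, weighting=weighting)
        except ValueError as e:
            log.warning("distance analysis skipped for %s: %s", cond, e)
            continue
        res = compare_to_null(obs, null.pooled, n_sample=obs.n)
        summary["blockage_distances"][cond] = res
        null.pooled.to_csv(out_dir / f"null_cdf_{cond}.csv")
        x, p = obs.ecdf()
        pd.DataFrame({"distance_um": x, "cum_prob": p}).to_csv(
            out_dir / f"observed_cdf_{cond}.csv", index=False)

    summary["elapsed_s"] = round(time.perf_counter() - t0, 3)
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, default=_json_default))
    return summary


@click.group()
@click.version_option(__version__)
@click.option("-v", "--verbose", is_flag=True, help="log progress to stderr")
def main(verbose: bool) -> None:
    """Coronary capillary no-reflow analysis pipeline."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="StudyConfig as JSON/YAML/TOML (default: study defaults)")
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
def generate(config_path, out_dir, seed) -> None:
    """Generate a synthetic study dataset."""
    try:
        cfg = (StudyConfig.from_file(config_path) if config_path
               else StudyConfig())
        cfg.validate()
    except (ValueError, TypeError) as e:
        raise click.ClickException(f"bad config: {e}")
    t0 = time.perf_counter()
    manifest = generate_study(cfg, seed, out_dir)
    log.info("generated %d hearts in %.1f s", len(manifest["hearts"]),
             time.perf_counter() - t0)
    click.echo(f"dataset written to {out_dir} ({len(manifest['hearts'])} hearts)")


@main.command()
@click.argument("data_dir", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--weighting", type=click.Choice(["image", "blockages"]),
              default="blockages", show_default=True,
              help="null-model pooling across images")
def analyse(data_dir, out_dir, weighting) -> None:
    """Analyse a dataset directory end to end."""
    summary = analyse_dataset(data_dir, out_dir, weighting=weighting)
    click.echo(f"summary written to {Path(out_dir) / 'summary.json'} "
               f"({summary['elapsed_s']} s)")


@main.command()
@click.argument("manifest_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path(), required=True)
def replay(manifest_path, out_dir) -> None:
    """Regenerate a dataset from its manifest (byte-identical)."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = StudyConfig.from_dict(manifest["config"])
    generate_study(cfg, manifest["seed"], out_dir)
    click.echo(f"dataset replayed to {out_dir}")


if __name__ == "__main__":
    main()
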