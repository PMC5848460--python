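"""End-to-end orchestration: synth -> measure -> stats in one run directory."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Dict, Optional, Union

import pandas as pd

from . import __version__
from .config import (
    cohort_from_config,
    dump_config,
    stain_matrix_from_config,
    thresholds_from_config,
)
from .morphometry import MeasureConfig, measure_cohort
from .stain import RGBImage
from .stats import category_summary, comparisons_frame, ish_subgroup_comparison
from .synth import generate_cohort

log = logging.getLogger("magrule")

__all__ = ["run_all", "run_measure", "run_stats", "load_image"]


def load_image(path: Union[str, Path], pixel_scale: float) -> RGBImage:
    """Read an RGB raster (PNG or TIFF) from disk."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[..., :3]
    return RGBImage(pixels, pixel_scale)


def _measure_config(cfg: Dict[str, Any]) -> MeasureConfig:
    m = cfg["measure"]
    return MeasureConfig(
        k_rois=int(m["k_rois"]),
        roi_length_um=float(m["roi_length_um"]),
        step_px=float(m["step_px"]),
        min_peak_od=float(m["min_peak_od"]),
        psf_correction=bool(m["psf_correction"]),
        psf_sigma_um=float(cfg["specimen"]["psf_sigma_um"]),
    )


def run_measure(
    cfg: Dict[str, Any], images_dir: Union[str, Path], manifest: pd.DataFrame,
    out_dir: Union[str, Path],
) -> Dict[str, pd.DataFrame]:
    """Measure a rendered cohort from disk and write cells/specimens tables."""
    images_dir = Path(images_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pixel_scale = float(cfg["specimen"]["pixel_scale"])
    by_id = manifest.groupby("specimen_id")["image"].first()

    def provider(specimen_id: str) -> RGBImage:
        return load_image(images_dir / by_id[specimen_id], pixel_scale)

    profiles, cells, specimens = measure_cohort(
        manifest,
        provider,
        cfg=_measure_config(cfg),
        thresholds=thresholds_from_config(cfg),
        stain_matrix=stain_matrix_from_config(cfg),
    )
    profiles.to_csv(out_dir / "profiles.csv", index=False)
    cells.to_csv(out_dir / "cells.csv", index=False)
    specimens.to_csv(out_dir / "specimens.csv", index=False)
    return {"profiles": profiles, "cells": cells, "specimens": specimens}


def run_stats(
    cfg: Dict[str, Any],
    cells: pd.DataFrame,
    specimens: pd.DataFrame,
    out_dir: Union[str, Path],
    make_plots: bool = False,
) -> None:
    """Write summary/comparison/correlation tables (and optional plots)."""
    from .stats import pearson_r

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = category_summary(cells, specimens, cfg["stats"]["bin_width_um"])
    summary.summary.to_csv(out_dir / "summary.csv", index=False)
    summary.cell_width_hist.to_csv(out_dir / "cell_width_hist.csv", index=False)
    summary.specimen_width_hist.to_csv(
        out_dir / "specimen_width_hist.csv", index=False
    )
    comps = pd.concat(
        [
            comparisons_frame(summary.pairwise_width, "width"),
            comparisons_frame(summary.pairwise_intensity, "intensity"),
        ],
        ignore_index=True,
    )

    pooled = cells[cells["score_preset"].isin(["1+", "2+"])].dropna(
        subset=["mean_width_um", "mean_intensity_pct"]
    )
    corr_rows = []
    if len(pooled) >= 3:
        res = pearson_r(
            pooled["mean_width_um"], pooled["mean_intensity_pct"], "1+ and 2+ pooled"
        )
        corr_rows.append(
            {"subset": res.subset, "n": res.n, "pearson_r": res.pearson_r}
        )
    pd.DataFrame(corr_rows).to_csv(out_dir / "correlation.csv", index=False)

    labels = (
        specimens["ish_label"].astype(str).value_counts()
        if "ish_label" in specimens.columns
        else {}
    )
    if min(labels.get("positive", 0), labels.get("negative", 0)) >= 2:
        ish = ish_subgroup_comparison(specimens)
        comps = pd.concat(
            [
                comps,
                comparisons_frame([ish["width"]], "ish_width"),
                comparisons_frame([ish["intensity"]], "ish_intensity"),
            ],
            ignore_index=True,
        )
    comps.to_csv(out_dir / "comparisons.csv", index=False)

    if make_plots:
        _plot_report(summary, pooled, out_dir)


def _plot_report(summary, pooled: pd.DataFrame, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    h = summary.cell_width_hist
    axes[0].bar(h["bin_left_um"], h["count"], width=0.1, align="edge")
    axes[0].set_xlabel("per-cell width (um)")
    axes[0].set_ylabel("count")
    if len(pooled):
        axes[1].scatter(
            pooled["mean_width_um"], pooled["mean_intensity_pct"], s=6, alpha=0.5
        )
    axes[1].set_xlabel("width (um)")
    axes[1].set_ylabel("intensity (%)")
    fig.tight_layout()
    fig.savefig(out_dir / "report.png", dpi=150)
    plt.close(fig)


def run_in_memory(
    cohort,
    cfg: Optional[Dict[str, Any]] = None,
) -> Dict[str, pd.DataFrame]:
    """Render and measure a cohort without touching the filesystem.

    Streams one specimen at a time (render, deconvolve, measure, discard),
    so memory stays flat for large cohorts.  Returns the manifest, profile,
    cell and specimen tables.
    """
    from .config import DEFAULT_CONFIG
    from .morphometry import measure_specimen
    from .synth import iter_cohort, truths_to_frame

    if cfg is None:
        cfg = DEFAULT_CONFIG
    mcfg = _measure_config(cfg)
    thresholds = thresholds_from_config(cfg)
    stain_matrix = stain_matrix_from_config(cfg)
    manifest_frames, profile_frames = [], []
    cell_rows, specimen_rows = [], []
    for specimen_id, scfg, image, truths in iter_cohort(cohort, stain_matrix):
        manifest_frames.append(truths_to_frame(specimen_id, scfg, truths))
        cms, summary, profiles = measure_specimen(
            image, truths, specimen_id, mcfg, thresholds, stain_matrix,
            roi_seed=scfg.seed,
        )
        profile_frames.append(profiles)
        truth_by_id = {t.cell_id: t for t in truths}
        for cm in cms:
            cell_rows.append(
                {
                    "specimen_id": specimen_id,
                    "cell_id": cm.cell_id,
                    "mean_width_um": cm.mean_width_um,
                    "mean_intensity_pct": cm.mean_intensity_pct,
                    "n_valid_rois": cm.n_valid_rois,
                    "true_width_um": truth_by_id[cm.cell_id].width_um,
                    "true_amplitude_od": truth_by_id[cm.cell_id].amplitude_od,
                    "score_preset": scfg.preset.score.label,
                    "ish_label": scfg.ish_label or "none",
                    "seed": scfg.seed,
                }
            )
        specimen_rows.append(
            {
                "specimen_id": specimen_id,
                "n_cells": summary.n_cells,
                "mean_width_um": summary.mean_width_um,
                "sd_width_um": summary.sd_width_um,
                "mean_intensity_pct": summary.mean_intensity_pct,
                "assigned_score": summary.assigned_score.label,
                "score_preset": scfg.preset.score.label,
                "ish_label": scfg.ish_label or "none",
                "seed": scfg.seed,
            }
        )
    return {
        "manifest": pd.concat(manifest_frames, ignore_index=True),
        "profiles": pd.concat(profile_frames, ignore_index=True),
        "cells": pd.DataFrame(cell_rows),
        "specimens": pd.DataFrame(specimen_rows),
    }


def run_all(
    cfg: Dict[str, Any],
    out_dir: Union[str, Path],
    master_seed: Optional[int] = None,
    make_plots: bool = False,
) -> Dict[str, pd.DataFrame]:
    """Full pipeline: render cohort, measure it, compute statistics.

    Creates ``out_dir/{images,tables,report}``, records the exact config and
    software version used, and is deterministic for a fixed master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if master_seed is not None:
        cfg = {**cfg, "seed": int(master_seed)}
    dump_config({**cfg, "version": __version__}, out_dir / "config_used.yaml")

    log.info("rendering cohort (seed=%s)", cfg["seed"])
    cohort = cohort_from_config(cfg)
    manifest = generate_cohort(
        cohort,
        out_dir / "images",
        image_format=cfg["cohort"]["image_format"],
        stain_matrix=stain_matrix_from_config(cfg),
    )
    log.info("measuring %d specimens", manifest["specimen_id"].nunique())
    tables = run_measure(cfg, out_dir / "images", manifest, out_dir / "tables")
    log.info("computing statistics")
    run_stats(
        cfg, tables["cells"], tables["specimens"], out_dir / "report", make_plots
    )
    tables["manifest"] = manifest
    return tables
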