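"""End-to-end orchestration: stack → segmentation → readouts → tracking →
motility, with CSV/JSON outputs and a run log.

Thresholding strategy: by default one global threshold per channel is
derived from the whole stack (Otsu on a frame subsample, floored at a
robust background guard of median + 5 robust SD). A global value keeps
sparse planes — z-sections beyond the tumoroid, or a PI channel with no
killing — from being thresholded into noise, which per-plane Otsu would
do. A numeric ``threshold`` in the config overrides this per channel.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from tumotrack.config import PipelineConfig
from tumotrack.scenario import ValidationError
from tumotrack.segmentation import (
    Plane,
    PlaneObjects,
    SegmentationParams,
    build_tumoroid_mask,
    mask_tcells,
    segment_objects,
)
from tumotrack.quantify import PlaneCounts, build_time_series, plane_counts
from tumotrack.stack import ImageStack
from tumotrack.tracking import detect_3d, filter_tracks, link, trajectories_to_frame
from tumotrack.motility import (
    fit_trajectory,
    fits_to_frame,
    summarize_population,
)


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run computed."""

    time_series: object
    plane_table: pd.DataFrame
    trajectories: list
    fits: list
    population: object
    thresholds: Dict[str, float]
    warnings: List[str] = field(default_factory=list)
    paths: Dict[str, Path] = field(default_factory=dict)


def auto_threshold(channel_data: np.ndarray, max_sample_frames: int = 8) -> float:
    """Global per-channel threshold: Otsu over a frame subsample, floored
    at median + 5·(1.4826·MAD) so an object-free channel does not get
    thresholded inside its noise floor."""
    n_t = channel_data.shape[0]
    step = max(1, n_t // max_sample_frames)
    sample = channel_data[::step]
    med = float(np.median(sample))
    mad = float(np.median(np.abs(sample - med)))
    guard = med + 5.0 * 1.4826 * mad
    if guard == med:
        # noise-free channel: keep the threshold strictly above background
        guard = med + max(1e-3 * abs(med), 1e-6)
    if sample.max() == sample.min():
        return guard
    return max(float(threshold_otsu(sample)), guard)


def segment_stack(stack: ImageStack, config: PipelineConfig
                  ) -> tuple[List[PlaneCounts], pd.DataFrame, Dict[str, float]]:
    """Per-plane segmentation, masking and counting over the whole stack."""
    thresholds: Dict[str, float] = {}
    for role in ("nuclei", "pi", "tcell"):
        if config.threshold == "otsu":
            thresholds[role] = auto_threshold(stack.channel(role))
        else:
            thresholds[role] = float(config.threshold)
    counts: List[PlaneCounts] = []
    rows = []
    for t in range(stack.n_frames):
        nuclei_by_plane: Dict[int, PlaneObjects] = {}
        pi_by_plane: Dict[int, PlaneObjects] = {}
        tcell_by_plane: Dict[int, PlaneObjects] = {}
        for role, store in (("nuclei", nuclei_by_plane), ("pi", pi_by_plane),
                            ("tcell", tcell_by_plane)):
            params = SegmentationParams(
                smoothing_sigma_um=config.smoothing_sigma_um,
                threshold=thresholds[role],
                min_area_um2=config.min_area_um2,
                max_area_um2=config.max_area_um2,
                split_touching=config.split_touching)
            for z in range(stack.n_planes):
                plane = Plane(intensity=stack.plane(role, t, z), channel=role,
                              z=z, t=t, pixel_size=stack.lateral_pixel_size)
                store[z] = segment_objects(plane, params)
        mask = build_tumoroid_mask(nuclei_by_plane,
                                   closing_radius_um=config.closing_radius_um)
        for z in range(stack.n_planes):
            inside, _outside = mask_tcells(tcell_by_plane[z], mask)
            counts.append(plane_counts(nuclei_by_plane[z], pi_by_plane[z], inside))
            for role, objs in (("nucleus", nuclei_by_plane[z]),
                               ("pi", pi_by_plane[z]),
                               ("tcell_inside", inside)):
                for r in objs.table.itertuples(index=False):
                    rows.append((t, z, role, int(r.label), r.x_um, r.y_um,
                                 r.area_um2))
    table = pd.DataFrame(
        rows, columns=["t", "z", "class", "label", "x_um", "y_um", "area_um2"])
    return counts, table, thresholds


def track_stack(stack: ImageStack, config: PipelineConfig,
                threshold: float | None = None) -> list:
    """3D T-cell detection and linking over all frames."""
    if threshold is None:
        if config.tcell_threshold == "otsu":
            threshold = auto_threshold(stack.channel("tcell"))
        else:
            threshold = float(config.tcell_threshold)
    detections = []
    for t in range(stack.n_frames):
        detections.append(detect_3d(
            stack.volume("tcell", t), threshold,
            lateral_pixel_size=stack.lateral_pixel_size,
            z_step=stack.z_step, t=t * stack.frame_interval,
            volume_gate=(config.volume_gate_low_um3,
                         config.volume_gate_high_um3)))
    trajectories = link(detections, max_displacement=config.max_displacement_um)
    return filter_tracks(trajectories, min_duration_h=config.min_duration_h)


def run_pipeline(config: PipelineConfig, stack: ImageStack | None = None
                 ) -> PipelineResult:
    """Run the full analysis and write all outputs under
    ``config.output_dir``. Idempotent for fixed inputs, config and seed."""
    t_start = time.time()
    if stack is None:
        if not config.input_stack:
            raise ValidationError("no input stack: set input_stack or pass one")
        stack = ImageStack.read(config.input_stack)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_list: List[str] = []

    counts, plane_table, thresholds = segment_stack(stack, config)
    series = build_time_series(counts)
    if series.zero_denominator.any():
        warnings_list.append(
            f"{int(series.zero_denominator.sum())} timepoints had no nuclei "
            "(killing fraction reported as 0 with zero-denominator flag)")

    trajectories = track_stack(stack, config,
                               threshold=thresholds.get("tcell"))
    fits = []
    for traj in trajectories:
        try:
            fits.append(fit_trajectory(traj, max_lag_h=config.max_lag_h,
                                       t_d=config.t_d_h))
        except ValidationError:
            continue  # too short for a 3-lag fit after capping
    population = summarize_population(fits) if fits else None
    if population and population.n_undefined:
        warnings_list.append(
            f"{population.n_undefined} stationary fits had undefined f_D")

    paths = {
        "time_series": out / "time_series.csv",
        "plane_objects": out / "plane_objects.csv",
        "trajectories": out / "trajectories.csv",
        "fits": out / "cell_fits.csv",
        "summary": out / "summary.json",
        "log": out / "run_log.json",
    }
    series.to_frame().to_csv(paths["time_series"], index=False)
    plane_table.to_csv(paths["plane_objects"], index=False)
    trajectories_to_frame(trajectories).to_csv(paths["trajectories"], index=False)
    fits_to_frame(fits).to_csv(paths["fits"], index=False)
    summary = {
        "n_frames": stack.n_frames,
        "n_trajectories": len(trajectories),
        "n_fits": len(fits),
        "thresholds": thresholds,
        "population": None if population is None else {
            "median": population.median, "sd": population.sd,
            "n": population.n, "n_undefined": population.n_undefined},
        "warnings": warnings_list,
    }
    paths["summary"].write_text(json.dumps(summary, indent=2))
    from tumotrack import __version__
    log = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 2),
        "default_provenance": PipelineConfig.DEFAULT_PROVENANCE,
    }
    paths["log"].write_text(json.dumps(log, indent=2))
    return PipelineResult(time_series=series, plane_table=plane_table,
                          trajectories=trajectories, fits=fits,
                          population=population, thresholds=thresholds,
                          warnings=warnings_list, paths=paths)
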