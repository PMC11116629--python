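"""Seeded cohort simulation: videos on disk + plate metadata + ground truth.

One BFP and one mCherry stack are written per larva per timepoint, named
``{well}_{timepoint}_{channel}.tif``.  Per-larva biology (diastolic size,
heart rate, contraction phase, distractor layout) is drawn from seed-derived
substreams so the output is bit-reproducible for a given (scenario, seed)
and independent of iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..video import VideoStack, write_video
from .heart import CHANNELS, HeartModel, draw_distractor_positions, heart_geometry_at, render_video
from .scenario import Scenario

__all__ = ["CohortResult", "simulate_cohort", "well_name"]

_ROWS = "ABCDEFGH"


def well_name(index: int) -> str:
    """Row-major 96-well coordinate (A1..H12) for larva ``index``."""
    if not 0 <= index < 96:
        raise ValueError("a single 96-well plate holds at most 96 larvae")
    return f"{_ROWS[index // 12]}{index % 12 + 1}"


@dataclass
class CohortResult:
    out_dir: Path
    metadata: pd.DataFrame
    ground_truth: pd.DataFrame
    metadata_csv: Path
    ground_truth_csv: Path


def _larva_model(scenario: Scenario, group_idx: int, larva_idx: int, seed: int) -> tuple[HeartModel, float]:
    """Per-larva base heart model (at ratio 1) and its area scale factor."""
    rng = np.random.default_rng([seed, 1000 + group_idx, larva_idx])
    base = scenario.heart
    # Lognormal area factor with mean 1 and CV size_cv.
    if scenario.size_cv > 0:
        sigma = math.sqrt(math.log(1.0 + scenario.size_cv**2))
        area_factor = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
    else:
        area_factor = 1.0
    if scenario.heart_rate_cv > 0:
        sr = math.sqrt(math.log(1.0 + scenario.heart_rate_cv**2))
        rate = base.heart_rate_bpm * float(np.exp(rng.normal(-0.5 * sr**2, sr)))
    else:
        rate = base.heart_rate_bpm
    phase = float(rng.uniform(0.0, 2.0 * math.pi))
    axis_scale = math.sqrt(area_factor)
    a0, b0 = base.diastolic_semi_axes
    model = base.with_(
        diastolic_semi_axes=(a0 * axis_scale, b0 * axis_scale),
        heart_rate_bpm=rate,
        phase=phase,
    )
    return model, area_factor


def _true_areas(model: HeartModel, times: np.ndarray, pixel_size_um: float) -> dict[str, float]:
    """Analytic compartment areas at the discrete-frame systole, in um^2."""
    a, b = heart_geometry_at(model, times)
    prod = a * b
    i_sys = int(np.argmin(prod))
    i_dia = int(np.argmax(prod))
    px2 = pixel_size_um**2
    ellipse_sys = math.pi * prod[i_sys]
    bfp_px = ellipse_sys * model.bfp_area_fraction if model.recombined else ellipse_sys * model.bfp_area_fraction
    mch_px = ellipse_sys * model.fhf_area_fraction * model.mcherry_survival if model.recombined else 0.0
    return {
        "systole_frame": i_sys,
        "true_bfp_area_um2": bfp_px * px2,
        "true_mcherry_area_um2": mch_px * px2,
        "true_dmax_px": 2.0 * a[i_dia],
        "true_dmin_px": 2.0 * a[i_sys],
    }


def simulate_cohort(scenario: Scenario, out_dir: str | Path, seed: int | None = None, force: bool = False) -> CohortResult:
    """Generate the full cohort and write it under ``out_dir``.

    Refuses to write into an existing non-empty directory unless ``force``.
    Returns the plate metadata and ground-truth tables (also written as CSV).
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"output directory {out_dir} is not empty (use force=True to overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = scenario.seed if seed is None else int(seed)

    imaging = scenario.imaging
    times = np.arange(imaging.n_frames) / imaging.frame_rate_fps
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []

    larva_offset = 0
    for gi, group in enumerate(scenario.groups):
        ratios = group.ratio_trajectory(scenario.timepoints)
        for li in range(group.n_larvae):
            well = well_name(larva_offset + li)
            base_model, area_factor = _larva_model(scenario, gi, li, seed)
            for ti, tp in enumerate(scenario.timepoints):
                model = base_model.with_(
                    recombined=group.recombined,
                    bfp_area_fraction=ratios[tp] if group.recombined else 1.0,
                    mcherry_survival=group.ablation_survival_fraction if group.recombined else 1.0,
                )
                rng = np.random.default_rng([seed, gi, li, ti])
                distractors = (
                    draw_distractor_positions(model, imaging.frame_shape, scenario.noise.n_distractors, rng)
                    if scenario.noise.n_distractors > 0
                    else None
                )
                for channel in CHANNELS:
                    frames = render_video(
                        model,
                        times,
                        channel,
                        frame_shape=imaging.frame_shape,
                        noise=scenario.noise,
                        rng=rng,
                        distractor_positions=distractors,
                    )
                    path = out_dir / f"{well}_{tp}_{channel}.tif"
                    write_video(
                        path,
                        VideoStack(frames, imaging.pixel_size_um, imaging.frame_rate_fps, channel=channel),
                    )
                    meta_rows.append(
                        {
                            "well": well,
                            "group": group.name,
                            "timepoint": tp,
                            "channel": channel,
                            "path": path.name,
                            "pixel_size_um": imaging.pixel_size_um,
                            "frame_rate_fps": imaging.frame_rate_fps,
                        }
                    )
                truth = _true_areas(model, times, imaging.pixel_size_um)
                truth_rows.append(
                    {
                        "well": well,
                        "group": group.name,
                        "timepoint": tp,
                        "true_heart_rate_bpm": model.heart_rate_bpm,
                        "area_factor": area_factor,
                        **truth,
                    }
                )
        larva_offset += group.n_larvae

    metadata = pd.DataFrame(meta_rows)
    ground_truth = pd.DataFrame(truth_rows)
    metadata_csv = out_dir / "plate.csv"
    ground_truth_csv = out_dir / "ground_truth.csv"
    metadata.to_csv(metadata_csv, index=False)
    ground_truth.to_csv(ground_truth_csv, index=False)
    return CohortResult(out_dir, metadata, ground_truth, metadata_csv, ground_truth_csv)
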