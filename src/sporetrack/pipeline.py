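"""End-to-end runs: simulate → track → analyze, with config and manifests.

Each stage reads/writes plain files (TIFF stacks in; CSV/JSON/PNG out) and
records a run manifest (config snapshot, input hashes, per-stage row counts,
version, wall-clock) so a run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .detect import detect_stack, normalize_stack
from .geometry import geometry_table, segment_cells
from .motion import (
    MIN_TRACKS_COMPLIANT,
    analyze_tracks,
    cumulated_distance,
    distance_from_origin,
)
from .simulate import PRESETS, simulate_preset
from .tracking import (
    DEFAULT_MAX_STEP_UM,
    link_tracks,
    tracks_from_table,
    tracks_table,
)


@dataclass
class PipelineConfig:
    """All knobs of the standard pipeline, with physical units.

    Defaults follow the synthetic presets: 0.1 µm/px, 0.5 min frame
    interval, 3σ detection, PSF-FWHM minimum separation, 0.45 µm linking
    gate and MSD fitting over the first half of lags with the 15-track
    ensemble minimum.
    """

    pixel_size: float = 0.1            # µm/px
    frame_interval: float = 0.5        # min
    psf_sigma_um: float = 0.13         # µm
    k_sigma: float = 3.0
    min_separation_px: float | None = None
    max_step_um: float = DEFAULT_MAX_STEP_UM
    max_gap_frames: int = 0
    min_track_length: int = 3
    max_lag_fraction: float = 0.5
    min_tracks: int = MIN_TRACKS_COMPLIANT
    min_area_px: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "psf_sigma_um", "k_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig,
                    inputs: dict[str, str], counts: dict[str, int],
                    elapsed: float) -> dict:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config.to_dict(),
        "inputs": inputs,
        "row_counts": counts,
        "wall_clock_s": round(elapsed, 3),
    }
    with open(out_dir / f"{stage}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_simulate(
    config: PipelineConfig,
    preset: str,
    out_dir: str | Path,
    n_cells: int = 4,
) -> dict:
    """Generate one preset scene and write stack + truth + manifest."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid: {sorted(PRESETS)}")
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = simulate_preset(preset, seed=config.seed, n_cells=n_cells)
    tifffile.imwrite(out / f"{preset}_stack.tif", scene.stack)
    truth = scene.truth_table()
    truth.to_csv(out / f"{preset}_truth.csv", index=False, float_format="%.9g")
    return _write_manifest(
        out, "simulate", config, {},
        {"truth_rows": len(truth), "n_frames": int(scene.stack.shape[0])},
        time.perf_counter() - t0,
    )


def track_stack(
    stack: np.ndarray, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """In-memory segment → normalize → detect → link.

    Segmentation runs on the time-median frame (cells are stationary in the
    chamber); returns (geometry, detections, tracks) tables.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    # median over time suppresses the moving foci, leaving cell bodies only
    median_frame = np.median(stack, axis=0)
    geometries = segment_cells(
        median_frame, pixel_size=config.pixel_size, min_area_px=config.min_area_px
    )
    geo = geometry_table(geometries)
    if not geometries:
        empty_det = detect_stack(np.empty((0, 1, 1)), [], config.frame_interval)
        return geo, empty_det, tracks_table([])
    normalized, _ = normalize_stack(stack)
    detections = detect_stack(
        normalized,
        geometries,
        dt=config.frame_interval,
        k_sigma=config.k_sigma,
        min_separation_px=config.min_separation_px,
        psf_sigma_px=config.psf_sigma_um / config.pixel_size,
    )
    tracks = link_tracks(
        detections,
        geometries,
        pixel_size=config.pixel_size,
        dt=config.frame_interval,
        max_step=config.max_step_um,
        max_gap_frames=config.max_gap_frames,
        min_length=config.min_track_length,
    )
    return geo, detections, tracks_table(tracks)


def run_track(
    config: PipelineConfig, stack_path: str | Path, out_dir: str | Path
) -> dict:
    """File-based tracking stage: TIFF in, geometry/detections/tracks CSVs out."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack_path = Path(stack_path)
    try:
        stack = tifffile.imread(stack_path)
    except Exception as exc:
        raise ValueError(f"cannot read TIFF stack {stack_path}: {exc}") from exc
    geo, detections, tracks = track_stack(stack, config)
    geo.to_csv(out / "geometry.csv", index=False)
    detections.to_csv(out / "detections.csv", index=False)
    tracks.to_csv(out / "tracks.csv", index=False)
    if geo.empty:
        warnings.warn("no cells found in stack; outputs are empty", stacklevel=2)
    return _write_manifest(
        out, "track", config, {stack_path.name: _sha256(stack_path)},
        {"cells": len(geo), "detections": len(detections), "track_rows": len(tracks)},
        time.perf_counter() - t0,
    )


def analyze_tracks_table(
    tracks: pd.DataFrame, config: PipelineConfig
) -> dict:
    """In-memory motion analysis of a tracks table.

    Returns a report dict with the ensemble MSD curve, the (v, D, α, regime)
    fit, pooled speeds, per-track statistics, and a ``below_min_tracks``
    warning flag when fewer than ``config.min_tracks`` trajectories
    contribute.
    """
    track_objs = tracks_from_table(tracks)
    curve, est, speeds = analyze_tracks(
        track_objs,
        max_lag_fraction=config.max_lag_fraction,
        min_track_length=config.min_track_length,
    )
    per_track = []
    for t in track_objs:
        if len(t) < 2:
            continue
        dfo = distance_from_origin(t)
        cum = cumulated_distance(t)
        per_track.append(
            {
                "track_id": t.track_id,
                "cell_id": t.cell_id,
                "n_frames": len(t),
                "duration_min": float(t.times[-1] - t.times[0]),
                "final_distance_from_origin_um": float(dfo[-1]),
                "cumulated_distance_um": float(cum[-1]),
                "clamped_fraction": t.clamped_fraction,
            }
        )
    return {
        "n_tracks": curve.n_tracks,
        "below_min_tracks": curve.n_tracks < config.min_tracks,
        "v_um_per_min": est.v,
        "D_um2_per_min": est.D,
        "alpha": est.alpha,
        "regime": est.regime_call,
        "fit_residual": est.residual,
        "median_speed_um_per_min": float(np.median(speeds)),
        "speeds": speeds,
        "msd_curve": curve,
        "per_track": pd.DataFrame(per_track),
    }


def run_analyze(
    config: PipelineConfig, tracks_path: str | Path, out_dir: str | Path,
    plots: bool = True,
) -> dict:
    """File-based analysis stage: tracks CSV in, motion report + plots out."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks_path = Path(tracks_path)
    tracks = pd.read_csv(tracks_path)
    report = analyze_tracks_table(tracks, config)
    curve = report["msd_curve"]
    pd.DataFrame(
        {"lag_min": curve.lag_times, "msd_um2": curve.msd, "n_pairs": curve.n_pairs}
    ).to_csv(out / "msd.csv", index=False)
    pd.DataFrame({"speed_um_per_min": report["speeds"]}).to_csv(
        out / "speeds.csv", index=False
    )
    report["per_track"].to_csv(out / "per_track.csv", index=False)
    summary = {
        k: report[k]
        for k in (
            "n_tracks", "below_min_tracks", "v_um_per_min", "D_um2_per_min",
            "alpha", "regime", "fit_residual", "median_speed_um_per_min",
        )
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    if plots:
        _write_plots(out, report)
    _write_manifest(
        out, "analyze", config, {tracks_path.name: _sha256(tracks_path)},
        {"tracks": report["n_tracks"], "speeds": len(report["speeds"])},
        time.perf_counter() - t0,
    )
    return summary


def _write_plots(out: Path, report: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = report["msd_curve"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(report["speeds"], bins=30, color="steelblue")
    ax.set_xlabel("instantaneous speed (µm/min)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(out / "speed_histogram.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve.lag_times, curve.msd, "o", ms=3, label="ensemble MSD")
    t = curve.lag_times
    ax.plot(
        t,
        4 * report["D_um2_per_min"] * t + report["v_um_per_min"] ** 2 * t**2,
        "-",
        label=f"4Dt + v²t² (v={report['v_um_per_min']:.3f}, D={report['D_um2_per_min']:.4f})",
    )
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("MSD (µm²)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "msd_fit.png", dpi=120)
    plt.close(fig)
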