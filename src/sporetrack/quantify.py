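"""Non-tracking quantifications: intensity ratios, stain areas, foci counts,
kymographs.

These reproduce the single-cell fluorescence measurements that accompany
surface tracking: per-cell background-corrected intensity time courses
normalized to each cell's maximum (induction kinetics), the ratio of
lectin-stain area to cell area (compactness of the spore coat — loosely
attached coats spread beyond the cell outline), foci-per-cell count
distributions, and kymographs obtained by reslicing a stack along a cluster
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .geometry import CellGeometry


@dataclass
class IntensityTimecourse:
    cell_id: int
    times: np.ndarray          # min
    intensity: np.ndarray      # background-corrected mean counts (NaN = absent)
    ratio: np.ndarray          # intensity / max over the course, in [0, 1]


@dataclass
class AreaRatioRecord:
    cell_id: int
    stain_area_px2: float
    cell_area_px2: float
    ratio: float
    beyond_mask: bool          # True when stain extends past the cell outline


@dataclass
class Kymograph:
    data: np.ndarray           # (n_frames, n_samples)
    path: np.ndarray           # (M, 2) x,y polyline, arc-length resampled
    width_px: int


def rasterize_contour(geometry: CellGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of a cell's spline contour."""
    pts = geometry.contour.points
    rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def intensity_ratio_timecourse(
    stack: np.ndarray,
    geometries: list[CellGeometry],
    background: np.ndarray | tuple[slice, slice],
    times: np.ndarray | None = None,
) -> tuple[pd.DataFrame, list[IntensityTimecourse]]:
    """Per-cell background-corrected intensity ratios over time.

    ``background`` is either a boolean mask of reference pixels (e.g.
    non-expressing cells) or a pair of slices selecting a background region.
    Per frame and cell: mean masked intensity minus mean background; each
    cell's course is normalized to its own maximum so ratios lie in [0, 1]
    (negative corrected values clip to 0).  A cell absent at a time point
    (empty mask) yields NaN and is excluded from the per-time mean; the
    summary table reports mean, SD and n over cells per time.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    n_frames = stack.shape[0]
    times = np.arange(n_frames, dtype=float) if times is None else np.asarray(times)
    if isinstance(background, tuple):
        bg_mask = np.zeros(stack.shape[1:], dtype=bool)
        bg_mask[background] = True
    else:
        bg_mask = np.asarray(background, dtype=bool)
    if not bg_mask.any():
        raise ValueError("empty background reference")

    courses: list[IntensityTimecourse] = []
    for g in geometries:
        mask = rasterize_contour(g, stack.shape[1:])
        vals = np.full(n_frames, np.nan)
        for f in range(n_frames):
            if mask.any():
                vals[f] = stack[f][mask].mean() - stack[f][bg_mask].mean()
        finite = np.isfinite(vals)
        ratio = np.full(n_frames, np.nan)
        if finite.any() and np.nanmax(vals) > 0:
            ratio[finite] = np.clip(vals[finite] / np.nanmax(vals), 0.0, 1.0)
        courses.append(
            IntensityTimecourse(cell_id=g.cell_id, times=times, intensity=vals, ratio=ratio)
        )

    ratios = np.vstack([c.ratio for c in courses]) if courses else np.empty((0, n_frames))
    summary = pd.DataFrame(
        {
            "time_min": times,
            "mean_ratio": np.nanmean(ratios, axis=0) if len(courses) else np.nan,
            "sd_ratio": np.nanstd(ratios, axis=0) if len(courses) else np.nan,
            "n_cells": np.sum(np.isfinite(ratios), axis=0) if len(courses) else 0,
        }
    )
    return summary, courses


BEYOND_MASK_TOLERANCE = 0.05   # stain outside the cell > 5% of cell area → flag


def stain_area_ratio(
    stain_image: np.ndarray,
    geometry: CellGeometry,
    background: float | None = None,
) -> AreaRatioRecord:
    """Ratio of specific-stain area to cell area for one cell.

    The stain channel is background-subtracted (median outside the cell by
    default), Otsu-thresholded, and restricted to connected components that
    touch the cell mask (a loosely attached coat halo still counts, and
    pushes the ratio above 1 with ``beyond_mask`` set).
    """
    img = np.asarray(stain_image, dtype=float)
    mask = rasterize_contour(geometry, img.shape)
    if not mask.any():
        raise ValueError("cell mask is empty")
    if background is None:
        background = float(np.median(img[~mask])) if (~mask).any() else 0.0
    sub = img - background
    pos = sub[sub > 0]
    if pos.size == 0 or np.ptp(sub) == 0:
        return AreaRatioRecord(geometry.cell_id, 0.0, float(mask.sum()), 0.0, False)
    thr = threshold_otsu(sub)
    stain_mask = sub > thr
    labels, n = ndimage.label(stain_mask)
    keep = np.zeros_like(stain_mask)
    for lab in range(1, n + 1):
        comp = labels == lab
        if (comp & mask).any():
            keep |= comp
    cell_area = float(mask.sum())
    stain_area = float(keep.sum())
    outside = float((keep & ~mask).sum())
    return AreaRatioRecord(
        cell_id=geometry.cell_id,
        stain_area_px2=stain_area,
        cell_area_px2=cell_area,
        ratio=stain_area / cell_area,
        beyond_mask=outside > BEYOND_MASK_TOLERANCE * cell_area,
    )


def count_foci_per_cell(
    detections: pd.DataFrame, geometries: list[CellGeometry]
) -> tuple[pd.DataFrame, dict]:
    """Foci counts per cell with distribution summary.

    ``detections`` should come from a single frame (or a max projection);
    cells with no detections count as zero.  The summary reports mean, SD,
    max and the fraction of cells with at least one focus.
    """
    counts = {g.cell_id: 0 for g in geometries}
    if len(detections):
        for cid, n in detections.groupby("cell_id").size().items():
            if cid in counts:
                counts[cid] = int(n)
    table = pd.DataFrame(
        {"cell_id": list(counts), "n_foci": list(counts.values())}
    ).sort_values("cell_id", ignore_index=True)
    values = table["n_foci"].to_numpy()
    summary = {
        "n_cells": int(len(values)),
        "mean": float(values.mean()) if len(values) else 0.0,
        "sd": float(values.std()) if len(values) else 0.0,
        "max": int(values.max()) if len(values) else 0,
        "fraction_with_foci": float((values >= 1).mean()) if len(values) else 0.0,
    }
    return table, summary


def _resample_path(path: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Arc-length resampling of an (M, 2) polyline at ``spacing`` px."""
    path = np.asarray(path, dtype=float)
    seg = np.hypot(*np.diff(path, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return path[:1]
    n = max(int(np.floor(total / spacing)) + 1, 2)
    si = np.linspace(0, total, n)
    x = np.interp(si, s, path[:, 0])
    y = np.interp(si, s, path[:, 1])
    return np.column_stack([x, y])


def make_kymograph(
    stack: np.ndarray, path: np.ndarray, width_px: int = 3
) -> Kymograph:
    """Reslice a stack along a path: rows = time, columns = arc position.

    The polyline is resampled at 1 px arc-length spacing; at each sample the
    intensity is bilinearly interpolated and averaged over ``width_px``
    offsets along the local normal.  Raises if any sample leaves the image.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    pts = _resample_path(path)
    if len(pts) < 2:
        raise ValueError("path is degenerate (zero length)")
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    offsets = np.arange(width_px) - (width_px - 1) / 2.0

    h, w = stack.shape[1:]
    all_x = pts[:, 0][None, :] + offsets[:, None] * normal[:, 0][None, :]
    all_y = pts[:, 1][None, :] + offsets[:, None] * normal[:, 1][None, :]
    if (all_x < 0).any() or (all_x > w - 1).any() or (all_y < 0).any() or (all_y > h - 1).any():
        raise ValueError("kymograph path (with width) exits the image")

    data = np.empty((stack.shape[0], len(pts)))
    coords = np.stack([all_y.ravel(), all_x.ravel()])
    for f, frame in enumerate(stack):
        samples = ndimage.map_coordinates(frame, coords, order=1)
        data[f] = samples.reshape(len(offsets), len(pts)).mean(axis=0)
    return Kymograph(data=data, path=pts, width_px=width_px)


def ridge_path(stack: np.ndarray, smoothing_sigma: float = 1.0) -> np.ndarray:
    """Derive a default kymograph path from the time-summed stack.

    The summed image is smoothed, Otsu-thresholded and skeletonized; the
    skeleton pixels are chained into a polyline by a nearest-neighbor walk
    starting from a skeleton endpoint (or an arbitrary pixel on closed
    loops).  Returns an (M, 2) array of (x, y) positions.
    """
    stack = np.asarray(stack, dtype=float)
    summed = stack.sum(axis=0) if stack.ndim == 3 else stack
    smooth = ndimage.gaussian_filter(summed, smoothing_sigma)
    if np.ptp(smooth) == 0:
        raise ValueError("flat stack: no ridge to extract")
    mask = smooth > threshold_otsu(smooth)
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    if len(xs) == 0:
        raise ValueError("no ridge found above threshold")
    pts = list(zip(xs.tolist(), ys.tolist()))
    # endpoint = pixel with exactly one 8-neighbor on the skeleton
    ptset = set(pts)

    def neighbors(p):
        x, y = p
        return [
            (x + dx, y + dy)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            if (dx, dy) != (0, 0) and (x + dx, y + dy) in ptset
        ]

    endpoints = [p for p in pts if len(neighbors(p)) == 1]
    start = endpoints[0] if endpoints else pts[0]
    ordered = [start]
    remaining = set(pts) - {start}
    current = start
    while remaining:
        cand = [p for p in neighbors(current) if p in remaining]
        if not cand:
            # jump to nearest remaining pixel (disconnected skeleton)
            arr = np.array(list(remaining))
            d = np.hypot(arr[:, 0] - current[0], arr[:, 1] - current[1])
            nxt = tuple(arr[np.argmin(d)])
            if d.min() > 5:
                break
        else:
            nxt = min(
                cand, key=lambda p: (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
            )
        ordered.append(nxt)
        remaining.discard(nxt)
        current = nxt
    return np.array(ordered, dtype=float)
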