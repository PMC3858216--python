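"""Cell segmentation, subpixel spline contours, major axis and sphere fit.

Cells are segmented with a global Otsu threshold, their marching-squares
boundaries refined with a periodic cubic smoothing spline, and each cell
reduced to the geometry the spherical coordinate system needs: a center, a
fitted sphere radius ``p`` (mean center-to-contour distance) and a major-axis
direction that serves as the polar (θ = 0) reference.  Spherical cells have
no intrinsic major axis: when the mask eccentricity falls below a threshold
the axis is reported as degenerate and set to the x-axis by convention — θ is
then arbitrary up to a rotation, under which all orthodromic distances are
invariant.

Coordinates are 0-based pixel centers, x along columns, y along rows; angles
are measured from +x toward +y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage
from skimage import measure
from skimage.filters import threshold_otsu


class SegmentationError(ValueError):
    """Raised when a contour is too degenerate to analyze."""


class NotSphericalError(ValueError):
    """Raised when a cell is too elongated for a sphere fit (not yet rounded)."""


@dataclass
class CellContour:
    """Closed subpixel boundary with an interpolating periodic cubic spline.

    ``points`` are the spline-refined boundary samples (x, y) in px, open
    form (the closing point is implicit); ``tck`` is the periodic cubic
    spline through them, whose evaluation at the knot parameters reproduces
    the points to machine precision.
    """

    points: np.ndarray               # (N, 2) x,y px
    tck: tuple
    u: np.ndarray                    # spline parameters of ``points``
    area_px2: float

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Spline position at parameter(s) u in [0, 1); returns (M, 2)."""
        x, y = interpolate.splev(np.asarray(u), self.tck)
        return np.column_stack([x, y])

    def curvature(self, u: np.ndarray) -> np.ndarray:
        """Unsigned curvature |x'y'' − y'x''| / (x'² + y'²)^{3/2} at u."""
        dx, dy = interpolate.splev(np.asarray(u), self.tck, der=1)
        ddx, ddy = interpolate.splev(np.asarray(u), self.tck, der=2)
        denom = (dx**2 + dy**2) ** 1.5
        return np.abs(dx * ddy - dy * ddx) / np.maximum(denom, 1e-12)


@dataclass
class MajorAxis:
    angle: float                     # radians in (-pi/2, pi/2]
    endpoints: np.ndarray            # (2, 2) contour points, x,y px
    degenerate: bool                 # True for near-spherical cells


@dataclass
class CellGeometry:
    """Everything downstream stages need to know about one cell."""

    cell_id: int
    center: tuple[float, float]      # (x, y) px
    p_um: float                      # fitted sphere radius, µm
    major_axis_angle: float          # radians in (-pi/2, pi/2]
    eccentricity: float
    contour: CellContour
    axis_degenerate: bool = False
    moments: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mu20, mu02, mu11

    def contains(self, x: float, y: float) -> bool:
        """Point-in-polygon test against the spline contour."""
        return measure.points_in_poly(
            np.array([[x, y]]), self.contour.points
        )[0]

    def distance_to_contour(self, x: float, y: float) -> float:
        d = np.hypot(self.contour.points[:, 0] - x, self.contour.points[:, 1] - y)
        return float(d.min())


def _refine_contour(
    boundary_xy: np.ndarray, n_samples: int = 200, residual_px: float = 0.1
) -> CellContour:
    """Smooth a marching-squares boundary and rebuild an exact spline.

    A periodic cubic smoothing spline (residual target ``residual_px`` per
    point) removes pixel-grid jitter; the smooth curve is resampled at
    ``n_samples`` points which become the stored boundary, with an
    interpolating periodic spline through them.  The residual target is kept
    small because smoothing splines systematically shrink convex contours —
    at 0.1 px the bias on a fitted circle radius stays well below 0.1 px.
    """
    pts = boundary_xy
    if len(pts) < 8:
        raise SegmentationError(f"contour has only {len(pts)} points")
    # close for splprep (periodic needs first == last)
    closed = np.vstack([pts, pts[:1]])
    s = residual_px**2 * len(pts)
    try:
        tck_s, _ = interpolate.splprep([closed[:, 0], closed[:, 1]], s=s, per=1)
    except Exception as exc:  # pragma: no cover - scipy failure on odd input
        raise SegmentationError(f"spline fit failed: {exc}") from exc
    uu = np.linspace(0, 1, n_samples, endpoint=False)
    xs, ys = interpolate.splev(uu, tck_s)
    smooth = np.column_stack([xs, ys])
    closed2 = np.vstack([smooth, smooth[:1]])
    tck, u = interpolate.splprep([closed2[:, 0], closed2[:, 1]], s=0, per=1)
    # shoelace area of the smoothed polygon
    x, y = smooth[:, 0], smooth[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return CellContour(points=smooth, tck=tck, u=np.asarray(u[:-1]), area_px2=area)


def _mask_moments(mask: np.ndarray) -> tuple[tuple[float, float], float, float, tuple]:
    """Centroid, orientation angle and eccentricity from binary-mask moments."""
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    mu20 = np.mean((xs - cx) ** 2)
    mu02 = np.mean((ys - cy) ** 2)
    mu11 = np.mean((xs - cx) * (ys - cy))
    angle = 0.5 * np.arctan2(2 * mu11, mu20 - mu02)
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    common = np.sqrt(4 * mu11**2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    ecc = np.sqrt(1 - lam2 / lam1) if lam1 > 0 else 0.0
    return (cx, cy), float(angle), float(ecc), (mu20, mu02, mu11)


DEGENERATE_ECCENTRICITY = 0.1    # below this the mask is treated as circular


def _component_boundary(
    img: np.ndarray, comp: np.ndarray, bg_level: float
) -> np.ndarray | None:
    """Subpixel boundary of one component at the half-contrast level.

    Marching squares is run on the grayscale image (cropped around the
    component) at the midpoint between the background level and the
    component's interior median, so on a blurred edge the contour falls on
    the true object outline rather than on the binarization staircase.
    """
    ys, xs = np.nonzero(comp)
    pad = 3
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, img.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, img.shape[1])
    crop = img[y0:y1, x0:x1]
    level = 0.5 * (bg_level + np.median(img[comp]))
    contours = measure.find_contours(crop, level)
    if not contours:
        return None
    cy, cx = ys.mean() - y0, xs.mean() - x0
    best = None
    for c in contours:
        if len(c) < 8 or not np.allclose(c[0], c[-1]):
            continue
        if measure.points_in_poly(np.array([[cy, cx]]), c)[0]:
            if best is None or len(c) > len(best):
                best = c
    if best is None:
        return None
    out = best[:, ::-1].copy()      # (row, col) -> (x, y)
    out[:, 0] += x0
    out[:, 1] += y0
    return out


def segment_cells(
    image: np.ndarray,
    pixel_size: float = 1.0,
    min_area_px: int = 50,
) -> list[CellGeometry]:
    """Segment cells in one grayscale frame.

    Global Otsu threshold → connected components ≥ ``min_area_px`` →
    subpixel spline contour per component, extracted from the grayscale
    image at the half-contrast level.  ``p_um`` is the mean
    center-to-contour distance scaled by ``pixel_size``.  A flat or empty
    image yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a single 2D frame")
    if np.ptp(img) == 0:
        return []
    # threshold on a median-filtered copy: bright diffraction-limited foci
    # (tiny area, large amplitude) otherwise capture Otsu's upper class and
    # the cell bodies end up below threshold
    filtered = ndimage.median_filter(img, size=5)
    if np.ptp(filtered) == 0:
        return []
    thr = threshold_otsu(filtered)
    mask = img > thr
    if not mask.any() or mask.all():
        return []
    bg_level = float(np.median(img[~mask]))
    labels = measure.label(mask)
    geometries: list[CellGeometry] = []
    for region_label in range(1, labels.max() + 1):
        comp = labels == region_label
        if comp.sum() < min_area_px:
            continue
        boundary_xy = _component_boundary(img, comp, bg_level)
        if boundary_xy is None:
            continue
        # drop duplicated closing point if present
        if np.allclose(boundary_xy[0], boundary_xy[-1]):
            boundary_xy = boundary_xy[:-1]
        try:
            contour = _refine_contour(boundary_xy)
        except SegmentationError:
            continue
        (cx, cy), angle, ecc, mu = _mask_moments(comp)
        dists = np.hypot(contour.points[:, 0] - cx, contour.points[:, 1] - cy)
        degenerate = ecc < DEGENERATE_ECCENTRICITY
        geometries.append(
            CellGeometry(
                cell_id=len(geometries),
                center=(float(cx), float(cy)),
                p_um=float(dists.mean() * pixel_size),
                major_axis_angle=0.0 if degenerate else angle,
                eccentricity=ecc,
                contour=contour,
                axis_degenerate=degenerate,
                moments=mu,
            )
        )
    return geometries


def estimate_major_axis(
    geometry: CellGeometry,
    curvature_weight: float = 1.0,
    angle_weight: float = 1.0,
    n_samples: int = 400,
) -> MajorAxis:
    """Locate the major axis and its contour endpoints.

    The axis direction is the principal axis of the mask's second moments.
    Each endpoint is the contour point on the corresponding axis ray chosen
    by a weighted score that rewards high spline curvature and penalizes
    angular deviation from the centerline:

        score = w_curv · κ/κ_max − w_ang · |Δangle|/(π/2),

    restricted to points within ±90° of the ray.  Cells with mask
    eccentricity below the degeneracy threshold get a flagged x-axis
    convention instead.
    """
    contour = geometry.contour
    if len(contour.points) < 8:
        raise SegmentationError("degenerate contour (<8 points)")
    if geometry.axis_degenerate:
        cx, cy = geometry.center
        # by convention: intersect the x-axis ray with the contour
        uu = np.linspace(0, 1, n_samples, endpoint=False)
        pts = contour.evaluate(uu)
        ang = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
        e1 = pts[np.argmin(np.abs(_wrap(ang))), :]
        e2 = pts[np.argmin(np.abs(_wrap(ang - np.pi))), :]
        return MajorAxis(angle=0.0, endpoints=np.vstack([e1, e2]), degenerate=True)

    uu = np.linspace(0, 1, n_samples, endpoint=False)
    pts = contour.evaluate(uu)
    kappa = contour.curvature(uu)
    kmax = kappa.max() if kappa.max() > 0 else 1.0
    cx, cy = geometry.center
    point_ang = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)

    endpoints = []
    for ray in (geometry.major_axis_angle, geometry.major_axis_angle + np.pi):
        dev = np.abs(_wrap(point_ang - ray))
        score = curvature_weight * kappa / kmax - angle_weight * dev / (np.pi / 2)
        score[dev > np.pi / 2] = -np.inf
        endpoints.append(pts[int(np.argmax(score))])
    return MajorAxis(
        angle=geometry.major_axis_angle,
        endpoints=np.vstack(endpoints),
        degenerate=False,
    )


@dataclass
class SphereFit:
    p_um: float
    sd_um: float      # circularity diagnostic: SD of center-to-contour distance


def fit_sphere(
    geometry: CellGeometry,
    pixel_size: float,
    eccentricity_max: float = 0.25,
) -> SphereFit:
    """Fit the sphere radius ``p`` for a rounded (sporulating) cell.

    p is the mean distance from the mask centroid to the spline-sampled
    contour, scaled to µm; the SD of those distances is reported as a
    circularity diagnostic.  Raises :class:`NotSphericalError` when the
    mask eccentricity exceeds ``eccentricity_max`` (cell not yet rounded).
    """
    if geometry.eccentricity > eccentricity_max:
        raise NotSphericalError(
            f"eccentricity {geometry.eccentricity:.3f} exceeds bound "
            f"{eccentricity_max:.3f}: cell has not rounded"
        )
    uu = np.linspace(0, 1, 400, endpoint=False)
    pts = geometry.contour.evaluate(uu)
    cx, cy = geometry.center
    dists = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) * pixel_size
    return SphereFit(p_um=float(dists.mean()), sd_um=float(dists.std()))


def geometry_table(geometries: list[CellGeometry]) -> pd.DataFrame:
    """Flat per-cell table for CSV export."""
    return pd.DataFrame(
        [
            {
                "cell_id": g.cell_id,
                "center_x_px": g.center[0],
                "center_y_px": g.center[1],
                "p_um": g.p_um,
                "axis_rad": g.major_axis_angle,
                "axis_degenerate": g.axis_degenerate,
                "eccentricity": g.eccentricity,
                "area_px2": g.contour.area_px2,
            }
            for g in geometries
        ]
    )


def _wrap(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = (a + np.pi) % (2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out if out.ndim else float(out)
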