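"""Spherical coordinates, orthodromic distances and trajectory linking.

A focus detected at planar position (x, y) inside a spherical cell of center
c and radius p is first expressed in polar coordinates (r, θ): r is the
planar center-to-focus distance and θ the angle from the cell's major axis.
Because foci sit on the sphere surface, the polar system extends to
spherical coordinates (p, θ, φ) with the azimuthal (elevation) angle

    φ = arccos(r / p),

so φ = 0 on the equatorial boundary and φ = π/2 at the projected center.
The distance actually traveled between two surface points is the orthodromic
(great-circle) arc

    d = p·arccos(cosθ₁cosφ₁cosθ₂cosφ₂ + sinθ₁cosφ₁sinθ₂cosφ₂ + sinφ₁sinφ₂),

equivalently p times the angle between the 3D unit vectors
n = (cosφ·cosθ, cosφ·sinθ, sinφ).  Single-plane imaging cannot distinguish
the two hemispheres (φ ≥ 0 always); all foci are treated as lying on one
hemisphere, which underestimates distances for the rare steps that cross the
equator.

Detections are linked frame-to-frame per cell by a globally optimal
one-to-one assignment (Hungarian algorithm) minimizing total orthodromic
distance, with links longer than ``max_step`` forbidden and optional gap
closing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import CellGeometry

P_MATCH_RTOL = 1e-6


@dataclass
class PolarCoordinate:
    """In-plane position of a focus relative to its cell."""

    r: float          # µm, center-to-focus planar distance
    theta: float      # rad in (-pi, pi], from the major axis


@dataclass
class SphericalCoordinate:
    """Position on the spore sphere; ``clamped`` marks r > p detections."""

    p: float          # µm
    theta: float      # rad
    phi: float        # rad in [0, pi/2]
    clamped: bool = False

    def unit_vector(self) -> np.ndarray:
        cphi = np.cos(self.phi)
        return np.array(
            [cphi * np.cos(self.theta), cphi * np.sin(self.theta), np.sin(self.phi)]
        )


@dataclass
class Track:
    """Time-ordered spherical positions of one linked focus."""

    track_id: int
    cell_id: int
    frames: np.ndarray           # (n,) int
    times: np.ndarray            # (n,) min, strictly increasing
    p: float                     # µm, shared sphere radius
    theta: np.ndarray            # (n,) rad
    phi: np.ndarray              # (n,) rad
    intensity: np.ndarray        # (n,)
    x_px: np.ndarray             # (n,) original planar detections
    y_px: np.ndarray
    clamped_fraction: float = 0.0

    def __len__(self) -> int:
        return len(self.frames)

    def coordinates(self) -> list[SphericalCoordinate]:
        return [
            SphericalCoordinate(self.p, t, f) for t, f in zip(self.theta, self.phi)
        ]

    def unit_vectors(self) -> np.ndarray:
        """(n, 3) unit vectors on the sphere."""
        cphi = np.cos(self.phi)
        return np.column_stack(
            [cphi * np.cos(self.theta), cphi * np.sin(self.theta), np.sin(self.phi)]
        )


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = (a + np.pi) % (2 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return out if out.ndim else float(out)


def to_polar(
    detection, geometry: CellGeometry, pixel_size: float
) -> PolarCoordinate:
    """Planar detection → polar (r, θ) relative to the cell's major axis.

    ``detection`` needs ``x``/``y`` attributes (px).  θ is measured from the
    major-axis direction, positive from +x toward +y; a focus exactly at the
    center gets θ = 0 by convention.
    """
    dx = detection.x - geometry.center[0]
    dy = detection.y - geometry.center[1]
    r = float(np.hypot(dx, dy) * pixel_size)
    if r == 0:
        return PolarCoordinate(r=0.0, theta=0.0)
    theta = float(wrap_angle(np.arctan2(dy, dx) - geometry.major_axis_angle))
    return PolarCoordinate(r=r, theta=theta)


def to_spherical(polar: PolarCoordinate, p: float) -> SphericalCoordinate:
    """Lift a polar coordinate to the sphere: φ = arccos(r/p).

    Detections with r > p (localization noise outside the fitted circle)
    are clamped to the boundary (φ = 0) and flagged via ``clamped``.
    """
    if p <= 0:
        raise ValueError("sphere radius p must be positive")
    ratio = polar.r / p
    clamped = ratio > 1.0
    phi = float(np.arccos(min(ratio, 1.0)))
    return SphericalCoordinate(p=p, theta=polar.theta, phi=phi, clamped=clamped)


def orthodromic_distance(
    a: SphericalCoordinate, b: SphericalCoordinate
) -> float:
    """Great-circle arc length (µm) between two points on the same sphere."""
    if abs(a.p - b.p) > P_MATCH_RTOL * max(a.p, b.p):
        raise ValueError(
            f"sphere radii differ ({a.p} vs {b.p}): cross-cell comparison"
        )
    cosd = (
        np.cos(a.theta) * np.cos(a.phi) * np.cos(b.theta) * np.cos(b.phi)
        + np.sin(a.theta) * np.cos(a.phi) * np.sin(b.theta) * np.cos(b.phi)
        + np.sin(a.phi) * np.sin(b.phi)
    )
    return float(a.p * np.arccos(np.clip(cosd, -1.0, 1.0)))


def arc_distances(
    theta1, phi1, theta2, phi2, p: float
) -> np.ndarray:
    """Vectorized orthodromic distance for equal-radius coordinate arrays."""
    cosd = (
        np.cos(theta1) * np.cos(phi1) * np.cos(theta2) * np.cos(phi2)
        + np.sin(theta1) * np.cos(phi1) * np.sin(theta2) * np.cos(phi2)
        + np.sin(phi1) * np.sin(phi2)
    )
    return p * np.arccos(np.clip(cosd, -1.0, 1.0))


def euclidean_to_orthodromic(
    xy1, xy2, center, p: float, pixel_size: float
) -> float:
    """Great-circle distance directly from two planar pixel positions.

    Each point is lifted to the upper hemisphere (z = √(p² − r²), with r
    clamped to p as in :func:`to_spherical`), the 3D chord c computed, and
    the arc returned as 2·p·arcsin(c/(2p)).  Agrees with
    :func:`orthodromic_distance` on the corresponding spherical coordinates
    to numerical precision.
    """
    pts3d = []
    for xy in (xy1, xy2):
        dx = (xy[0] - center[0]) * pixel_size
        dy = (xy[1] - center[1]) * pixel_size
        r2 = dx * dx + dy * dy
        if r2 > p * p:
            scale = p / np.sqrt(r2)
            dx, dy, z = dx * scale, dy * scale, 0.0
        else:
            z = np.sqrt(p * p - r2)
        pts3d.append(np.array([dx, dy, z]))
    chord = np.linalg.norm(pts3d[0] - pts3d[1])
    return float(2 * p * np.arcsin(np.clip(chord / (2 * p), -1.0, 1.0)))


# --- linking ----------------------------------------------------------------


def _assignment(cost: np.ndarray, gate: float) -> list[tuple[int, int]]:
    """Globally optimal gated one-to-one matching.

    Minimizes Σ(link costs) + gate·(#unmatched rows + #unmatched cols)/... by
    padding the cost matrix with per-item "no link" alternatives at cost
    ``gate``; links with cost > gate are forbidden outright.  Ties are broken
    deterministically by input order.
    """
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    big = 1e9
    padded = np.full((n + m, n + m), 0.0)
    tl = np.where(cost <= gate, cost, big)
    # deterministic tie-break: minuscule preference for earlier indices
    eps = 1e-9 * gate if gate > 0 else 1e-12
    ii, jj = np.mgrid[0:n, 0:m]
    tl = tl + eps * (ii * m + jj) / (n * m + 1)
    padded[:n, :m] = tl
    padded[:n, m:] = big
    padded[n:, :m] = big
    padded[:n, m:][np.diag_indices(n)] = gate
    padded[n:, :m][np.diag_indices(m)] = gate
    rows, cols = linear_sum_assignment(padded)
    out = []
    for r, c in zip(rows, cols):
        if r < n and c < m and padded[r, c] < big:
            out.append((int(r), int(c)))
    return out


class _OpenTrack:
    __slots__ = ("track_id", "cell_id", "rows", "last_frame", "last_coord")

    def __init__(self, track_id, cell_id, row, frame, coord):
        self.track_id = track_id
        self.cell_id = cell_id
        self.rows = [row]
        self.last_frame = frame
        self.last_coord = coord

    def append(self, row, frame, coord):
        self.rows.append(row)
        self.last_frame = frame
        self.last_coord = coord


DEFAULT_MAX_STEP_UM = 0.45   # 3 × per-frame displacement at the 0.3 µm/min upper speed, dt=0.5


def link_tracks(
    detections: pd.DataFrame,
    geometries: list[CellGeometry],
    pixel_size: float,
    dt: float,
    max_step: float = DEFAULT_MAX_STEP_UM,
    max_gap_frames: int = 0,
    min_length: int = 2,
) -> list[Track]:
    """Link a detections table into per-cell trajectories.

    ``detections`` needs columns frame, time_min, cell_id, x_px, y_px,
    intensity.  Within each cell, consecutive frames are matched by a
    globally optimal one-to-one assignment minimizing total orthodromic
    distance, with links above ``max_step`` µm forbidden (the gate scales
    with the number of elapsed frames when gap closing is enabled).
    Unmatched detections seed new tracks; tracks shorter than ``min_length``
    are discarded.  Track ids are assigned in creation order and are
    deterministic for identical input.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    geom_by_id = {g.cell_id: g for g in geometries}
    tracks: list[Track] = []
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    next_id = 0

    if len(detections) == 0:
        return []
    det = detections.sort_values(["frame", "cell_id"], kind="stable").reset_index(
        drop=True
    )

    for cell_id, cdet in det.groupby("cell_id", sort=True):
        geom = geom_by_id.get(cell_id)
        if geom is None:
            continue
        p = geom.p_um
        open_tracks = []
        closed = []
        for frame, fdet in cdet.groupby("frame", sort=True):
            rows = list(fdet.itertuples())
            coords = []
            for row in rows:
                pol = to_polar(
                    _XY(row.x_px, row.y_px), geom, pixel_size
                )
                coords.append(to_spherical(pol, p))
            # retire tracks beyond the gap window
            still_open = []
            for t in open_tracks:
                if frame - t.last_frame <= max_gap_frames + 1:
                    still_open.append(t)
                else:
                    closed.append(t)
            open_tracks = still_open

            if open_tracks:
                cost = np.empty((len(open_tracks), len(rows)))
                gates = np.empty((len(open_tracks), 1))
                for i, t in enumerate(open_tracks):
                    gates[i, 0] = max_step * (frame - t.last_frame)
                    for j, c in enumerate(coords):
                        cost[i, j] = orthodromic_distance(t.last_coord, c)
                # normalize per-row gate into a single gate by scaling costs
                scaled = cost / gates
                matches = _assignment(scaled, 1.0)
            else:
                matches = []
            matched_tracks = {i for i, _ in matches}
            matched_dets = {j for _, j in matches}
            for i, j in matches:
                open_tracks[i].append(rows[j], frame, coords[j])
            for j, (row, c) in enumerate(zip(rows, coords)):
                if j not in matched_dets:
                    open_tracks.append(
                        _OpenTrack(next_id, cell_id, row, frame, c)
                    )
                    open_tracks[-1].rows = [row]
                    next_id += 1
            # keep list ordered by track id for determinism
            open_tracks.sort(key=lambda t: t.track_id)
        closed.extend(open_tracks)
        for t in sorted(closed, key=lambda t: t.track_id):
            if len(t.rows) < min_length:
                continue
            tracks.append(_finalize(t, geom, p, pixel_size))
    tracks.sort(key=lambda t: t.track_id)
    # renumber contiguously
    for new_id, t in enumerate(tracks):
        t.track_id = new_id
    return tracks


class _XY:
    __slots__ = ("x", "y")

    def __init__(self, x, y):
        self.x = x
        self.y = y


def _finalize(t: _OpenTrack, geom: CellGeometry, p: float, pixel_size: float) -> Track:
    frames = np.array([r.frame for r in t.rows], dtype=int)
    times = np.array([r.time_min for r in t.rows], dtype=float)
    xs = np.array([r.x_px for r in t.rows], dtype=float)
    ys = np.array([r.y_px for r in t.rows], dtype=float)
    inten = np.array([r.intensity for r in t.rows], dtype=float)
    thetas = np.empty(len(frames))
    phis = np.empty(len(frames))
    clamped = 0
    for i, (x, y) in enumerate(zip(xs, ys)):
        sph = to_spherical(to_polar(_XY(x, y), geom, pixel_size), p)
        thetas[i], phis[i] = sph.theta, sph.phi
        clamped += sph.clamped
    return Track(
        track_id=t.track_id,
        cell_id=t.cell_id,
        frames=frames,
        times=times,
        p=p,
        theta=thetas,
        phi=phis,
        intensity=inten,
        x_px=xs,
        y_px=ys,
        clamped_fraction=clamped / len(frames),
    )


def tracks_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format tracks table (round-trips with :func:`tracks_from_table`)."""
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append(
                {
                    "track_id": t.track_id,
                    "cell_id": t.cell_id,
                    "frame": int(t.frames[i]),
                    "time_min": t.times[i],
                    "p_um": t.p,
                    "theta_rad": t.theta[i],
                    "phi_rad": t.phi[i],
                    "x_px": t.x_px[i],
                    "y_px": t.y_px[i],
                    "intensity": t.intensity[i],
                    "clamped_fraction": t.clamped_fraction,
                }
            )
    columns = [
        "track_id", "cell_id", "frame", "time_min", "p_um", "theta_rad",
        "phi_rad", "x_px", "y_px", "intensity", "clamped_fraction",
    ]
    return pd.DataFrame(rows, columns=columns)


def tracks_from_table(table: pd.DataFrame) -> list[Track]:
    """Rebuild Track objects from a long-format table."""
    tracks = []
    for tid, g in table.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                cell_id=int(g["cell_id"].iloc[0]),
                frames=g["frame"].to_numpy(dtype=int),
                times=g["time_min"].to_numpy(dtype=float),
                p=float(g["p_um"].iloc[0]),
                theta=g["theta_rad"].to_numpy(dtype=float),
                phi=g["phi_rad"].to_numpy(dtype=float),
                intensity=g["intensity"].to_numpy(dtype=float),
                x_px=g["x_px"].to_numpy(dtype=float),
                y_px=g["y_px"].to_numpy(dtype=float),
                clamped_fraction=float(g["clamped_fraction"].iloc[0])
                if "clamped_fraction" in g
                else 0.0,
            )
        )
    return tracks
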