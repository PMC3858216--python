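"""Synthetic time-lapse microscopy of foci moving on spherical cell surfaces.

Sporulating cells are modelled as spheres of radius ``p`` (µm) imaged in a
single focal plane.  Bright diffraction-limited foci move on the sphere under
one of four motion regimes:

``directed``
    geodesic (great-circle) motion at linear speed ``v_true``, with optional
    tangential Brownian jitter of coefficient ``D_true``;
``diffusive``
    tangent-plane Gaussian steps with per-axis variance ``2*D_true*dt``,
    reprojected to the sphere, so the per-step arc MSD is ``4*D_true*dt``;
``arrested``
    frame-independent jitter about a fixed anchor point (plateau MSD);
``directed_with_reversals``
    geodesic motion whose sense flips as a Poisson process at
    ``reversal_rate`` events per minute (erratic, saltatory tracks).

Trajectories are rendered into noisy 16-bit image stacks with an orthographic
projection, a Gaussian point-spread function, defocus dimming for foci away
from the focal plane, a dim cell-body disk, a multiplicative slow background
drift, Poisson photon noise and Gaussian read noise.  Ground truth is always
retained so detection, linking and motion analysis can be validated without
any external data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

REGIMES = ("directed", "diffusive", "arrested", "directed_with_reversals")


@dataclass
class MotionParams:
    """Ground-truth motion model for one focus population.

    Parameters
    ----------
    regime : str
        One of ``directed``, ``diffusive``, ``arrested``,
        ``directed_with_reversals``.
    v_true : float
        Linear speed along the great circle, µm·min⁻¹.
    D_true : float
        Surface diffusion (or residual jitter) coefficient, µm²·min⁻¹.
    reversal_rate : float
        Poisson rate of direction reversals, events·min⁻¹ (only used by
        ``directed_with_reversals``).
    p_true : float
        Sphere radius, µm.
    dt : float
        Frame interval, min.
    n_frames : int
        Number of frames (≥ 2).
    seed : int
        Seed for the trajectory's random number generator.
    """

    regime: str = "directed"
    v_true: float = 0.12
    D_true: float = 0.012
    reversal_rate: float = 0.0
    p_true: float = 0.75
    dt: float = 0.5
    n_frames: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; valid: {REGIMES}")
        if self.v_true < 0 or self.D_true < 0:
            raise ValueError("v_true and D_true must be nonnegative")
        if self.p_true <= 0 or self.dt <= 0:
            raise ValueError("p_true and dt must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.regime == "arrested" and self.v_true != 0:
            raise ValueError("arrested regime requires v_true = 0")


@dataclass
class OpticsParams:
    """Imaging model: projection, PSF, noise and defocus dimming.

    ``defocus_halfdepth`` is the distance from the focal plane at which a
    focus' amplitude halves; ``focal_plane_z`` is the plane's height relative
    to the sphere center (0 = equatorial "middle" section).
    """

    pixel_size: float = 0.1          # µm per px
    psf_sigma: float = 0.13          # µm
    peak_photons: float = 800.0      # in-focus focus amplitude, counts
    background_level: float = 100.0  # counts
    background_drift_amplitude: float = 0.1   # fractional, one cycle per movie
    read_noise_sd: float = 2.0       # counts
    defocus_halfdepth: float = 0.5   # µm
    focal_plane_z: float = 0.0       # µm

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < self.pixel_size / 2:
            raise ValueError("psf_sigma must be >= pixel_size/2 (diffraction-limited)")


# Cell body fluorescence rendered as a dim disk this many times brighter
# than the background (diffuse cytoplasmic signal).
CELL_BODY_CONTRAST = 0.8


@dataclass
class CellTruth:
    """Ground-truth geometry of one rendered cell."""

    cell_id: int
    center_px: tuple[float, float]   # (x, y)
    p_um: float


@dataclass
class GroundTruthTrajectory:
    """One focus' true path on the sphere.

    ``positions`` are 3D points in µm relative to the sphere center, all of
    norm ``p_true``.  ``theta`` is atan2(y, x) and ``phi`` is the signed
    elevation arcsin(z/p) — negative below the focal plane; the tracker's
    azimuthal angle is its absolute value.
    """

    focus_id: int
    cell_id: int
    params: MotionParams
    positions: np.ndarray        # (n_frames, 3), µm
    times: np.ndarray            # (n_frames,), min

    @property
    def theta(self) -> np.ndarray:
        return np.arctan2(self.positions[:, 1], self.positions[:, 0])

    @property
    def phi(self) -> np.ndarray:
        return np.arcsin(np.clip(self.positions[:, 2] / self.params.p_true, -1, 1))

    @property
    def arc_steps(self) -> np.ndarray:
        """True per-frame arc displacement, µm (length n_frames - 1)."""
        p = self.params.p_true
        u = self.positions / p
        cosd = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
        return p * np.arccos(cosd)


@dataclass
class SyntheticScene:
    """A rendered stack plus everything needed to score a tracker against it."""

    stack: np.ndarray                 # (n_frames, H, W) uint16
    trajectories: list[GroundTruthTrajectory]
    cells: list[CellTruth]
    motion: MotionParams
    optics: OpticsParams

    def truth_table(self) -> pd.DataFrame:
        """Per-frame truth, one row per focus per frame."""
        rows = []
        cell_by_id = {c.cell_id: c for c in self.cells}
        ps = self.optics.pixel_size
        for traj in self.trajectories:
            cell = cell_by_id[traj.cell_id]
            cx, cy = cell.center_px
            pos = traj.positions
            for f in range(pos.shape[0]):
                x_um, y_um, z_um = pos[f]
                rows.append(
                    {
                        "focus_id": traj.focus_id,
                        "cell_id": traj.cell_id,
                        "frame": f,
                        "time_min": traj.times[f],
                        "x_px": cx + x_um / ps,
                        "y_px": cy + y_um / ps,
                        "z_um": z_um,
                        "p_um": traj.params.p_true,
                        "theta_rad": traj.theta[f],
                        "phi_rad": traj.phi[f],
                    }
                )
        columns = [
            "focus_id", "cell_id", "frame", "time_min", "x_px", "y_px",
            "z_um", "p_um", "theta_rad", "phi_rad",
        ]
        return pd.DataFrame(rows, columns=columns)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis of the tangent plane at unit vector u."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def simulate_surface_trajectory(
    params: MotionParams, focus_id: int = 0, cell_id: int = 0
) -> GroundTruthTrajectory:
    """Simulate one focus trajectory on the sphere under ``params``.

    Directed motion advances along a geodesic by angle ``v_true*dt/p_true``
    per frame (exactly, so the noiseless cumulated arc length is
    ``v_true*dt*(n_frames-1)``), with the direction parallel-transported.
    Brownian jitter is a tangent-plane Gaussian step of per-axis variance
    ``2*D_true*dt`` followed by radial reprojection (valid for steps ≪ p).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    p, dt, n = params.p_true, params.dt, params.n_frames
    sigma = np.sqrt(2.0 * params.D_true * dt)   # µm, per tangent axis

    u = _random_unit_vector(rng)
    tang, _ = _tangent_basis(u)
    anchor = u.copy()
    sense = 1.0
    alpha = params.v_true * dt / p              # geodesic step angle

    out = np.empty((n, 3))
    out[0] = u * p
    for f in range(1, n):
        if params.regime in ("directed", "directed_with_reversals"):
            if params.regime == "directed_with_reversals":
                if rng.poisson(params.reversal_rate * dt) % 2 == 1:
                    sense = -sense
            a = sense * alpha
            u_new = u * np.cos(a) + tang * np.sin(a)
            tang = -u * np.sin(a) + tang * np.cos(a)
            u = u_new
            if sigma > 0:
                e1, e2 = _tangent_basis(u)
                step = sigma * (rng.normal() * e1 + rng.normal() * e2)
                u = u * p + step
                u /= np.linalg.norm(u)
                tang -= np.dot(tang, u) * u
                tang /= np.linalg.norm(tang)
        elif params.regime == "diffusive":
            e1, e2 = _tangent_basis(u)
            step = sigma * (rng.normal() * e1 + rng.normal() * e2)
            u = u * p + step
            u /= np.linalg.norm(u)
        else:  # arrested: independent jitter about the anchor
            e1, e2 = _tangent_basis(anchor)
            step = sigma * (rng.normal() * e1 + rng.normal() * e2)
            u = anchor * p + step
            u /= np.linalg.norm(u)
        out[f] = u * p

    times = np.arange(n) * dt
    return GroundTruthTrajectory(
        focus_id=focus_id, cell_id=cell_id, params=params, positions=out, times=times
    )


def defocus_attenuation(z: float, optics: OpticsParams) -> float:
    """Lorentzian amplitude dimming with distance from the focal plane."""
    dz = (z - optics.focal_plane_z) / optics.defocus_halfdepth
    return 1.0 / (1.0 + dz * dz)


def _add_gaussian_spot(
    frame: np.ndarray, x: float, y: float, amplitude: float, sigma_px: float
) -> None:
    """Accumulate a 2D Gaussian (evaluated at pixel centers) in place."""
    h, w = frame.shape
    half = int(np.ceil(4 * sigma_px))
    x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma_px**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma_px**2))
    frame[y0:y1, x0:x1] += amplitude * np.outer(gy, gx)


def render_scene(
    trajectories: Sequence[GroundTruthTrajectory],
    cells: Sequence[CellTruth],
    optics: OpticsParams,
    image_shape: tuple[int, int] = (64, 64),
    seed: int = 0,
    noise: bool = True,
) -> SyntheticScene:
    """Render trajectories into a noisy single-plane image stack.

    Each focus becomes a 2D Gaussian of width ``psf_sigma`` at the
    orthographic projection of its 3D position, dimmed by the defocus model.
    The expected image (background drift × [background + cell disks + foci])
    receives Poisson photon noise and Gaussian read noise when ``noise`` is
    on.  Foci projecting outside the image are omitted from that frame with a
    warning.  The stack is quantized to uint16; ground truth is retained in
    the returned scene.
    """
    if not trajectories:
        n_frames = 2
    else:
        n_frames = trajectories[0].positions.shape[0]
        ps = {t.params.p_true for t in trajectories}
        if len(ps) > 1:
            raise ValueError("all trajectories must share p_true")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    cell_by_id = {c.cell_id: c for c in cells}
    sigma_px = optics.psf_sigma / optics.pixel_size

    # static scene component: background + dim cell disks, edge blurred by
    # the PSF (supersampled so partial pixels at the rim are correct)
    yy, xx = np.mgrid[0:h, 0:w]
    base = np.full((h, w), float(optics.background_level))
    body = np.zeros((h, w))
    sub = np.linspace(-0.5 + 0.125, 0.5 - 0.125, 4)
    for cell in cells:
        cx, cy = cell.center_px
        r2 = (cell.p_um / optics.pixel_size) ** 2
        frac = np.zeros((h, w))
        for oy in sub:
            for ox in sub:
                frac += (xx + ox - cx) ** 2 + (yy + oy - cy) ** 2 <= r2
        body += frac / len(sub) ** 2
    body = gaussian_filter(body, sigma_px)
    base += CELL_BODY_CONTRAST * optics.background_level * np.clip(body, 0, 1)

    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    for f in range(n_frames):
        frame = base.copy()
        for traj in trajectories:
            cell = cell_by_id[traj.cell_id]
            x_um, y_um, z_um = traj.positions[f]
            x = cell.center_px[0] + x_um / optics.pixel_size
            y = cell.center_px[1] + y_um / optics.pixel_size
            if not (0 <= x < w and 0 <= y < h):
                warnings.warn(
                    f"focus {traj.focus_id} outside image bounds in frame {f}; omitted",
                    stacklevel=2,
                )
                continue
            amp = optics.peak_photons * defocus_attenuation(z_um, optics)
            _add_gaussian_spot(frame, x, y, amp, sigma_px)
        drift = 1.0 + optics.background_drift_amplitude * np.sin(
            2 * np.pi * f / n_frames
        )
        frame *= drift
        if noise:
            frame = rng.poisson(frame).astype(float)
            frame += rng.normal(0.0, optics.read_noise_sd, size=frame.shape)
        stack[f] = np.clip(np.round(frame), 0, 65535).astype(np.uint16)

    motion = trajectories[0].params if trajectories else MotionParams(seed=seed)
    return SyntheticScene(
        stack=stack,
        trajectories=list(trajectories),
        cells=list(cells),
        motion=motion,
        optics=optics,
    )


# --- preset scenes -----------------------------------------------------------

#: Motion-parameter templates for the conditions the package emulates.
#: "WT" = directed rotation; "exoA" = frequent reversals (directionality
#: lost); "aglQ" = paralyzed foci (residual jitter only); "blank" = no foci.
PRESETS: dict[str, dict] = {
    "WT": dict(regime="directed", v_true=0.12, D_true=0.012),
    "exoA": dict(
        regime="directed_with_reversals", v_true=0.12, D_true=0.012, reversal_rate=2.0
    ),
    "aglQ": dict(regime="arrested", v_true=0.0, D_true=0.002),
    "blank": None,
}

CELL_SPACING_PX = 32          # grid pitch when laying out several cells
FOCI_PER_CELL = 2


def simulate_preset(
    preset: str,
    seed: int,
    n_cells: int = 1,
    n_foci_per_cell: int = FOCI_PER_CELL,
    n_frames: int = 60,
    optics: OpticsParams | None = None,
    noise: bool = True,
) -> SyntheticScene:
    """Build a ready-to-track scene for one of the named presets.

    Cells are laid out on a square grid; each hosts ``n_foci_per_cell``
    independently-seeded trajectories (none for ``blank``).  All randomness
    derives from ``seed`` through a SeedSequence, so repeated calls are
    bit-identical.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid: {sorted(PRESETS)}")
    optics = optics or OpticsParams()
    ss = np.random.SeedSequence(seed)
    render_seed = int(ss.generate_state(1)[0] % (2**31))

    ncols = int(np.ceil(np.sqrt(n_cells)))
    nrows = int(np.ceil(n_cells / ncols))
    h = nrows * CELL_SPACING_PX
    w = ncols * CELL_SPACING_PX
    cells = [
        CellTruth(
            cell_id=i,
            center_px=(
                (i % ncols) * CELL_SPACING_PX + CELL_SPACING_PX / 2,
                (i // ncols) * CELL_SPACING_PX + CELL_SPACING_PX / 2,
            ),
            p_um=0.75,
        )
        for i in range(n_cells)
    ]

    trajectories: list[GroundTruthTrajectory] = []
    if PRESETS[preset] is not None:
        child_seeds = ss.spawn(n_cells * n_foci_per_cell)
        fid = 0
        for cell in cells:
            for _ in range(n_foci_per_cell):
                params = MotionParams(
                    **PRESETS[preset],
                    p_true=cell.p_um,
                    dt=0.5,
                    n_frames=n_frames,
                    seed=int(child_seeds[fid].generate_state(1)[0] % (2**31)),
                )
                trajectories.append(
                    simulate_surface_trajectory(params, focus_id=fid, cell_id=cell.cell_id)
                )
                fid += 1
    return render_scene(
        trajectories, cells, optics, image_shape=(h, w), seed=render_seed, noise=noise
    )


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Write TIFF stacks and truth CSVs for all presets; return the manifest.

    Each preset gets ``<name>_stack.tif`` (multi-page 16-bit) and
    ``<name>_truth.csv``; the manifest (also written as ``manifest.json``)
    records files, seeds and scene parameters.  Deterministic: the same seed
    yields byte-identical truth tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    preset_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(sorted(PRESETS), ss.spawn(len(PRESETS)))
    }
    manifest: dict = {"seed": seed, "presets": {}}
    for name in sorted(PRESETS):
        scene = simulate_preset(name, seed=preset_seeds[name], n_cells=4)
        stack_file = out / f"{name}_stack.tif"
        truth_file = out / f"{name}_truth.csv"
        tifffile.imwrite(stack_file, scene.stack)
        scene.truth_table().to_csv(truth_file, index=False, float_format="%.9g")
        manifest["presets"][name] = {
            "stack": stack_file.name,
            "truth": truth_file.name,
            "seed": preset_seeds[name],
            "n_cells": len(scene.cells),
            "n_foci": len(scene.trajectories),
            "n_frames": int(scene.stack.shape[0]),
            "motion": asdict(scene.motion) if scene.trajectories else None,
            "optics": asdict(scene.optics),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
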