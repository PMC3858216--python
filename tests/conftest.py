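"""Shared fixtures: small synthetic images and scenes, generated at test time."""

import numpy as np
import pytest

import sporetrack as st


def make_disk_image(
    radius_px: float = 7.5,
    center=(16.0, 16.0),
    shape=(32, 32),
    background: float = 100.0,
    contrast: float = 80.0,
    blur_sigma: float = 1.0,
) -> np.ndarray:
    """Anti-aliased disk on a flat background (4x4 supersampled, blurred)."""
    from scipy.ndimage import gaussian_filter

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    sub = np.linspace(-0.5 + 0.125, 0.5 - 0.125, 4)
    frac = np.zeros(shape)
    for oy in sub:
        for ox in sub:
            frac += (xx + ox - center[0]) ** 2 + (yy + oy - center[1]) ** 2 <= radius_px**2
    img = background + contrast * frac / 16.0
    return gaussian_filter(img, blur_sigma)


def make_ellipse_image(
    a_px: float,
    b_px: float,
    angle_rad: float = 0.0,
    center=(24.0, 24.0),
    shape=(48, 48),
    background: float = 100.0,
    contrast: float = 80.0,
) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = (xx - center[0]) * ca + (yy - center[1]) * sa
    v = -(xx - center[0]) * sa + (yy - center[1]) * ca
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return gaussian_filter(background + contrast * inside, 1.0)


@pytest.fixture(scope="session")
def disk_image():
    return make_disk_image()


@pytest.fixture(scope="session")
def wt_scene():
    """Small rendered WT scene with well-separated foci (one per cell)."""
    return st.simulate_preset("WT", seed=11, n_cells=9, n_foci_per_cell=1)


@pytest.fixture(scope="session")
def wt_tracked(wt_scene):
    """(geometry, detections, tracks) tables from the WT scene."""
    cfg = st.PipelineConfig()
    geo, det, tracks = st.track_stack(wt_scene.stack, cfg)
    return geo, det, tracks
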