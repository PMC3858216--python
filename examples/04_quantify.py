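"""Single-cell quantifications: foci counts, stain area ratio, kymograph.

Counts detected foci per cell on a multi-focus scene (summarized the way
cluster-per-cell distributions are reported), scores a synthetic loose-coat
lectin stain against a compact one with the stain-area/cell-area ratio, and
builds a kymograph along the path of a moving focus (the stripe slope is the
focus speed in px/frame).
"""

import numpy as np
from scipy.ndimage import gaussian_filter

import sporetrack as st
from sporetrack.simulate import _add_gaussian_spot

# --- foci per cell ----------------------------------------------------------
scene = st.simulate_preset("WT", seed=5, n_cells=6, n_foci_per_cell=2, n_frames=8)
cfg = st.PipelineConfig()
geometry, detections, _ = st.track_stack(scene.stack, cfg)
geoms = st.segment_cells(np.median(scene.stack.astype(float), axis=0),
                         pixel_size=cfg.pixel_size, min_area_px=cfg.min_area_px)
frame0 = detections[detections.frame == 0]
table, summary = st.count_foci_per_cell(frame0, geoms)
print(f"foci/cell: mean {summary['mean']:.2f} ± {summary['sd']:.2f}, "
      f"max {summary['max']}, {summary['fraction_with_foci']:.0%} of "
      f"{summary['n_cells']} cells with >=1 focus")

# --- stain area ratio: compact vs loose coat --------------------------------
def disk_image(radius_factor):
    yy, xx = np.mgrid[0:32, 0:32]
    cell = gaussian_filter(
        100.0 + 80.0 * ((xx - 16.0) ** 2 + (yy - 16.0) ** 2 <= 7.5**2), 1.0
    )
    stain = np.full((32, 32), 50.0)
    stain[(xx - 16.0) ** 2 + (yy - 16.0) ** 2 <= (7.5 * radius_factor) ** 2] = 400.0
    return cell, stain

cell_img, compact_stain = disk_image(0.95)
_, loose_stain = disk_image(1.25)
geom = st.segment_cells(cell_img, min_area_px=30)[0]
compact = st.stain_area_ratio(compact_stain, geom)
loose = st.stain_area_ratio(loose_stain, geom)
print(f"stain area ratio: compact coat {compact.ratio:.2f} "
      f"(beyond mask: {compact.beyond_mask}), "
      f"loose coat {loose.ratio:.2f} (beyond mask: {loose.beyond_mask})")

# --- kymograph of a moving focus --------------------------------------------
stack = np.full((20, 30, 60), 100.0)
for f in range(20):
    _add_gaussian_spot(stack[f], 8.0 + 2.0 * f, 15.0, 500, 1.3)
path = st.ridge_path(stack)
kymo = st.make_kymograph(stack, path)
peaks = kymo.data.argmax(axis=1)
# the ridge path's orientation is arbitrary, so compare magnitudes
slope = abs(np.polyfit(np.arange(20), peaks, 1)[0])
print(f"kymograph: {kymo.data.shape[0]} frames x {kymo.data.shape[1]} samples, "
      f"stripe slope {slope:.2f} px/frame (true speed 2.00 px/frame)")
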