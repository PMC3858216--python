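"""Classify the three motion regimes from their MSD shapes.

Simulates 25 trajectories per condition — directed rotation (WT), frequent
reversals (exoA: directionality lost, MSD ≈ linear), and arrested jitter
(aglQ: MSD plateaus) — converts them to the tracker's spherical coordinates,
and calls the regime from the ensemble MSD.  α near 2 with a dominant
quadratic term means active directed transport; α ≈ 1 undirected random
motion; α ≈ 0 confinement.
"""

import numpy as np

import sporetrack as st
from sporetrack.tracking import Track

for preset in ("WT", "exoA", "aglQ"):
    ss = np.random.SeedSequence(99)
    tracks = []
    for i, child in enumerate(ss.spawn(25)):
        params = st.MotionParams(
            **st.PRESETS[preset], seed=int(child.generate_state(1)[0] % 2**31)
        )
        traj = st.simulate_surface_trajectory(params)
        pos = traj.positions
        r = np.hypot(pos[:, 0], pos[:, 1])
        tracks.append(Track(
            track_id=i, cell_id=0, frames=np.arange(params.n_frames),
            times=traj.times, p=params.p_true,
            theta=np.arctan2(pos[:, 1], pos[:, 0]),
            phi=np.arccos(np.clip(r / params.p_true, 0, 1)),
            intensity=np.ones(params.n_frames),
            x_px=pos[:, 0], y_px=pos[:, 1],
        ))
    curve, est, speeds = st.analyze_tracks(tracks)
    print(f"{preset:5s}: v={est.v:.3f} µm/min  D={est.D:.4f} µm²/min  "
          f"alpha={est.alpha:.2f}  -> {est.regime_call}")
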