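"""End-to-end parameter recovery: render → segment → detect → link → MSD fit.

Renders 25 cells carrying one directed focus each (the wild-type condition),
runs the full pipeline, and fits the ensemble mean-square displacement with
MSD(t) = 4·D·t + v²·t².  The fitted v and D estimate the transport speed and
the apparent surface diffusion of the foci; the regime call is based on the
log-log MSD slope α and the dominance of the quadratic term.
"""

import sporetrack as st

scene = st.simulate_preset("WT", seed=7, n_cells=25, n_foci_per_cell=1)
cfg = st.PipelineConfig()           # 0.1 µm/px, 0.5 min/frame, defaults

geometry, detections, tracks = st.track_stack(scene.stack, cfg)
report = st.analyze_tracks_table(tracks, cfg)

print(f"cells segmented : {len(geometry)}")
print(f"detections      : {len(detections)}")
print(f"tracks          : {report['n_tracks']} (paper-compliant ensemble: >=15)")
print(f"fitted v        : {report['v_um_per_min']:.3f} µm/min   (generative 0.120)")
print(f"fitted D        : {report['D_um2_per_min']:.4f} µm²/min (generative 0.0120)")
print(f"alpha           : {report['alpha']:.2f}")
print(f"median speed    : {report['median_speed_um_per_min']:.3f} µm/min "
      f"(observed band 0.1-0.3)")
print(f"regime          : {report['regime']}")
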