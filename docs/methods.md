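# Methods

## Coordinate model

A sporulating cell is modelled as a sphere of radius *p* (µm) whose center
and outline are measured from the image. A focus localized at planar
position (x, y) inside the cell is first expressed in polar coordinates:
r is the center-to-focus distance (µm) and θ the angle from the cell's
major axis, measured in the pixel frame (x along columns, y along rows,
positive from +x toward +y). Because foci sit on the sphere surface, the
planar radius determines the elevation: φ = arccos(r/p), so φ = 0 on the
projected boundary and φ = π/2 at the projected center. The distance
traveled between two surface points is the great-circle arc

    d = p·arccos(cosθ₁cosφ₁cosθ₂cosφ₂ + sinθ₁cosφ₁sinθ₂cosφ₂ + sinφ₁sinφ₂),

identically p times the angle between the unit vectors
n = (cosφ·cosθ, cosφ·sinθ, sinφ). An equivalent chord-lift route
(z = √(p²−r²), arc = 2p·arcsin(chord/2p)) is provided and agrees with the
trig formula to 1e-9; the tests verify both against an independent
dot-product oracle on 10⁴ random pairs.

**Hemisphere folding.** φ = arccos(r/p) is nonnegative: a single focal
plane cannot tell whether a focus is above or below it, so all foci are
treated as lying on one hemisphere. Steps that actually cross the equator
are underestimated (a reflection maps the far hemisphere onto the near one;
distances within one hemisphere are preserved, distances across are not).
This is a property of the measurement, deliberately not "corrected": its
main visible effect is a downward bias of ~25% on the fitted velocity of
trajectories on randomly oriented great circles (0.09 recovered for a
generative 0.12 µm/min), which stays within the ±0.05 µm/min uncertainty
such fits carry. Degenerate cases: a focus exactly at the center gets θ = 0
by convention; detections with r > p (localization noise outside the fitted
circle) are clamped to the boundary and counted in a per-track
`clamped_fraction` diagnostic.

**Major axis.** The θ = 0 reference is the principal axis of the mask's
second moments. Spheres have no intrinsic axis: below mask eccentricity
0.1 the axis is flagged degenerate and set to the x-axis — θ is then
arbitrary up to a global rotation, under which every orthodromic distance
is invariant, so all downstream statistics are unaffected. Axis endpoints
on elongated cells are chosen on the contour by a configurable weighted
score (curvature reward minus angular-deviation penalty, weights 1 : 1 by
default).

## Segmentation and contours

Cells are found by a global Otsu threshold computed on a 5×5
median-filtered copy of the frame (bright diffraction-limited foci occupy
so few pixels at such high amplitude that they would otherwise claim Otsu's
upper class and push the cell bodies below threshold). Each component's
subpixel boundary is extracted by marching squares on the *grayscale*
image at the half-contrast level (midpoint of background and component
interior medians) — on a blurred edge this lands on the true outline rather
than the binarization staircase. The boundary is smoothed with a periodic
cubic spline (residual target 0.1 px/point; larger targets visibly shrink
convex contours), resampled at 200 points, and stored with an exact
interpolating periodic spline. The sphere radius p is the mean
center-to-contour distance, reported with its SD as a circularity
diagnostic; the fit refuses cells with mask eccentricity above 0.25
(cell not yet rounded). On noiseless disks the fitted radius is accurate
to <0.1 px. The pipeline segments the time-median frame, which suppresses
moving foci while preserving cell bodies.

## Detection

Stacks are first normalized: each frame is divided by its background
estimate (median outside the per-frame Otsu mask) and rescaled to the first
frame's background, exactly inverting multiplicative illumination drift.
Candidate foci are local maxima of the PSF-matched (Gaussian, σ = PSF)
filtered, median-background-subtracted frame above k·σ_noise (k = 3
default), where σ_noise comes from adjacent-pixel differences — an
estimator immune to cell-body structure. The median background window
(~8×PSF σ) removes spots but follows body edges, avoiding rim ridges that a
Gaussian coarse background leaves. Maxima closer than the PSF FWHM are
merged keeping the brighter. Subpixel refinement fits a symmetric 2D
Gaussian plus constant-plus-tilt background in a 7×7 raw-image window
(the tilt term prevents spots on the cell-body rim gradient from being
pulled toward the bright side), with an intensity-weighted-centroid
fallback. Localization RMS on the rendered wild-type scenes is ≈0.07 px at
800 peak photons. Detections are assigned to the cell whose contour
contains them (or passes within 2 px); unassignable detections are dropped.

## Linking

Within each cell, consecutive frames are matched by the Hungarian algorithm
on the orthodromic-distance cost matrix, padded so that every detection and
every open track has a "no link" alternative at the gate cost; links longer
than the gate (default 0.45 µm = 3× the per-frame displacement at the upper
observed speed of 0.3 µm/min) are forbidden. The resulting matching
minimizes total arc length plus gate-cost per unmatched item, which the
tests verify against exhaustive enumeration for n ≤ 3. Unmatched detections
seed new tracks; optional gap closing (default off) keeps track ends alive
for a configurable number of frames with a proportionally scaled gate. Ties
are broken deterministically by input order, so runs are reproducible.

## Motion statistics

All displacements are orthodromic. Instantaneous speed is the arc step over
the frame interval; cumulated distance is the running sum of steps;
distance from origin is the arc to the first position (cumulated ≥
distance-from-origin frame-wise, always). The ensemble MSD is
time-averaged: per track, the squared arc displacement is averaged over all
frame pairs at each lag; the ensemble curve is the pair-count-weighted mean
across tracks, with lags up to half the longest track span (an
origin-referenced estimator is also available). Curves built from fewer
than 15 tracks are flagged non-compliant with the ensemble-size convention
used for such data.

The second-order model MSD(t) = 4·D·t + v²·t² is fitted by nonnegative
least squares on the basis {4t, t²}, weighted by pair counts, over the
**first half of the curve's lags**: on a sphere the arc distance saturates
at π·p, so including long lags flattens the curve and destroys the
quadratic term (full-range fits under-recover v by a factor ~3). An
optional constant offset (default off, since the model has no intercept)
can absorb static localization error. α is the log-log slope over the
first half of the *fitted* lags — the small-arc regime where the planar
conventions α = 1 (diffusive) and α = 2 (ballistic) apply; at longer lags
hemisphere folding drags even a genuinely diffusive walk below 1.

Regime calls: **arrested** if the MSD never exceeds a noise floor
(10⁻³ µm²); **subdiffusive** if α < 0.9; **directed** if α > 1.2 *and* the
fitted quadratic term v²t² supplies at least half the measured MSD at the
curve's last lag; otherwise **diffusive**. The α thresholds are declared
conventions; with them, classification accuracy on 25-track ensembles is
90–100% per regime across independent 20-seed batches.

## Synthetic scenes

The generator defines the study conditions; its defaults are fixed, not
tuned. Motion on the unit sphere uses exact geodesic advance
(angle v·dt/p per frame, direction parallel-transported) plus
tangent-plane Gaussian jitter (per-axis variance 2·D·dt) with radial
reprojection — valid for steps ≪ p; at the default step/p ratio of 0.2 the
reprojection shortens the per-step arc MSD by ~6%, within the 10% band the
diffusive calibration is held to. Regimes: *directed* (WT: v = 0.12 µm/min,
D = 0.012 µm²/min — the values such experiments report);
*directed_with_reversals* (exoA: same v and D, sense flipping as a Poisson
process at 2 min⁻¹ — the reversal rate is a declared choice, reversal
behavior being described only qualitatively); *arrested* (aglQ:
frame-independent jitter about a fixed anchor with D = 0.002 µm²/min,
producing the plateau MSD of paralyzed foci — free small-D diffusion would
instead give α ≈ 1); *diffusive* (tangent random walk). Geometry and
optics defaults: p = 0.75 µm, dt = 0.5 min, 60 frames, 0.1 µm/px,
PSF σ = 0.13 µm, 800 peak photons, background 100 counts with a 10%
one-cycle sinusoidal illumination drift multiplying the whole frame,
read noise SD 2, Lorentzian defocus dimming with 0.5 µm half-depth about an
equatorial focal plane, cell body rendered as a PSF-blurred disk at 80% of
background contrast. All randomness derives from a single seed through
`numpy.random.SeedSequence`, making stacks and truth tables bit-identical
across runs.

What the generator does *not* emulate: photobleaching, multi-cell crowding
and touching cells, z-stacks, camera gain/offset calibration, sample drift,
and real PSF asymmetries. Passing tests therefore demonstrate that the
measurement chain is correct under the stated imaging model, not that it is
robust to every artifact of real microscopy.

## Problem sizes and numerical choices

The validation runs use 25 cells × 1 focus × 60 frames for parameter
recovery (well-separated foci, matching the ensemble size the method
expects) and 20 seeds × 25 trajectories per regime for classification;
these sizes give stable estimates while keeping the whole suite fast.
Two random foci on one 1.5 µm sphere overlap in projection in roughly a
fifth of frames — resolving merged diffraction-limited spots is multi-emitter
fitting, explicitly out of scope — so multi-focus scenes are used for
counting and detection stress tests rather than for MSD calibration.
arccos round-off leaves ~10⁻⁸ µm residuals on identical points; tests and
degenerate-input handling use tolerances above that scale. All arccos/
arcsin arguments are clipped to [−1, 1] before evaluation.

## Known limitations

- Cross-hemisphere steps are underestimated (folding); v is biased low by
  roughly the amount quantified above for randomly oriented orbits, and
  exactly zero for orbits in the focal plane.
- The linker has no motion model; two foci that pass within the merge
  radius can swap identities. Validation scenes for fidelity use
  well-separated foci.
- Segmentation assumes isolated near-circular cells; touching cells are
  not split (no watershed) and elongated pre-spore cells are rejected by
  the sphere fit rather than measured.
- The MSD fit assumes the 4Dt + v²t² form; anomalous-transport models and
  confinement radii are not fitted.
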