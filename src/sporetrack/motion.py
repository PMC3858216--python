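"""Trajectory statistics: speeds, distances, MSD and motion classification.

For a focus moving on a sphere the displacement between two time points is
the orthodromic arc, so all statistics here are arc-based.  The ensemble
mean-square displacement of directed surface transport follows

    MSD(t) = 4·D·t + v²·t²,

with v the mean velocity and D the apparent (2D surface) diffusion
coefficient; the two are separated by a nonnegative least-squares fit on the
basis {4t, t²}.  The log-log MSD slope α distinguishes subdiffusive
(α < 0.9), diffusive (α ≈ 1) and directed (α > 1.2, quadratic-dominated)
regimes; trajectories whose MSD never leaves the noise floor are called
arrested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .tracking import Track, arc_distances

MIN_TRACKS_COMPLIANT = 15   # ensemble curves from fewer tracks are flagged


@dataclass
class MSDCurve:
    """Ensemble (pair-count weighted) time-averaged MSD curve."""

    lag_times: np.ndarray     # (L,) min, excludes lag 0
    msd: np.ndarray           # (L,) µm²
    n_pairs: np.ndarray       # (L,) displacement pairs per lag
    n_tracks: int
    compliant: bool           # n_tracks >= MIN_TRACKS_COMPLIANT


@dataclass
class MotionEstimate:
    """Result of the second-order MSD fit."""

    v: float                  # µm·min⁻¹
    D: float                  # µm²·min⁻¹
    residual: float           # weighted RMS of the fit
    alpha: float              # log-log MSD slope over the first half of fitted lags
    regime_call: str | None = None
    fit_lag_max: float = 0.0  # largest lag (min) used by the fit


def _step_distances(track: Track, lag: int = 1) -> np.ndarray:
    """Orthodromic distances between positions ``lag`` frames apart.

    Gaps are respected: only pairs whose frame indices differ by exactly
    ``lag`` contribute.
    """
    frames = track.frames
    idx = {int(f): i for i, f in enumerate(frames)}
    a, b = [], []
    for f, i in idx.items():
        j = idx.get(f + lag)
        if j is not None:
            a.append(i)
            b.append(j)
    if not a:
        return np.empty(0)
    a, b = np.array(a), np.array(b)
    return arc_distances(
        track.theta[a], track.phi[a], track.theta[b], track.phi[b], track.p
    )


def instantaneous_speeds(track: Track) -> np.ndarray:
    """Arc displacement over time difference for each consecutive frame pair."""
    if len(track) < 2:
        raise ValueError("track needs at least 2 points")
    u = track.unit_vectors()
    cosd = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    dists = track.p * np.arccos(cosd)
    dts = np.diff(track.times)
    return dists / dts


def distance_from_origin(track: Track) -> np.ndarray:
    """Orthodromic distance of every position to the track's first position."""
    u = track.unit_vectors()
    cosd = np.clip(u @ u[0], -1.0, 1.0)
    return track.p * np.arccos(cosd)


def cumulated_distance(track: Track) -> np.ndarray:
    """Running sum of consecutive orthodromic steps (path length), per frame."""
    u = track.unit_vectors()
    cosd = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    steps = track.p * np.arccos(cosd)
    return np.concatenate([[0.0], np.cumsum(steps)])


def compute_msd(
    tracks: list[Track],
    max_lag_fraction: float = 0.5,
    mode: str = "time_averaged",
) -> MSDCurve:
    """Ensemble MSD from orthodromic displacements.

    ``time_averaged`` (default): per track, the MSD at lag k averages the
    squared arc displacement over *all* frame pairs k apart; the ensemble
    curve is the pair-count-weighted mean across tracks.  ``origin``: only
    displacements from each track's first position contribute.  Lags run up
    to ``max_lag_fraction`` of the longest track's span.
    """
    if not tracks:
        raise ValueError("no tracks")
    if mode not in ("time_averaged", "origin"):
        raise ValueError("mode must be 'time_averaged' or 'origin'")
    dts = [np.diff(t.times) for t in tracks if len(t) > 1]
    dt = float(np.min([d.min() for d in dts]))
    span = max(int(t.frames[-1] - t.frames[0]) for t in tracks)
    max_lag = max(int(np.floor(span * max_lag_fraction)), 1)

    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for t in tracks:
        if len(t) < 3:
            continue
        if mode == "time_averaged":
            for k in range(1, max_lag + 1):
                d = _step_distances(t, lag=k)
                if d.size:
                    sums[k - 1] += np.sum(d**2)
                    counts[k - 1] += d.size
        else:
            d = distance_from_origin(t)
            lags = (t.frames - t.frames[0]).astype(int)
            for lag, dist in zip(lags[1:], d[1:]):
                if 1 <= lag <= max_lag:
                    sums[lag - 1] += dist**2
                    counts[lag - 1] += 1
    valid = counts > 0
    n_tracks = sum(1 for t in tracks if len(t) >= 3)
    return MSDCurve(
        lag_times=(np.arange(1, max_lag + 1) * dt)[valid],
        msd=np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)[valid],
        n_pairs=counts[valid],
        n_tracks=n_tracks,
        compliant=n_tracks >= MIN_TRACKS_COMPLIANT,
    )


def _loglog_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Slope of log(msd) vs log(t)."""
    ok = (y > 0) & (t > 0)
    if ok.sum() < 2:
        return 0.0
    return float(np.polyfit(np.log(t[ok]), np.log(y[ok]), 1)[0])


def fit_msd_directed(
    curve: MSDCurve,
    include_offset: bool = False,
    fit_lag_fraction: float = 0.5,
) -> MotionEstimate:
    """Second-order MSD fit: msd(t) = 4·D·t + v²·t² (nonnegative D, v²).

    Weighted (by pair counts) nonnegative least squares on the basis
    {4t, t²} over the first ``fit_lag_fraction`` of the curve's lags —
    restricting the fit keeps it in the small-arc regime where the
    quadratic law holds on a sphere (at large lags the arc distance
    saturates at π·p and the curve flattens).  With ``include_offset`` an
    additional constant term absorbs static localization error.  α is the
    log-log slope over the same lag range.  An all-zero curve returns
    v = D = 0.
    """
    if len(curve.lag_times) < 4:
        raise ValueError("need at least 4 lag points for the second-order fit")
    n_fit = max(int(np.ceil(len(curve.lag_times) * fit_lag_fraction)), 4)
    t = curve.lag_times[:n_fit]
    y = curve.msd[:n_fit]
    npairs = curve.n_pairs[:n_fit]
    if np.all(y == 0):
        return MotionEstimate(v=0.0, D=0.0, residual=0.0, alpha=0.0,
                              fit_lag_max=float(t[-1]))
    w = np.sqrt(npairs / npairs.sum())
    cols = [4.0 * t, t**2]
    if include_offset:
        cols.append(np.ones_like(t))
    A = np.column_stack(cols) * w[:, None]
    b = y * w
    coef, rnorm = nnls(A, b)
    D, v2 = coef[0], coef[1]
    # alpha from the first half of the fitted lags: small arcs, where the
    # planar log-log slope conventions (1 = diffusive, 2 = ballistic) apply
    n_alpha = max(len(t) // 2, 2)
    return MotionEstimate(
        v=float(np.sqrt(v2)),
        D=float(D),
        residual=float(rnorm / np.sqrt(len(t))),
        alpha=_loglog_slope(t[:n_alpha], y[:n_alpha]),
        fit_lag_max=float(t[-1]),
    )


NOISE_FLOOR_UM2 = 1e-3      # MSD below this everywhere → arrested
ALPHA_SUBDIFFUSIVE = 0.9
ALPHA_DIRECTED = 1.2


def classify_motion(
    estimate: MotionEstimate,
    curve: MSDCurve,
    noise_floor: float = NOISE_FLOOR_UM2,
    alpha_sub: float = ALPHA_SUBDIFFUSIVE,
    alpha_dir: float = ALPHA_DIRECTED,
) -> str:
    """Call the motion regime from the fitted MSD.

    arrested — MSD never exceeds the noise floor; subdiffusive — α below
    ``alpha_sub``; directed — α above ``alpha_dir`` *and* the quadratic
    (v²t²) term supplies at least half the measured MSD at the last fitted
    lag; otherwise diffusive.
    """
    if curve.msd.size == 0 or curve.msd.max() < noise_floor:
        estimate.regime_call = "arrested"
        return "arrested"
    if estimate.alpha < alpha_sub:
        estimate.regime_call = "subdiffusive"
        return "subdiffusive"
    t_last = curve.lag_times[-1]
    quad = estimate.v**2 * t_last**2
    if estimate.alpha > alpha_dir and quad >= 0.5 * curve.msd[-1]:
        estimate.regime_call = "directed"
        return "directed"
    estimate.regime_call = "diffusive"
    return "diffusive"


def analyze_tracks(
    tracks: list[Track],
    max_lag_fraction: float = 0.5,
    min_track_length: int = 3,
) -> tuple[MSDCurve, MotionEstimate, np.ndarray]:
    """Convenience wrapper: filter, MSD, fit, classify.

    Returns the ensemble curve, the classified estimate and the pooled
    instantaneous speeds of all usable tracks.
    """
    usable = [t for t in tracks if len(t) >= max(min_track_length, 3)]
    if not usable:
        raise ValueError("no tracks of sufficient length")
    curve = compute_msd(usable, max_lag_fraction=max_lag_fraction)
    est = fit_msd_directed(curve)
    classify_motion(est, curve)
    speeds = np.concatenate([instantaneous_speeds(t) for t in usable])
    return curve, est, speeds
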