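"""Spherical coordinates, orthodromic distances, linking."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sporetrack as st
from sporetrack.tracking import (
    SphericalCoordinate,
    _assignment,
    arc_distances,
    wrap_angle,
)


class XY:
    def __init__(self, x, y):
        self.x = x
        self.y = y


def dot_product_arc_oracle(a: SphericalCoordinate, b: SphericalCoordinate) -> float:
    """Independent 3D route: d = p·arccos(n_a · n_b)."""
    def n(c):
        return np.array(
            [
                np.cos(c.phi) * np.cos(c.theta),
                np.cos(c.phi) * np.sin(c.theta),
                np.sin(c.phi),
            ]
        )

    return a.p * np.arccos(np.clip(np.dot(n(a), n(b)), -1, 1))


def random_coords(rng, n, p):
    theta = rng.uniform(-np.pi, np.pi, n)
    phi = rng.uniform(0, np.pi / 2, n)
    return [SphericalCoordinate(p=p, theta=t, phi=f) for t, f in zip(theta, phi)]


class TestPolar:
    def test_focus_at_center(self):
        g = _geom(center=(10, 10), axis=0.0)
        pol = st.to_polar(XY(10, 10), g, pixel_size=0.1)
        assert pol.r == 0.0 and pol.theta == 0.0

    def test_focus_on_axis_ray(self):
        g = _geom(center=(10, 10), axis=0.0)
        pol = st.to_polar(XY(15, 10), g, pixel_size=0.1)
        assert pol.r == pytest.approx(0.5)
        assert pol.theta == pytest.approx(0.0)

    def test_quarter_turn_has_theta_pi_over_2(self):
        g = _geom(center=(10, 10), axis=0.0)
        pol = st.to_polar(XY(10, 15), g, pixel_size=0.1)  # +y direction
        assert pol.theta == pytest.approx(np.pi / 2)

    def test_theta_measured_from_major_axis(self):
        g = _geom(center=(0, 0), axis=np.pi / 4)
        pol = st.to_polar(XY(1, 1), g, pixel_size=1.0)
        assert pol.theta == pytest.approx(0.0, abs=1e-12)


class TestSpherical:
    @pytest.mark.parametrize(
        "r_frac,phi_expected",
        [(1.0, 0.0), (0.0, np.pi / 2), (0.5, np.pi / 3)],
    )
    def test_phi_arccos_relation(self, r_frac, phi_expected):
        from sporetrack.tracking import PolarCoordinate

        sph = st.to_spherical(PolarCoordinate(r=r_frac * 0.75, theta=0.3), p=0.75)
        assert sph.phi == pytest.approx(phi_expected)
        assert sph.theta == 0.3
        assert not sph.clamped

    def test_r_beyond_p_clamped_and_flagged(self):
        from sporetrack.tracking import PolarCoordinate

        sph = st.to_spherical(PolarCoordinate(r=0.8, theta=0.0), p=0.75)
        assert sph.clamped and sph.phi == 0.0


class TestOrthodromicDistance:
    def test_identical_points_zero(self):
        a = SphericalCoordinate(p=0.75, theta=0.4, phi=0.2)
        assert st.orthodromic_distance(a, a) == 0.0

    def test_antipodal_on_equator(self):
        a = SphericalCoordinate(p=1.0, theta=0.0, phi=0.0)
        b = SphericalCoordinate(p=1.0, theta=np.pi, phi=0.0)
        assert st.orthodromic_distance(a, b) == pytest.approx(np.pi)

    def test_worked_example_against_dot_product_oracle(self):
        a = SphericalCoordinate(p=0.5, theta=0.0, phi=0.0)
        b = SphericalCoordinate(p=0.5, theta=np.pi / 3, phi=np.pi / 6)
        d = st.orthodromic_distance(a, b)
        assert d == pytest.approx(0.5615, abs=5e-4)
        assert d == pytest.approx(dot_product_arc_oracle(a, b), abs=1e-12)

    def test_mismatched_radii_rejected(self):
        a = SphericalCoordinate(p=0.75, theta=0.0, phi=0.0)
        b = SphericalCoordinate(p=0.80, theta=0.0, phi=0.0)
        with pytest.raises(ValueError, match="cross-cell"):
            st.orthodromic_distance(a, b)

    def test_three_route_equivalence_on_random_pairs(self):
        """Trig formula ≡ 3D dot product ≡ chord lift, 10⁴ pairs, 1e-9."""
        rng = np.random.default_rng(0)
        p, ps = 0.75, 0.1
        coords = random_coords(rng, 20_000, p)
        center = (50.0, 50.0)
        for a, b in zip(coords[::2], coords[1::2]):
            d_trig = st.orthodromic_distance(a, b)
            d_dot = dot_product_arc_oracle(a, b)
            xy_a = (
                center[0] + a.p * np.cos(a.phi) * np.cos(a.theta) / ps,
                center[1] + a.p * np.cos(a.phi) * np.sin(a.theta) / ps,
            )
            xy_b = (
                center[0] + b.p * np.cos(b.phi) * np.cos(b.theta) / ps,
                center[1] + b.p * np.cos(b.phi) * np.sin(b.theta) / ps,
            )
            d_chord = st.euclidean_to_orthodromic(xy_a, xy_b, center, p, ps)
            assert abs(d_trig - d_dot) < 1e-9
            assert abs(d_trig - d_chord) < 1e-9

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(1)
        p = 0.6
        coords = random_coords(rng, 3_000, p)
        for a, b, c in zip(coords[::3], coords[1::3], coords[2::3]):
            dab = st.orthodromic_distance(a, b)
            dba = st.orthodromic_distance(b, a)
            dac = st.orthodromic_distance(a, c)
            dcb = st.orthodromic_distance(c, b)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= np.pi * p + 1e-12
            assert dab <= dac + dcb + 1e-9

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        coords = random_coords(rng, 40, 0.75)
        a, b = coords[:20], coords[20:]
        vec = arc_distances(
            np.array([c.theta for c in a]),
            np.array([c.phi for c in a]),
            np.array([c.theta for c in b]),
            np.array([c.phi for c in b]),
            0.75,
        )
        scal = [st.orthodromic_distance(x, y) for x, y in zip(a, b)]
        assert np.allclose(vec, scal, atol=1e-12)


class TestChordLift:
    def test_coincident_points(self):
        assert st.euclidean_to_orthodromic((5, 5), (5, 5), (0, 0), 0.75, 0.1) == 0.0

    def test_diametrically_opposite_boundary_points(self):
        d = st.euclidean_to_orthodromic((17.5, 10), (2.5, 10), (10, 10), 0.75, 0.1)
        assert d == pytest.approx(np.pi * 0.75, abs=1e-9)


def brute_force_assignment_oracle(cost, gate):
    """Enumerate all partial injections; minimize link cost + gate per unmatched."""
    n, m = cost.shape
    best, best_val = [], n * gate + m * gate
    rows = list(range(n))
    for k in range(0, min(n, m) + 1):
        for rsub in itertools.combinations(rows, k):
            for csub in itertools.permutations(range(m), k):
                if any(cost[r, c] > gate for r, c in zip(rsub, csub)):
                    continue
                val = sum(cost[r, c] for r, c in zip(rsub, csub))
                val += gate * (n - k) + gate * (m - k)
                if val < best_val - 1e-12:
                    best_val = val
                    best = sorted(zip(rsub, csub))
    return best, best_val


class TestLinking:
    def test_single_detection_per_frame_single_track(self):
        det = _detections([[(12, 10)], [(12.5, 10)], [(13, 10)]])
        tracks = st.link_tracks(det, [_geom()], pixel_size=0.1, dt=0.5)
        assert len(tracks) == 1
        assert len(tracks[0]) == 3

    def test_well_separated_foci_no_switches(self, wt_scene, wt_tracked):
        """Links on a well-separated scene match ground truth exactly."""
        geo, det, tracks = wt_tracked
        truth = wt_scene.truth_table()
        bad = 0
        total = 0
        for tid, g in tracks.groupby("track_id"):
            g = g.sort_values("frame")
            ids = []
            for _, row in g.iterrows():
                tf = truth[truth.frame == row.frame]
                d = np.hypot(tf.x_px - row.x_px, tf.y_px - row.y_px)
                ids.append(int(tf.focus_id.iloc[d.argmin()]))
            total += len(ids) - 1
            bad += int((np.diff(ids) != 0).sum())
        assert total > 0
        assert bad == 0

    def test_assignment_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(200):
            n, m = rng.integers(1, 4, size=2)
            cost = rng.uniform(0, 1, size=(n, m))
            gate = 0.6
            got = sorted(_assignment(cost, gate))
            _, oracle_val = brute_force_assignment_oracle(cost, gate)
            got_val = sum(cost[r, c] for r, c in got)
            got_val += gate * (n - len(got)) + gate * (m - len(got))
            assert got_val == pytest.approx(oracle_val, abs=1e-6)

    def test_track_ids_deterministic(self):
        det = _detections(
            [[(12, 10), (10, 13)], [(12.4, 10), (10, 13.4)], [(12.8, 10), (10, 13.8)]]
        )
        t1 = st.tracks_table(st.link_tracks(det, [_geom()], 0.1, 0.5))
        t2 = st.tracks_table(st.link_tracks(det, [_geom()], 0.1, 0.5))
        pd.testing.assert_frame_equal(t1, t2)

    def test_gap_closing_bridges_missed_frame(self):
        det = _detections([[(12, 10)], [], [(13, 10)]])
        no_gap = st.link_tracks(det, [_geom()], 0.1, 0.5, max_gap_frames=0, min_length=1)
        with_gap = st.link_tracks(det, [_geom()], 0.1, 0.5, max_gap_frames=1, min_length=1)
        assert len(no_gap) == 2
        assert len(with_gap) == 1 and len(with_gap[0]) == 2

    def test_table_round_trip(self, wt_tracked):
        _, _, tracks = wt_tracked
        rebuilt = st.tracks_table(st.tracks_from_table(tracks))
        pd.testing.assert_frame_equal(
            tracks.reset_index(drop=True), rebuilt.reset_index(drop=True)
        )


def test_wrap_angle_range():
    a = wrap_angle(np.linspace(-10, 10, 1001))
    assert (a > -np.pi).all() and (a <= np.pi).all()
    assert wrap_angle(np.pi) == pytest.approx(np.pi)
    assert wrap_angle(-np.pi) == pytest.approx(np.pi)


# --- helpers ---------------------------------------------------------------


class _FakeContour:
    def __init__(self, center, r):
        ang = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        self.points = np.column_stack(
            [center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)]
        )


def _geom(center=(10.0, 10.0), axis=0.0, p_um=0.75, r_px=7.5):
    from sporetrack.geometry import CellGeometry

    g = CellGeometry.__new__(CellGeometry)
    g.cell_id = 0
    g.center = center
    g.p_um = p_um
    g.major_axis_angle = axis
    g.eccentricity = 0.0
    g.contour = _FakeContour(center, r_px)
    g.axis_degenerate = True
    return g


def _detections(frames):
    rows = []
    for f, dets in enumerate(frames):
        for x, y in dets:
            rows.append(
                {
                    "frame": f,
                    "time_min": f * 0.5,
                    "cell_id": 0,
                    "x_px": x,
                    "y_px": y,
                    "intensity": 100.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["frame", "time_min", "cell_id", "x_px", "y_px", "intensity"]
    )


# hypothesis property checks: coordinate invariants hold for any input
from hypothesis import given, settings, strategies as hst


@settings(max_examples=200, deadline=None)
@given(
    r=hst.floats(min_value=0.0, max_value=5.0, allow_nan=False),
    theta=hst.floats(min_value=-3.2, max_value=3.2, allow_nan=False),
    p=hst.floats(min_value=0.1, max_value=3.0, allow_nan=False),
)
def test_to_spherical_invariants(r, theta, p):
    from sporetrack.tracking import PolarCoordinate

    sph = st.to_spherical(PolarCoordinate(r=r, theta=theta), p=p)
    assert 0.0 <= sph.phi <= np.pi / 2
    assert sph.clamped == (r > p)
    if r <= p:
        # round trip: r = p cos(phi)
        assert p * np.cos(sph.phi) == pytest.approx(r, abs=1e-9)


@settings(max_examples=200, deadline=None)
@given(
    t1=hst.floats(-np.pi, np.pi), f1=hst.floats(0, np.pi / 2),
    t2=hst.floats(-np.pi, np.pi), f2=hst.floats(0, np.pi / 2),
)
def test_orthodromic_bounds_and_identity(t1, f1, t2, f2):
    a = SphericalCoordinate(p=0.75, theta=t1, phi=f1)
    b = SphericalCoordinate(p=0.75, theta=t2, phi=f2)
    d = st.orthodromic_distance(a, b)
    assert 0.0 <= d <= np.pi * 0.75 + 1e-12
    assert st.orthodromic_distance(a, a) <= 1e-7
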