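import numpy as np
import pytest

from actinshape.frames import FilamentFrame
from actinshape.geometry import (HelixGeometry, build_ideal_helix,
                                 generate_parametric_shape)
from actinshape.metrics import (compression_metrics, monomers_to_axis,
                                non_coplanarity, normalized_time,
                                peak_asymmetry, persistence_length,
                                resample_polyline, supertwist_angle,
                                unwrap_angles)
from conftest import random_rotation


class TestResample:
    def test_uniform_spacing_on_straight_line(self, straight_rod):
        out = resample_polyline(straight_rod, 51)
        assert np.allclose(np.diff(out.points[:, 0]), 10.0)

    def test_endpoints_preserved_exactly(self, right_coil):
        out = resample_polyline(right_coil, 37)
        assert np.array_equal(out.points[0], right_coil.points[0])
        assert np.array_equal(out.points[-1], right_coil.points[-1])

    def test_idempotent_on_uniform_chain(self, straight_rod):
        once = resample_polyline(straight_rod, 50)
        twice = resample_polyline(once, 50)
        assert np.allclose(once.points, twice.points, atol=1e-9)

    def test_contour_length_converges_for_semicircle(self):
        # dense parametric semicircle as arc-length oracle
        t = np.linspace(0.0, np.pi, 2000)
        pts = np.column_stack([100 * np.cos(t), 100 * np.sin(t),
                               np.zeros_like(t)])
        dense = FilamentFrame(pts[::-1])
        out = resample_polyline(dense, 50)
        assert out.contour_length == pytest.approx(np.pi * 100, rel=0.01)


class TestAxisSmoothing:
    def test_helix_beads_collapse_to_axis(self):
        frame = build_ideal_helix(HelixGeometry(n_subunits=60))
        axis = monomers_to_axis(frame, window=13)
        assert axis.is_axis_curve
        # true axis is the x-axis; residual transverse wiggle is tiny
        # relative to the 2.5 nm bead radius
        assert np.abs(axis.points[:, 1:]).max() < 0.2

    def test_point_count_reduced_by_window_minus_one(self):
        frame = build_ideal_helix(HelixGeometry(n_subunits=40))
        axis = monomers_to_axis(frame, window=11)
        assert axis.n_points == 40 - 10

    def test_collinear_chain_unchanged(self, straight_rod):
        axis = monomers_to_axis(straight_rod, window=5)
        assert np.allclose(axis.points[:, 1:], 0.0)

    def test_window_larger_than_chain_rejected(self, straight_rod):
        with pytest.raises(ValueError, match="window"):
            monomers_to_axis(straight_rod, window=51)


class TestCompressionMetrics:
    def test_target_state_ratio(self):
        pts = np.zeros((10, 3))
        pts[:, 0] = np.linspace(0, 350.0, 10)
        e2e, cr = compression_metrics(FilamentFrame(pts), 500.0)
        assert e2e == pytest.approx(350.0)
        assert cr == pytest.approx(0.30)

    def test_uncompressed_is_zero(self, straight_rod):
        _, cr = compression_metrics(straight_rod, 500.0)
        assert cr == pytest.approx(0.0)

    def test_rigid_motion_invariance(self, planar_arc, rng):
        R = random_rotation(rng)
        moved = planar_arc.rotated(R).translated([11.0, -5.0, 3.0])
        e1, c1 = compression_metrics(planar_arc, 500.0)
        e2, c2 = compression_metrics(moved, 500.0)
        assert e1 == pytest.approx(e2)
        assert c1 == pytest.approx(c2)


class TestPeakAsymmetry:
    def test_symmetric_arc_is_zero(self, planar_arc):
        assert peak_asymmetry(planar_arc) == pytest.approx(0.0, abs=0.03)

    def test_straight_rod_defined_as_zero(self, straight_rod):
        assert peak_asymmetry(straight_rod) == 0.0

    def test_bump_at_quarter_arc_gives_half(self):
        # deviation maximal at 1/4 of the chain: |2 s* - 1| = 0.5
        n = 401
        x = np.linspace(0.0, 400.0, n)
        y = np.zeros(n)
        bump = np.abs(x - 100.0) < 60.0
        y[bump] = 5.0 * np.cos((x[bump] - 100.0) / 60.0 * np.pi / 2) ** 2
        frame = FilamentFrame(np.column_stack([x, y, np.zeros(n)]))
        assert peak_asymmetry(frame) == pytest.approx(0.5, abs=0.02)

    def test_mirror_invariance(self, right_coil):
        assert peak_asymmetry(right_coil.mirrored()) == pytest.approx(
            peak_asymmetry(right_coil))


class TestNonCoplanarity:
    def test_planar_curves_are_zero(self, planar_arc):
        assert non_coplanarity(planar_arc) == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_cross_reaches_upper_bound(self):
        pts = np.array([[1.0, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        assert non_coplanarity(FilamentFrame(pts)) == pytest.approx(1.0 / 3)

    def test_matches_direct_eigendecomposition(self, rng):
        pts = rng.normal(size=(40, 3)).cumsum(axis=0)
        frame = FilamentFrame(pts)
        centred = pts - pts.mean(axis=0)
        lam = np.linalg.eigvalsh(centred.T @ centred / 40)
        assert non_coplanarity(frame) == pytest.approx(lam[0] / lam.sum())

    def test_range_and_rotation_invariance(self, right_coil, rng):
        nc = non_coplanarity(right_coil)
        assert 0.0 < nc <= 1.0 / 3
        rot = right_coil.rotated(random_rotation(rng))
        assert non_coplanarity(rot) == pytest.approx(nc, abs=1e-10)


class TestSupertwist:
    def test_straight_filament_flagged_missing(self, straight_rod):
        assert np.isnan(supertwist_angle(straight_rod))

    def test_planar_arc_is_zero_or_pi_free(self, planar_arc):
        # symmetric planar arc: tangents tilt within the bend plane only,
        # so the projections are (anti)parallel -> 0 or +/-180, never a
        # partial winding
        ang = supertwist_angle(planar_arc)
        assert min(abs(ang), abs(abs(ang) - 180.0)) < 1e-6

    @pytest.mark.parametrize("winding", [60.0, -60.0, 150.0])
    def test_coil_matches_analytic_winding(self, winding):
        coil = generate_parametric_shape("helical_coil", length_nm=350.0,
                                         coil_radius_nm=40.0,
                                         winding_deg=winding, n_points=200)
        # a sampled coil's end segments are chords whose azimuth sits at the
        # segment midpoint, so the exact chord-winding is psi*(n-2)/(n-1)
        exact_chord = winding * 198.0 / 199.0
        assert supertwist_angle(coil) == pytest.approx(exact_chord, abs=1e-9)
        assert supertwist_angle(coil) == pytest.approx(winding,
                                                       rel=2.0 / 200.0)

    def test_mirror_antisymmetry(self, right_coil):
        st = supertwist_angle(right_coil)
        assert supertwist_angle(right_coil.mirrored()) == pytest.approx(-st)

    def test_corotated_axis_invariance(self, right_coil, rng):
        R = random_rotation(rng)
        st0 = supertwist_angle(right_coil)
        st1 = supertwist_angle(right_coil.rotated(R), axis_direction=R[:, 0])
        assert st1 == pytest.approx(st0, abs=1e-8)

    def test_supertwist_implies_non_coplanarity(self, right_coil):
        assert abs(supertwist_angle(right_coil)) > 1.0
        assert non_coplanarity(right_coil) > 0.0

    def test_unwrap_tracks_accumulated_coiling(self):
        series = np.array([10.0, 90.0, 170.0, -150.0, -70.0, np.nan, 20.0])
        out = unwrap_angles(series)
        assert np.allclose(out[[0, 1, 2, 3, 4, 6]],
                           [10.0, 90.0, 170.0, 210.0, 290.0, 380.0])
        assert np.isnan(out[5])


class TestNormalizedTime:
    def test_total_time_of_protocol(self):
        from actinshape.dynamics import CompressionProtocol
        prot = CompressionProtocol(velocity=15.0, initial_end_to_end=500.0,
                                   compression_fraction=0.7)
        assert prot.total_time == pytest.approx(0.010)  # 10 ms
        t = normalized_time(np.array([0.0, 0.005, 0.010, 0.02]), prot)
        assert np.allclose(t, [0.0, 0.5, 1.0, 1.0])


class TestPersistenceLength:
    def test_recovers_exact_exponential_decay(self):
        """Synthetic planar tangent walk with exact exp(-s/Lp) correlation.

        A 2D random walk of tangent angles with independent Gaussian
        increments has <t(s).t(s+ds)> = exp(-ds/(2 Lp2d)); matching the 3D
        worm-like-chain convention used by the estimator gives a clean
        oracle for the log-linear fit.
        """
        lp_nm = 10_000.0
        ds = 10.0
        n_seg = 60
        rng = np.random.default_rng(7)
        frames = []
        for _ in range(300):
            # 3D tangents: two transverse angle walks, variance ds/Lp each
            th = rng.normal(scale=np.sqrt(ds / lp_nm), size=(n_seg, 2))
            ang = np.cumsum(th, axis=0)
            t = np.column_stack([np.cos(ang[:, 0]) * np.cos(ang[:, 1]),
                                 np.sin(ang[:, 0]) * np.cos(ang[:, 1]),
                                 np.sin(ang[:, 1])])
            pts = np.vstack([[0.0, 0.0, 0.0], np.cumsum(ds * t, axis=0)])
            frames.append(FilamentFrame(pts))
        est = persistence_length([frames], max_lag=20)
        assert est.Lp == pytest.approx(10.0, rel=0.05)   # um

    def test_rigid_rod_flagged_infinite(self, straight_rod):
        est = persistence_length([[straight_rod] * 3])
        assert est.infinite
        assert "rigid" in est.summary()
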