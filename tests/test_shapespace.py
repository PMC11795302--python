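import numpy as np
import pandas as pd
import pytest

from actinshape.frames import FilamentFrame
from actinshape.geometry import generate_parametric_shape
from actinshape.metrics import (non_coplanarity, peak_asymmetry,
                                supertwist_angle)
from actinshape.shapespace import (ShapeSample, ShapeSpacePCA,
                                   align_filament)


def compression_family(n_shapes=40, n_points=50, noise=0.0, rng=None):
    """Synthetic family whose only mode is compression.

    Straight chains whose end-to-end distance shrinks linearly with the
    compression ratio: exactly one linear shape mode, so PCA must place
    all variance in PC1 and the PC1 score is an affine function of the
    compression ratio.
    """
    shapes, ratios = [], []
    for i in range(n_shapes):
        cr = 0.02 + 0.4 * i / (n_shapes - 1)
        rod = generate_parametric_shape("straight",
                                        length_nm=500.0 * (1 - cr),
                                        n_points=n_points)
        pts = rod.points
        if noise and rng is not None:
            pts = pts + rng.normal(scale=noise, size=pts.shape)
        shapes.append(pts)
        ratios.append(cr)
    return shapes, np.asarray(ratios)


class TestAlignment:
    def test_rotates_bulge_to_positive_y(self):
        arc = generate_parametric_shape("planar_arc", height_nm=80.0)
        # move the bulge into +z
        rot = arc.points.copy()
        rot[:, 2] = arc.points[:, 1]
        rot[:, 1] = 0.0
        frame = FilamentFrame(rot)
        aligned = align_filament(frame)
        assert np.allclose(aligned.points[:, 2], 0.0, atol=1e-9)
        assert aligned.points[:, 1].max() > 70.0

    def test_idempotent(self):
        arc = generate_parametric_shape("planar_arc", height_nm=80.0)
        once = align_filament(arc)
        twice = align_filament(once)
        assert np.allclose(once.points, twice.points, atol=1e-12)

    def test_x_axis_chain_returns_identity(self, straight_rod):
        aligned = align_filament(straight_rod)
        assert np.allclose(aligned.points, straight_rod.points)

    def test_preserves_x_arclength_endtoend_and_achiral_metrics(
            self, right_coil):
        aligned = align_filament(right_coil)
        assert np.allclose(aligned.points[:, 0], right_coil.points[:, 0])
        assert aligned.contour_length == pytest.approx(
            right_coil.contour_length)
        assert aligned.end_to_end == pytest.approx(right_coil.end_to_end)
        assert non_coplanarity(aligned) == pytest.approx(
            non_coplanarity(right_coil), abs=1e-12)
        assert peak_asymmetry(aligned) == pytest.approx(
            peak_asymmetry(right_coil), abs=1e-12)

    def test_preserves_supertwist_sign_on_coils(self, right_coil):
        st0 = supertwist_angle(right_coil)
        st1 = supertwist_angle(align_filament(right_coil))
        assert st1 == pytest.approx(st0, abs=1e-9)


class TestShapeSpace:
    def _fit(self, noise=0.0):
        rng = np.random.default_rng(0)
        shapes, ratios = compression_family(noise=noise, rng=rng)
        samples = [ShapeSample(aligned_points=s, source="monomer",
                               velocity=15.0, replicate=0,
                               normalized_time=r / 0.42)
                   for s, r in zip(shapes, ratios)]
        metrics = pd.DataFrame({
            "compression_ratio": ratios,
            "supertwist_angle": np.nan,
            "non_coplanarity": 0.0,
            "peak_asymmetry": 0.0,
            "normalized_time": ratios / 0.42})
        model = ShapeSpacePCA(samples, metrics, n_components=5)
        return model.fit(), ratios

    def test_single_mode_family_concentrates_in_pc1(self):
        res, _ = self._fit()
        assert res.explained_variance_ratio[0] > 0.99
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_pc1_sign_fixed_to_compression(self):
        res, ratios = self._fit()
        scores = res.project()
        r = np.corrcoef(scores["PC1"], ratios)[0, 1]
        assert r > 0.99

    def test_full_reconstruction_is_exact(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 24))
        res = ShapeSpacePCA(X, n_components=24).fit()
        back = res.inverse_transform((X - res.mean_shape) @ res.components.T)
        assert np.allclose(back, X, atol=1e-8)

    def test_components_orthonormal(self):
        res, _ = self._fit(noise=0.5)
        G = res.components @ res.components.T
        assert np.allclose(G, np.eye(res.n_components), atol=1e-8)

    def test_mean_shape_projects_to_zero(self):
        res, _ = self._fit()
        scores = res.project([res.mean_shape])
        assert np.allclose(scores.iloc[0].to_numpy(dtype=float), 0.0,
                           atol=1e-9)

    def test_score_of_mean_plus_component_is_unit(self):
        res, _ = self._fit(noise=0.5)
        c = 7.5
        sample = res.mean_shape + c * res.components[2]
        scores = res.project([sample]).iloc[0]
        expected = np.zeros(res.n_components)
        expected[2] = c
        assert np.allclose(scores.to_numpy(dtype=float), expected, atol=1e-8)

    def test_dimensionality_mismatch_rejected(self):
        res, _ = self._fit()
        with pytest.raises(ValueError, match="dimensionality"):
            res.project(np.zeros((2, 17)))

    def test_too_few_samples_rejected(self):
        X = np.zeros((3, 30))
        with pytest.raises(ValueError, match="samples"):
            ShapeSpacePCA(X, n_components=5)


class TestLatentWalk:
    def test_score_zero_returns_mean_shape(self):
        res, _ = TestShapeSpace()._fit()
        frames = res.latent_walk(0, score_values=[0.0])
        assert np.allclose(frames[0].points.reshape(-1), res.mean_shape,
                           atol=1e-12)

    def test_walk_along_pc1_monotonically_compresses(self):
        res, _ = TestShapeSpace()._fit()
        frames = res.latent_walk(0)
        e2e = [f.end_to_end for f in frames]
        assert np.all(np.diff(e2e) < 0)  # PC1 score up = more compressed

    def test_symmetric_scores_give_symmetric_shapes(self):
        res, _ = TestShapeSpace()._fit(noise=0.5)
        plus, minus = res.latent_walk(1, score_values=[4.0, -4.0])
        mid = 0.5 * (plus.points + minus.points)
        assert np.allclose(mid.reshape(-1), res.mean_shape, atol=1e-9)

    def test_out_of_range_component_rejected(self):
        res, _ = TestShapeSpace()._fit()
        with pytest.raises(ValueError, match="component_index"):
            res.latent_walk(99)


class TestFeatureCorrelation:
    def test_pc1_correlates_perfectly_with_compression(self):
        res, _ = TestShapeSpace()._fit()
        corr = res.feature_correlations()
        assert corr.loc["PC1", "compression_ratio"] == pytest.approx(
            1.0, abs=1e-6)

    def test_constant_column_reported_as_nan(self):
        res, _ = TestShapeSpace()._fit()
        corr = res.feature_correlations()
        assert np.isnan(corr.loc["PC1", "non_coplanarity"])

    def test_noise_columns_uncorrelated_within_sampling_bound(self):
        rng = np.random.default_rng(12)
        n = 400
        X = rng.normal(size=(n, 12))
        metrics = pd.DataFrame({
            "compression_ratio": rng.normal(size=n),
            "supertwist_angle": rng.normal(size=n),
            "non_coplanarity": rng.normal(size=n),
            "peak_asymmetry": rng.normal(size=n),
            "normalized_time": rng.normal(size=n)})
        res = ShapeSpacePCA(X, metrics, n_components=4).fit()
        corr = res.feature_correlations().to_numpy(dtype=float)
        assert np.nanmax(np.abs(corr)) < 3.0 / np.sqrt(n)

    def test_summary_mentions_components(self):
        res, _ = TestShapeSpace()._fit()
        text = res.summary()
        assert "PC1" in text and "explained" in text
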