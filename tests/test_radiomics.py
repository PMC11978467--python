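"""Tests for resampling, normalization and the 107-feature extractor."""

import numpy as np
import pytest

from bmprog.radiomics import (
    FEATURE_NAMES,
    ImageVolume,
    MaskVolume,
    extract_features,
    normalize_zscore,
    resample_isotropic,
)
from bmprog.radiomics.shape import shape_features
from bmprog.radiomics.texture import discretize
from bmprog.simimage import generate_lesion_image


@pytest.fixture(scope="module")
def lesion_image():
    return generate_lesion_image(seed=42)


@pytest.fixture(scope="module")
def extracted(lesion_image):
    img, lesion, brain = lesion_image
    img_r, masks = resample_isotropic(img, {"lesion": lesion, "brain": brain}, 0.5)
    norm = normalize_zscore(img_r, masks["brain"], masks["lesion"])
    return norm, masks, extract_features(norm, masks["lesion"])


class TestResampling:
    def test_already_isotropic_passes_through(self):
        img = ImageVolume(np.random.default_rng(0).normal(size=(8, 8, 8)), (0.5, 0.5, 0.5))
        out, _ = resample_isotropic(img, {}, 0.5)
        np.testing.assert_array_equal(out.data, img.data)

    def test_constant_preserved_and_geometry_doubles(self):
        img = ImageVolume(np.full((10, 10, 10), 7.0), (1.0, 1.0, 1.0))
        mask = MaskVolume(np.ones((10, 10, 10), bool), (1.0, 1.0, 1.0))
        out, masks = resample_isotropic(img, {"lesion": mask}, 0.5)
        assert out.data.shape == (20, 20, 20)
        np.testing.assert_allclose(out.data, 7.0)
        assert masks["lesion"].data.shape == (20, 20, 20)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            ImageVolume(np.empty((0, 0, 0)), (1, 1, 1))


class TestNormalization:
    @staticmethod
    def _setup(shift=0.0, scale=1.0):
        rng = np.random.default_rng(1)
        data = rng.normal(100.0, 10.0, size=(12, 12, 12)) * scale + shift
        brain = np.ones(data.shape, bool)
        lesion = np.zeros(data.shape, bool)
        lesion[4:6, 4:6, 4:6] = True
        data[lesion] = 500.0 * scale + shift  # enhancing lesion
        return ImageVolume(data, (1, 1, 1)), MaskVolume(brain, (1, 1, 1), "brain"), MaskVolume(
            lesion, (1, 1, 1)
        )

    def test_mean_maps_to_zero_and_clip(self):
        img, brain, lesion = self._setup()
        out = normalize_zscore(img, brain, lesion)
        ref = brain.data & ~lesion.data
        # exact zero before clipping; the +/-3 clip moves the mean only by
        # the ~0.3% of reference voxels in the tails
        assert abs(out.data[ref].mean()) < 5e-3
        assert out.data.max() <= 3.0 and out.data.min() >= -3.0
        assert np.all(out.data[lesion.data] == 3.0)  # raw z >> 3, clipped

    def test_affine_invariance(self):
        img1, brain, lesion = self._setup()
        img2, _, _ = self._setup(shift=50.0, scale=2.0)
        out1 = normalize_zscore(img1, brain, lesion)
        out2 = normalize_zscore(img2, brain, lesion)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-9)

    def test_zero_variance_rejected(self):
        img = ImageVolume(np.full((6, 6, 6), 5.0), (1, 1, 1))
        brain = MaskVolume(np.ones((6, 6, 6), bool), (1, 1, 1), "brain")
        with pytest.raises(ValueError):
            normalize_zscore(img, brain)


class TestFeatureVector:
    def test_exactly_107_named_features(self, extracted):
        _, _, fv = extracted
        assert len(fv) == 107
        assert list(fv.index) == list(FEATURE_NAMES)
        assert len(set(fv.index)) == 107
        assert np.all(np.isfinite(fv.to_numpy()))

    def test_class_composition(self):
        counts = {}
        for name in FEATURE_NAMES:
            counts[name.split("_")[1]] = counts.get(name.split("_")[1], 0) + 1
        assert counts == {
            "shape": 14,
            "firstorder": 18,
            "glcm": 24,
            "glrlm": 16,
            "glszm": 16,
            "gldm": 14,
            "ngtdm": 5,
        }

    def test_determinism(self, extracted):
        norm, masks, fv = extracted
        fv2 = extract_features(norm, masks["lesion"])
        np.testing.assert_array_equal(fv.to_numpy(), fv2.to_numpy())

    def test_shape_invariant_to_intensity_rescale(self, extracted):
        norm, masks, fv = extracted
        rescaled = ImageVolume(norm.data * 3.1 + 0.7, norm.spacing)
        fv2 = extract_features(rescaled, masks["lesion"])
        shape_cols = [n for n in FEATURE_NAMES if n.startswith("original_shape_")]
        np.testing.assert_allclose(fv[shape_cols], fv2[shape_cols])

    def test_texture_invariant_to_affine_shift(self, extracted):
        # fixed bin COUNT discretization is affine-invariant, so all
        # histogram-based texture features are too
        norm, masks, fv = extracted
        shifted = ImageVolume(norm.data * 2.0 - 1.0, norm.spacing)
        fv2 = extract_features(shifted, masks["lesion"])
        texture_cols = [
            n
            for n in FEATURE_NAMES
            if n.split("_")[1] in ("glcm", "glrlm", "glszm", "gldm", "ngtdm")
        ]
        np.testing.assert_allclose(fv[texture_cols], fv2[texture_cols], rtol=1e-9)

    def test_constant_lesion_has_zero_variance(self):
        data = np.zeros((12, 12, 12))
        mask = np.zeros(data.shape, bool)
        mask[4:8, 4:8, 4:8] = True
        data[mask] = 1.5
        fv = extract_features(ImageVolume(data, (1, 1, 1)), MaskVolume(mask, (1, 1, 1)))
        assert fv["original_firstorder_Variance"] == 0.0
        assert fv["original_firstorder_Entropy"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_mask_rejected(self, extracted):
        norm, masks, _ = extracted
        with pytest.raises(ValueError):
            MaskVolume(np.zeros(norm.data.shape, bool), norm.spacing)

    def test_grid_mismatch_rejected(self, extracted):
        norm, masks, _ = extracted
        small = MaskVolume(np.ones((4, 4, 4), bool), norm.spacing)
        with pytest.raises(ValueError):
            extract_features(norm, small)


class TestShapeFeatures:
    @staticmethod
    def _ball(radius_vox, shape=(40, 40, 40)):
        g = np.indices(shape).astype(float)
        c = (np.asarray(shape) - 1) / 2.0
        return ((g - c[:, None, None, None]) ** 2).sum(axis=0) <= radius_vox**2

    def test_sphere_is_most_spherical(self):
        sphere = shape_features(self._ball(12), (0.5, 0.5, 0.5))
        g = np.indices((40, 40, 40)).astype(float)
        c = 19.5
        ellipsoid = (
            ((g[0] - c) / 16) ** 2 + ((g[1] - c) / 12) ** 2 + ((g[2] - c) / 7) ** 2
        ) <= 1
        ell = shape_features(ellipsoid, (0.5, 0.5, 0.5))
        assert 0.95 <= sphere["Sphericity"] <= 1.02
        assert sphere["Sphericity"] > ell["Sphericity"]

    def test_sphere_mesh_volume_close_to_analytic(self):
        f = shape_features(self._ball(12), (0.5, 0.5, 0.5))
        analytic = 4.0 / 3.0 * np.pi * 6.0**3  # radius 12 voxels at 0.5 mm
        assert f["MeshVolume"] == pytest.approx(analytic, rel=0.04)
        assert f["Maximum3DDiameter"] == pytest.approx(12.0, rel=0.05)

    def test_axis_lengths_ordering(self):
        g = np.indices((40, 40, 40)).astype(float)
        c = 19.5
        ellipsoid = (
            ((g[0] - c) / 16) ** 2 + ((g[1] - c) / 12) ** 2 + ((g[2] - c) / 7) ** 2
        ) <= 1
        f = shape_features(ellipsoid, (1.0, 1.0, 1.0))
        assert f["MajorAxisLength"] >= f["MinorAxisLength"] >= f["LeastAxisLength"]
        assert 0 < f["Flatness"] <= f["Elongation"] <= 1


class TestTextureHandTraced:
    """A 1x1x4 strip with gray levels (1,1,2,2): every matrix can be written
    down by hand, pinning the texture formulas independently of the code."""

    @staticmethod
    def _strip():
        from bmprog.radiomics.texture import gray_level_volume

        img = np.array([[[10.0, 10.0, 20.0, 20.0]]])
        mask = np.ones(img.shape, bool)
        return gray_level_volume(img, mask, bin_count=2)

    def test_glcm(self):
        from bmprog.radiomics.texture import glcm_features

        # single informative direction; p = [[1/3,1/6],[1/6,1/3]]
        f = glcm_features(self._strip())
        assert f["Contrast"] == pytest.approx(1 / 3)
        assert f["MaximumProbability"] == pytest.approx(1 / 3)
        assert f["JointEntropy"] == pytest.approx(1.918295, abs=1e-5)
        assert f["Correlation"] == pytest.approx(1 / 3)

    def test_glrlm(self):
        from bmprog.radiomics.texture import glrlm_features

        # along the strip: two runs of length 2; the 12 other directions see
        # four runs of length 1 each; features average over directions
        f = glrlm_features(self._strip())
        assert f["ShortRunEmphasis"] == pytest.approx((0.25 + 12.0) / 13.0)
        assert f["RunPercentage"] == pytest.approx((0.5 + 12.0) / 13.0)

    def test_glszm(self):
        from bmprog.radiomics.texture import glszm_features

        # two zones of size 2 -> P/ns identical to a 2-run matrix
        f = glszm_features(self._strip())
        assert f["SmallAreaEmphasis"] == pytest.approx(0.25)
        assert f["ZonePercentage"] == pytest.approx(0.5)
        assert f["GrayLevelNonUniformity"] == pytest.approx(1.0)

    def test_gldm(self):
        from bmprog.radiomics.texture import gldm_features

        # every voxel has exactly one same-level neighbor -> dependence 2
        f = gldm_features(self._strip())
        assert f["SmallDependenceEmphasis"] == pytest.approx(0.25)
        assert f["DependenceEntropy"] == pytest.approx(1.0)
        assert f["GrayLevelNonUniformity"] == pytest.approx(2.0)

    def test_ngtdm(self):
        from bmprog.radiomics.texture import ngtdm_features

        # s = (0.5, 0.5), p = (0.5, 0.5) -> coarseness 2, contrast 1/16
        f = ngtdm_features(self._strip())
        assert f["Coarseness"] == pytest.approx(2.0)
        assert f["Contrast"] == pytest.approx(0.0625)


class TestDiscretization:
    def test_fixed_bin_count_range(self, rng):
        vals = rng.normal(size=5000)
        d = discretize(vals, 64)
        assert d.min() == 1 and d.max() == 64

    def test_constant_input_single_level(self):
        d = discretize(np.full(100, 3.3), 64)
        assert np.all(d == 1)

    def test_affine_invariance(self, rng):
        vals = rng.normal(size=2000)
        np.testing.assert_array_equal(discretize(vals, 64), discretize(vals * 5 + 2, 64))
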