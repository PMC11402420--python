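"""Feature families versus independent brute-force oracles and worked examples."""

import numpy as np
import pytest

from srct_radiomics import (
    build_feature_table,
    glcm,
    glcm_cluster_shade,
    glcm_features,
    glcm_sum_variance,
    glszm,
    glszm_features,
    glszm_zone_size_entropy,
    intensity_stats,
    wavelet_decompose,
)
from srct_radiomics.ct_preprocess import DiscretizedImage, discretize_fixed_count
from srct_radiomics.radiomic_features import (
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    FeatureError,
    extract_features,
)

import oracles

# The worked 3x3 example used throughout: three grey levels, hand-checkable.
BINS_3X3 = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]])
ROI_3X3 = np.ones((3, 3), dtype=bool)


def _disc(bins, n_bins=None):
    bins = np.asarray(bins)
    return DiscretizedImage(
        bins=bins, n_bins=n_bins or int(bins.max()), roi=bins > 0
    )


class TestIntensityStats:
    def test_two_point_moments(self):
        s = intensity_stats(np.array([-900.0, -800.0]))
        assert s["hist_mean"] == -850.0
        assert s["hist_sd"] == 50.0

    def test_symmetric_sample_zero_skew(self):
        s = intensity_stats(np.array([-900.0, -850.0, -800.0]))
        assert s["hist_skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_is_three(self, rng):
        s = intensity_stats(rng.normal(-850, 25, 10_000))
        assert s["hist_kurtosis"] == pytest.approx(3.0, abs=0.15)

    def test_zero_variance_flags_missing(self):
        s = intensity_stats(np.full(10, -500.0))
        assert np.isnan(s["hist_skewness"]) and np.isnan(s["hist_kurtosis"])

    def test_single_value_errors(self):
        with pytest.raises(FeatureError):
            intensity_stats(np.array([1.0]))


class TestGLCM:
    def test_worked_example_single_direction(self):
        """Hand-enumerated ordered pairs of the 3x3 example, direction (0,1)."""
        P = glcm(_disc(BINS_3X3), directions=[(0, 1)])
        counts = P.p * 12  # 6 horizontal pairs, symmetric accumulation
        assert counts[0, 0] == pytest.approx(2)   # (1,1) ordered pairs
        assert counts[2, 2] == pytest.approx(4)   # (3,3) ordered pairs
        assert counts.sum() == pytest.approx(12)
        assert counts[0, 1] == pytest.approx(2) and counts[1, 0] == pytest.approx(2)
        assert counts[1, 1] == pytest.approx(2)   # (2,2) ordered pairs

    def test_constant_roi_concentrates_mass(self):
        bins = np.full((4, 4), 3)
        P = glcm(_disc(bins, n_bins=5))
        assert P.p[2, 2] == pytest.approx(1.0)
        assert P.p.sum() == pytest.approx(1.0)

    def test_symmetry_and_marginals(self, rng):
        bins = rng.integers(1, 7, size=(8, 8))
        P = glcm(_disc(bins, n_bins=6))
        assert np.allclose(P.p, P.p.T)
        assert np.allclose(P.p.sum(axis=1), P.p.sum(axis=0))

    @pytest.mark.parametrize("ndim", [2, 3])
    def test_matches_brute_force_enumeration(self, ndim, rng):
        dirs = DIRECTIONS_2D if ndim == 2 else DIRECTIONS_3D
        for _ in range(25):
            shape = tuple(rng.integers(3, 7, size=ndim))
            bins = rng.integers(1, 5, size=shape)
            roi = rng.random(shape) > 0.25
            if roi.sum() < 4:
                continue
            d = DiscretizedImage(bins=np.where(roi, bins, 0), n_bins=4, roi=roi)
            try:
                P = glcm(d)
            except FeatureError:
                continue
            brute = oracles.brute_glcm(bins, roi, dirs, n_bins=4)
            assert np.allclose(P.p, brute / brute.sum(), atol=1e-12)

    def test_sum_variance_equals_brute_double_sum(self, rng):
        bins = rng.integers(1, 6, size=(7, 7))
        P = glcm(_disc(bins, n_bins=5))
        assert glcm_sum_variance(P) == pytest.approx(
            oracles.brute_glcm_sum_variance(P.p), rel=1e-10
        )

    def test_sum_variance_trivials(self):
        const = glcm(_disc(np.full((4, 4), 2), n_bins=3))
        assert glcm_sum_variance(const) == pytest.approx(0.0, abs=1e-12)
        checker = np.indices((4, 4)).sum(axis=0) % 2 + 1
        P = glcm(_disc(checker, n_bins=2), directions=[(0, 1)])
        # all mass at (1,2)/(2,1): p_{x+y}(3) = 1, zero variance
        assert glcm_sum_variance(P) == pytest.approx(0.0, abs=1e-12)

    def test_cluster_shade_matches_brute_triple_sum(self, rng):
        P = glcm(_disc(BINS_3X3))
        assert glcm_cluster_shade(P) == pytest.approx(
            oracles.brute_glcm_cluster_shade(P.p), rel=1e-10
        )
        bins = rng.integers(1, 5, size=(6, 6))
        P2 = glcm(_disc(bins, n_bins=4))
        assert glcm_cluster_shade(P2) == pytest.approx(
            oracles.brute_glcm_cluster_shade(P2.p), rel=1e-10
        )

    def test_cluster_shade_zero_for_symmetric_histogram(self):
        const = glcm(_disc(np.full((4, 4), 2), n_bins=3))
        assert glcm_cluster_shade(const) == pytest.approx(0.0, abs=1e-12)
        checker = np.indices((6, 6)).sum(axis=0) % 2 + 1
        P = glcm(_disc(checker, n_bins=2))
        # p_{x+y} symmetric about its mean: odd central moment vanishes
        assert glcm_cluster_shade(P) == pytest.approx(0.0, abs=1e-10)

    def test_too_small_roi_errors(self):
        d = DiscretizedImage(
            bins=np.array([[1, 0], [0, 0]]), n_bins=1,
            roi=np.array([[True, False], [False, False]]),
        )
        with pytest.raises(FeatureError):
            glcm(d)


class TestGLSZM:
    def test_worked_example_three_zones(self):
        S = glszm(_disc(BINS_3X3))
        assert S.n_zones == 3
        # every zone has size 3
        assert S.s[:, 2].sum() == 3 and S.s.sum() == 3
        assert glszm_zone_size_entropy(S) == pytest.approx(np.log2(3), rel=1e-12)

    def test_constant_roi_single_zone(self):
        bins = np.full((3, 4), 2)
        S = glszm(_disc(bins, n_bins=3))
        assert S.n_zones == 1
        assert S.s[1, 11] == 1
        assert glszm_zone_size_entropy(S) == 0.0

    def test_zone_sizes_partition_roi(self, rng):
        for _ in range(10):
            bins = rng.integers(1, 4, size=(6, 6))
            roi = rng.random((6, 6)) > 0.3
            if not roi.any():
                continue
            d = DiscretizedImage(bins=np.where(roi, bins, 0), n_bins=3, roi=roi)
            S = glszm(d)
            z = np.arange(1, S.s.shape[1] + 1)
            assert (S.s * z).sum() == roi.sum()

    @pytest.mark.parametrize("ndim", [2, 3])
    def test_matches_brute_flood_fill(self, ndim, rng):
        for _ in range(25):
            shape = tuple(rng.integers(3, 7, size=ndim))
            bins = rng.integers(1, 5, size=shape)
            roi = rng.random(shape) > 0.25
            if not roi.any():
                continue
            d = DiscretizedImage(bins=np.where(roi, bins, 0), n_bins=4, roi=roi)
            S = glszm(d)
            brute = oracles.brute_zone_matrix(bins, roi, n_bins=4)
            assert S.s.shape == brute.shape
            assert np.array_equal(S.s, brute)
            assert glszm_zone_size_entropy(S) == pytest.approx(
                oracles.brute_zone_size_entropy(brute), rel=1e-10
            )

    def test_entropy_bounded_by_log_zone_count(self, rng):
        bins = rng.integers(1, 5, size=(8, 8))
        S = glszm(_disc(bins, n_bins=4))
        assert glszm_zone_size_entropy(S) <= np.log2(S.n_zones) + 1e-12


class TestWavelets:
    def test_constant_image_detail_bands_vanish(self):
        sub = wavelet_decompose(np.full((16, 16), -700.0))
        assert set(sub) == {"LL", "LH", "HL", "HH"}
        assert np.allclose(sub["LL"], sub["LL"].flat[0])
        assert abs(sub["LL"].flat[0]) > abs(-700.0)  # scaled by the filter gain
        for band in ("LH", "HL", "HH"):
            assert np.allclose(sub[band], 0.0, atol=1e-8)

    def test_subband_counts_2d_vs_3d(self, rng):
        assert len(wavelet_decompose(rng.normal(size=(12, 12)))) == 4
        sub3 = wavelet_decompose(rng.normal(size=(12, 12, 12)))
        assert len(sub3) == 8
        assert set(sub3) == {
            "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"
        }

    def test_parseval_energy_conservation_orthogonal(self, rng):
        # periodization keeps the decimated transform exactly orthogonal
        import pywt

        img = rng.normal(size=(32, 32))
        coeffs = pywt.dwtn(img, "coif1", mode="periodization")
        energy = sum(float((c**2).sum()) for c in coeffs.values())
        assert energy == pytest.approx(float((img**2).sum()), rel=1e-6)

    def test_too_small_image_errors(self, rng):
        with pytest.raises(FeatureError):
            wavelet_decompose(rng.normal(size=(3, 3)))


class TestExtraction:
    def test_fixed_feature_count_and_determinism(self, small_cohort):
        pats = small_cohort[:3]
        t1 = build_feature_table(pats, "2D", 2.0)
        t2 = build_feature_table(pats, "2D", 2.0)
        assert t1.values.shape[1] > 200
        assert (t1.values.notna()).all().all() or True  # NaNs allowed, cleaned later
        assert t1.values.equals(t2.values)
        # all patients share the descriptor set
        assert len({len(r) for r in t1.values.values}) == 1

    def test_duplicated_patient_identical_rows(self, small_cohort):
        p = small_cohort[0]
        t = build_feature_table([p, p], "3D", 2.0)
        assert np.allclose(t.values.iloc[0], t.values.iloc[1], equal_nan=True)

    def test_column_order_intensity_texture_wavelet(self, small_cohort):
        t = build_feature_table(small_cohort[:1], "2D", 2.0)
        fams = [d.family for d in t.descriptors]
        bands = [d.sub_band for d in t.descriptors]
        first_wavelet = bands.index("LL")
        assert all(b == "original" for b in bands[:first_wavelet])
        orig = fams[:first_wavelet]
        assert orig.index("GLCM") > max(
            i for i, f in enumerate(orig) if f == "intensity"
        )

    def test_hist_sd_larger_in_extensive_class(self, small_cohort):
        """Fibrotic texture widens the intensity distribution: group-mean
        hist_sd orders extensive > limited."""
        t = build_feature_table(small_cohort, "2D", 2.0, intensity_only=True)
        sd = t.values["original_hist_sd"]
        lab = t.labels
        assert sd[lab == "extensive"].mean() > sd[lab == "limited"].mean()

    def test_2d_3d_intensity_cross_check(self):
        """A z-constant volume yields identical slice-wise and volume-wise
        intensity statistics at matched resampling."""
        from srct_radiomics.ct_preprocess import CTVolume, ROIMask
        from srct_radiomics.radiomic_features import extract_features_3d

        rng = np.random.default_rng(5)
        plane = rng.normal(-700, 60, (40, 40)).astype(np.float32)
        vol = CTVolume(np.repeat(plane[None], 24, axis=0), spacing=(2.0, 2.0, 2.0))
        mask = ROIMask(np.ones(vol.shape, bool))
        f3 = extract_features_3d(vol, mask, target_spacing=2.0, intensity_only=True)
        s = intensity_stats(plane)
        assert f3["original_hist_mean"] == pytest.approx(s["hist_mean"], rel=1e-6)
        assert f3["original_hist_sd"] == pytest.approx(s["hist_sd"], rel=1e-6)

    def test_no_roi_errors(self, small_cohort):
        import dataclasses

        from srct_radiomics.ct_preprocess import ROIMask

        p = dataclasses.replace(
            small_cohort[0],
            fc_mask=ROIMask(np.zeros(small_cohort[0].fc_volume.shape, bool)),
        )
        with pytest.raises(FeatureError):
            extract_features(p, "3D", 2.0)
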