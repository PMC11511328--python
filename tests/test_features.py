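import numpy as np
import pytest

from speckleid.features import (FEATURE_NAMES, GLCM_STAT_NAMES,
                                GLRLM_STAT_NAMES, THETAS, compute_glcm,
                                compute_glrlm, extract_features,
                                first_order_stats, glcm_stats, glrlm_stats)

from conftest import random_images
from oracles import (brute_glcm_counts, brute_glcm_stats, brute_glrlm_runs,
                     brute_glrlm_stats)


class TestFirstOrder:
    def test_constant_image(self):
        stats = first_order_stats(np.full((8, 8), 100, dtype=np.uint8))
        assert stats == {"intensity": 100.0, "standard_deviation": 0.0,
                         "variance": 0.0, "kurtosis": 0.0, "skewness": 0.0}

    def test_two_level_image_hand_arithmetic(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        stats = first_order_stats(img)
        assert stats["intensity"] == pytest.approx(127.5)
        assert stats["variance"] == pytest.approx(16256.25)
        assert stats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        checker = np.indices((8, 8)).sum(axis=0) % 2 * 255
        block = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        a = first_order_stats(checker.astype(np.uint8))
        b = first_order_stats(block)
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_matches_numpy_moments(self, rng):
        img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        stats = first_order_stats(img)
        x = img.astype(float).ravel()
        assert stats["intensity"] == pytest.approx(x.mean())
        assert stats["variance"] == pytest.approx(x.var())
        z = (x - x.mean()) / x.std()
        assert stats["skewness"] == pytest.approx((z ** 3).mean())
        assert stats["kurtosis"] == pytest.approx((z ** 4).mean() - 3)


class TestGLCMCounts:
    def test_constant_image_single_entry(self):
        img = np.full((5, 5), 7, dtype=np.uint8)
        glcm = compute_glcm(img, theta=0)
        assert glcm.counts[7, 7] == 5 * 4
        assert glcm.counts.sum() == 5 * 4

    def test_tiny_image_exhaustive(self):
        img = np.array([[0, 1], [2, 3]], dtype=np.uint8)
        glcm = compute_glcm(img, theta=0)
        expected = np.zeros((256, 256), dtype=np.int64)
        expected[0, 1] = 1
        expected[2, 3] = 1
        assert np.array_equal(glcm.counts, expected)

    @pytest.mark.parametrize("theta,total", [
        (0, lambda m, n: m * (n - 1)),
        (90, lambda m, n: (m - 1) * n),
        (45, lambda m, n: (m - 1) * (n - 1)),
        (135, lambda m, n: (m - 1) * (n - 1)),
    ])
    def test_pair_count_totals(self, rng, theta, total):
        for shape in [(4, 7), (16, 16), (5, 3)]:
            img = rng.integers(0, 256, size=shape).astype(np.uint8)
            assert compute_glcm(img, theta=theta).counts.sum() == total(*shape)

    def test_invalid_theta(self, rng):
        with pytest.raises(ValueError):
            compute_glcm(rng.integers(0, 256, size=(4, 4)), theta=30)

    @pytest.mark.parametrize("theta", THETAS)
    def test_counts_match_brute_force(self, theta):
        for img in random_images(25, seed=theta):
            counts = compute_glcm(img, theta=theta).counts
            brute = brute_glcm_counts(img, theta)
            assert counts.sum() == sum(brute.values())
            for (i, j), v in brute.items():
                assert counts[i, j] == v
            assert counts.sum() == counts[tuple(zip(*brute.keys()))].sum()

    def test_normalization_sums_to_one(self, rng):
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        assert compute_glcm(img, theta=45).normalized.sum() == pytest.approx(1.0)


class TestGLCMStats:
    def test_constant_image(self):
        glcm = compute_glcm(np.full((6, 6), 9, dtype=np.uint8), theta=0)
        stats = glcm_stats(glcm)
        assert stats["energy"] == pytest.approx(1.0)
        assert stats["entropy"] == pytest.approx(0.0)
        assert stats["contrast"] == 0.0
        assert stats["dissimilarity"] == 0.0
        assert stats["maximum_probability"] == pytest.approx(1.0)

    def test_checkerboard_closed_form(self):
        # P concentrates 1/2 at (0,255) and 1/2 at (255,0)
        checker = (np.indices((8, 8)).sum(axis=0) % 2 * 255).astype(np.uint8)
        stats = glcm_stats(compute_glcm(checker, theta=0))
        assert stats["contrast"] == pytest.approx(255.0 ** 2)
        assert stats["dissimilarity"] == pytest.approx(255.0)
        assert stats["entropy"] == pytest.approx(np.log(2))
        assert stats["energy"] == pytest.approx(0.5)

    @pytest.mark.parametrize("theta", THETAS)
    def test_all_twenty_match_brute_force(self, theta):
        for img in random_images(25, seed=100 + theta):
            mine = glcm_stats(compute_glcm(img, theta=theta))
            brute = brute_glcm_stats(brute_glcm_counts(img, theta))
            assert set(mine) == set(GLCM_STAT_NAMES)
            for name in GLCM_STAT_NAMES:
                assert mine[name] == pytest.approx(brute[name], rel=1e-10,
                                                   abs=1e-10), name

    def test_empty_glcm_rejected(self):
        from speckleid.features import GLCM
        with pytest.raises(ValueError):
            glcm_stats(GLCM(counts=np.zeros((256, 256), dtype=np.int64),
                            d=1, theta=0))


class TestGLRLM:
    def test_constant_image_single_run_per_row(self):
        img = np.full((6, 6), 200, dtype=np.uint8)
        glrlm = compute_glrlm(img, theta=0)
        level = 200 * 32 // 256
        assert glrlm.counts[level, 5] == 6  # 6 runs of length 6
        assert glrlm.counts.sum() == 6

    def test_manual_row_runs(self):
        img = np.array([[0, 0, 64, 64, 64]], dtype=np.uint8)
        glrlm = compute_glrlm(img, theta=0)
        assert glrlm.counts[0, 1] == 1       # level 0, length 2
        assert glrlm.counts[64 * 32 // 256, 2] == 1  # level 8, length 3
        assert glrlm.counts.sum() == 2

    @pytest.mark.parametrize("theta", THETAS)
    def test_pixel_conservation(self, theta):
        for img in random_images(10, shape=(9, 13), seed=theta + 7):
            glrlm = compute_glrlm(img, theta=theta)
            lengths = np.arange(1, glrlm.counts.shape[1] + 1)
            assert (glrlm.counts * lengths).sum() == img.size

    @pytest.mark.parametrize("theta", THETAS)
    def test_counts_match_brute_force(self, theta):
        for img in random_images(25, seed=200 + theta):
            glrlm = compute_glrlm(img, theta=theta)
            runs = brute_glrlm_runs(img, theta)
            brute = {}
            for lvl, length in runs:
                brute[(lvl, length)] = brute.get((lvl, length), 0) + 1
            assert glrlm.counts.sum() == len(runs)
            for (lvl, length), v in brute.items():
                assert glrlm.counts[lvl, length - 1] == v

    def test_invalid_theta(self, rng):
        with pytest.raises(ValueError):
            compute_glrlm(rng.integers(0, 256, size=(4, 4)), theta=10)


class TestGLRLMStats:
    def test_constant_image_closed_form(self):
        n = 8
        img = np.full((n, n), 128, dtype=np.uint8)
        stats = glrlm_stats(compute_glrlm(img, theta=0))
        assert stats["sre"] == pytest.approx(1.0 / n ** 2)
        assert stats["lre"] == pytest.approx(float(n ** 2))
        assert stats["rp"] == pytest.approx(1.0 / n)

    def test_alternating_rows_all_unit_runs(self):
        img = np.tile(np.array([0, 255], dtype=np.uint8), (4, 4))
        stats = glrlm_stats(compute_glrlm(img, theta=0))
        assert stats["sre"] == pytest.approx(1.0)
        assert stats["lre"] == pytest.approx(1.0)
        assert stats["rp"] == pytest.approx(1.0)

    @pytest.mark.parametrize("theta", THETAS)
    def test_all_eleven_match_brute_force(self, theta):
        for img in random_images(25, seed=300 + theta):
            mine = glrlm_stats(compute_glrlm(img, theta=theta))
            runs = brute_glrlm_runs(img, theta)
            brute = brute_glrlm_stats(runs, img.size)
            assert set(mine) == set(GLRLM_STAT_NAMES)
            for name in GLRLM_STAT_NAMES:
                assert mine[name] == pytest.approx(brute[name], abs=1e-10), name


class TestExtractFeatures:
    def test_length_129_on_crop(self, speckle_frame_224):
        feats = extract_features(speckle_frame_224)
        assert len(feats) == 129
        assert list(feats) == list(FEATURE_NAMES)

    def test_names_unique(self):
        assert len(set(FEATURE_NAMES)) == 129

    @pytest.mark.parametrize("value", [0, 128, 255])
    def test_degenerate_images_all_finite(self, value):
        img = np.full((16, 16), value, dtype=np.uint8)
        feats = extract_features(img)
        assert all(np.isfinite(v) for v in feats.values())

    def test_rotation_permutes_directions(self, rng):
        # 90-degree rotation swaps the 0/90 and 45/135 direction labels for
        # the run-length family and for transpose-invariant GLCM statistics.
        img = rng.integers(0, 16, size=(16, 16)).astype(np.uint8) * 16
        a = extract_features(img)
        b = extract_features(np.rot90(img).copy())
        swap = {0: 90, 90: 0, 45: 135, 135: 45}
        check = [s for s in GLCM_STAT_NAMES if s != "sum_of_squares_variance"]
        for theta, other in swap.items():
            for stat in check:
                assert a[f"{stat}_{theta}"] == pytest.approx(
                    b[f"{stat}_{other}"], rel=1e-10, abs=1e-10), (stat, theta)
            for stat in GLRLM_STAT_NAMES:
                assert a[f"{stat}_{theta}"] == pytest.approx(
                    b[f"{stat}_{other}"], rel=1e-10, abs=1e-10), (stat, theta)

    def test_isotropy_on_large_speckle(self, optical_512):
        import speckleid as sk
        from speckleid.simulate import SimConfig
        rng = np.random.default_rng(17)
        img = sk.simulate_frame(0.5, SimConfig(grain_size_px=3), optical_512,
                                rng)
        feats = extract_features(img)
        # directions at equal lattice separation are statistically
        # equivalent; axial (1 px) vs diagonal (sqrt(2) px) offsets are not,
        # since difference-type statistics grow with separation.
        for stat in list(GLCM_STAT_NAMES) + list(GLRLM_STAT_NAMES):
            for ta, tb in ((0, 90), (45, 135)):
                a, b = feats[f"{stat}_{ta}"], feats[f"{stat}_{tb}"]
                scale = max(abs(a), abs(b))
                if scale == 0:
                    continue
                assert abs(a - b) / scale < 0.05, (stat, ta, tb)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((4, 4, 3), dtype=np.uint8))
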