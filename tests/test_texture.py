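"""GLCM construction and the 21 texture descriptors against a direct-summation oracle."""

import numpy as np
import pytest

from thermocad.texture import (
    GLCMConfig,
    TEXTURE_FEATURE_NAMES,
    compute_glcm,
    dwt_texture,
    roi_texture_features,
    texture_descriptors,
)


def oracle_descriptors(P):
    """Independent O(L^2) plain-loop evaluation of all 21 descriptors."""
    L = P.shape[0]
    px = [sum(P[i, j] for j in range(L)) for i in range(L)]
    py = [sum(P[i, j] for i in range(L)) for j in range(L)]
    mux = sum(i * px[i] for i in range(L))
    muy = sum(j * py[j] for j in range(L))
    sdx = np.sqrt(sum((i - mux) ** 2 * px[i] for i in range(L)))
    sdy = np.sqrt(sum((j - muy) ** 2 * py[j] for j in range(L)))
    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]

    def ent(v):
        return -sum(x * np.log(x) for x in np.ravel(v) if x > 0)

    out = {}
    out["autocorrelation"] = sum(i * j * P[i, j] for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    out["correlation"] = (
        sum((i - mux) * (j - muy) * P[i, j] for i in range(L) for j in range(L)) / (sdx * sdy)
        if sdx > 0 and sdy > 0 else 1.0)
    out["cluster_prominence"] = sum((i + j - mux - muy) ** 4 * P[i, j]
                                    for i in range(L) for j in range(L))
    out["cluster_shade"] = sum((i + j - mux - muy) ** 3 * P[i, j]
                               for i in range(L) for j in range(L))
    out["dissimilarity"] = sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L))
    out["energy"] = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    out["entropy"] = ent(P)
    out["homogeneity"] = sum(P[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L))
    out["maximum_probability"] = max(P[i, j] for i in range(L) for j in range(L))
    out["variance"] = sum((i - mux) ** 2 * P[i, j] for i in range(L) for j in range(L))
    sa = sum(k * psum[k] for k in range(2 * L - 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in range(2 * L - 1))
    out["sum_entropy"] = ent(psum)
    da = sum(k * pdiff[k] for k in range(L))
    out["difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in range(L))
    out["difference_entropy"] = ent(pdiff)
    hxy = out["entropy"]
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(P[i, j] * np.log(px[i] * py[j]) for i in range(L) for j in range(L)
                if P[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * np.log(px[i] * py[j]) for i in range(L) for j in range(L)
                if px[i] * py[j] > 0)
    out["imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    out["imc2"] = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    out["inn"] = sum(P[i, j] / (1 + (i - j) ** 2 / L ** 2) for i in range(L) for j in range(L))
    out["idn"] = sum(P[i, j] / (1 + abs(i - j) / L) for i in range(L) for j in range(L))
    out["idm"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    return out


def random_glcm(rng, L=16):
    P = rng.random((L, L))
    P = P + P.T  # symmetric, like the default configuration
    return P / P.sum()


class TestGLCM:
    def test_two_by_two_hand_count(self):
        img = np.array([[0, 0], [1, 1]], dtype=float)
        cfg = GLCMConfig(levels=2, distances=(1,), angles=(0.0,), symmetric=True)
        P = compute_glcm(img, cfg)[:, :, 0, 0]
        # horizontal pairs: (0,0) in the top row and (1,1) in the bottom row
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 1] == pytest.approx(0.5)
        assert P[0, 1] == 0 and P[1, 0] == 0

    def test_constant_roi_single_entry(self):
        img = np.full((8, 8), 3.0)
        P = compute_glcm(img, GLCMConfig(levels=4))
        for d in range(P.shape[2]):
            for a in range(P.shape[3]):
                sl = P[:, :, d, a]
                assert sl.max() == pytest.approx(1.0)
                assert (sl > 0).sum() == 1

    def test_normalization(self, rng):
        img = rng.integers(0, 255, (12, 12)).astype(float)
        P = compute_glcm(img, GLCMConfig(levels=8))
        np.testing.assert_allclose(P.sum(axis=(0, 1)), 1.0, atol=1e-12)

    def test_symmetry(self, rng):
        img = rng.integers(0, 255, (12, 12)).astype(float)
        P = compute_glcm(img, GLCMConfig(levels=8, symmetric=True))
        np.testing.assert_allclose(P, np.transpose(P, (1, 0, 2, 3)), atol=1e-15)

    def test_offset_larger_than_roi_rejected(self):
        img = np.arange(4, dtype=float).reshape(2, 2)
        with pytest.raises(ValueError, match="thinner"):
            compute_glcm(img, GLCMConfig(levels=2, distances=(5,)))

    def test_nonrectangular_roi_excludes_background_pairs(self):
        img = np.array([[0, 0, 9], [0, 0, 9], [9, 9, 9]], dtype=float)
        roi = img == 0  # L-free 2x2 block
        cfg = GLCMConfig(levels=2, distances=(1,), angles=(0.0,), symmetric=True)
        P = compute_glcm(img, cfg, roi_mask=roi)[:, :, 0, 0]
        assert P[0, 0] == pytest.approx(1.0)  # only the two in-ROI horizontal pairs


class TestDescriptors:
    def test_constant_image_limits(self):
        P = compute_glcm(np.full((8, 8), 5.0), GLCMConfig(levels=4))
        d = texture_descriptors(P)
        assert d["energy"] == pytest.approx(1.0)
        assert d["contrast"] == pytest.approx(0.0)
        assert d["dissimilarity"] == pytest.approx(0.0)
        assert d["homogeneity"] == pytest.approx(1.0)
        assert d["entropy"] == pytest.approx(0.0)
        assert d["maximum_probability"] == pytest.approx(1.0)

    def test_vertical_stripes_anticorrelated(self):
        # alternating columns of 0/1: horizontal neighbours always differ
        img = np.tile([0.0, 1.0], (8, 4))
        cfg = GLCMConfig(levels=2, distances=(1,), angles=(0.0,), symmetric=True)
        d = texture_descriptors(compute_glcm(img, cfg))
        assert d["correlation"] == pytest.approx(-1.0)
        assert d["contrast"] == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            P = random_glcm(rng)
            got = texture_descriptors(P)
            want = oracle_descriptors(P)
            for name in TEXTURE_FEATURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_energy_entropy_tradeoff(self, rng):
        P = random_glcm(rng)
        d = texture_descriptors(P)
        assert 0 < d["energy"] < 1 and d["entropy"] > 0

    def test_translation_invariance(self, rng):
        img = rng.integers(0, 255, (20, 20)).astype(float)
        roi = np.zeros((20, 20), bool)
        roi[2:12, 3:13] = True
        a = roi_texture_features(img, roi)
        shifted = np.roll(np.roll(img, 4, axis=0), 5, axis=1)
        roi_s = np.roll(np.roll(roi, 4, axis=0), 5, axis=1)
        b = roi_texture_features(shifted, roi_s)
        for name in TEXTURE_FEATURE_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-12), name

    def test_rotation_180_invariance_with_symmetric_angles(self, rng):
        img = rng.integers(0, 255, (16, 16)).astype(float)
        a = roi_texture_features(img)
        b = roi_texture_features(img[::-1, ::-1])
        for name in TEXTURE_FEATURE_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-9, abs=1e-12), name


class TestDWT:
    def test_level_zero_is_identity(self, rng):
        img = rng.integers(0, 255, (16, 16)).astype(float)
        a = dwt_texture(img, level=0)
        b = roi_texture_features(img)
        assert a == b

    def test_perfect_reconstruction(self, rng):
        import pywt

        img = rng.random((32, 32))
        coeffs = pywt.wavedec2(img, "db4", level=1)
        back = pywt.waverec2(coeffs, "db4")
        assert np.abs(back[:32, :32] - img).max() < 1e-8

    def test_constant_image_approx_band_uniform(self):
        d = dwt_texture(np.full((16, 16), 9.0), level=1)
        assert d["energy"] == pytest.approx(1.0)

    def test_roi_too_small_rejected(self):
        roi = np.zeros((16, 16), dtype=bool)
        roi[5, :] = True  # one-row bounding box
        with pytest.raises(ValueError, match="2\\^level"):
            dwt_texture(np.random.default_rng(0).random((16, 16)), roi_mask=roi, level=3)

    def test_detail_bands_available(self, rng):
        img = rng.random((32, 32))
        d = dwt_texture(img, level=1, include_details=True)
        assert set(d) == {"approx", "horiz", "vert", "diag"}
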