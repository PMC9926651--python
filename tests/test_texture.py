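"""GLCM quantization, co-occurrence tabulation and texture metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degratex import GLCMConfig, Raster, cooccurrence, glcm_metrics, quantize, windowed_glcm
from degratex.texture import METRIC_NAMES


def brute_metrics(P):
    """Independent double-loop evaluation of every metric formula."""
    L = P.shape[0]
    pi = P.sum(axis=1)
    mean = sum(i * pi[i] for i in range(L))
    var = sum((i - mean) ** 2 * pi[i] for i in range(L))
    out = {"mean": mean, "variance": var}
    corr = con = hom = dis = asm = ent = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            corr += (i - mean) * (j - mean) * p
            con += (i - j) ** 2 * p
            hom += p / (1 + (i - j) ** 2)
            dis += abs(i - j) * p
            asm += p * p
            if p > 0:
                ent -= p * np.log(p)
    out["correlation"] = corr / var if var > 0 else 0.0
    out.update(contrast=con, homogeneity=hom, dissimilarity=dis, asm=asm,
               entropy=ent)
    return out


class TestQuantize:
    def test_constant_raster_maps_to_level_zero(self):
        q = quantize(Raster(np.full((5, 5), 3.7)), levels=32)
        assert (q.data == 0).all()

    def test_linear_ramp_fills_every_level_in_order(self):
        vals = np.tile(np.arange(32, dtype=float), (4, 1))
        q = quantize(Raster(vals), levels=32)
        assert np.array_equal(q.data[0], np.arange(32))

    def test_extremes_map_to_extreme_levels(self):
        q = quantize(Raster(np.array([[0.2, 0.8]])), levels=32)
        assert q.data.tolist() == [[0, 31]]

    def test_all_masked_rejected(self):
        r = Raster(np.ones((4, 4)), np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="all-masked"):
            quantize(r)

    def test_shift_invariance_after_quantization(self):
        rng = np.random.default_rng(3)
        vals = rng.random((30, 30))
        cfg = GLCMConfig(window=5, levels=16)
        a = windowed_glcm(Raster(vals), cfg)
        b = windowed_glcm(Raster(vals + 100.0), cfg)
        assert np.allclose(a.values, b.values, equal_nan=True)


class TestCooccurrence:
    def test_uniform_window_concentrates_at_origin(self):
        P = cooccurrence(np.zeros((2, 2), int), (0, 1), levels=2)
        assert P[0, 0] == 1.0

    def test_checkerboard_horizontal_pairs(self):
        cb = np.indices((2, 2)).sum(0) % 2
        P = cooccurrence(cb, (0, 1), levels=2)
        assert P[0, 1] == 0.5 and P[1, 0] == 0.5 and P[0, 0] == 0.0

    def test_symmetric_and_normalized(self):
        rng = np.random.default_rng(1)
        win = rng.integers(0, 6, (9, 9))
        for off in ((0, 1), (1, 1), (1, 0), (1, -1)):
            P = cooccurrence(win, off, levels=6)
            assert np.allclose(P, P.T)
            assert np.isclose(P.sum(), 1.0)

    def test_masked_pixels_excluded(self):
        win = np.array([[0, 1], [1, 1]])
        mask = np.array([[True, False], [False, False]])
        P = cooccurrence(win, (0, 1), levels=2, mask=mask)
        # only the bottom-row pair (1,1) survives
        assert P[1, 1] == 1.0

    def test_no_valid_pairs_raises(self):
        with pytest.raises(ValueError, match="pairs"):
            cooccurrence(np.zeros((2, 2), int), (0, 1), levels=2,
                         mask=np.ones((2, 2), bool))

    def test_matches_skimage_reference(self):
        """Cross-check against the standard image-analysis implementation."""
        skimage = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(5)
        win = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        P_ref = skimage.graycomatrix(win, [1], [0], levels=8, symmetric=True,
                                     normed=True)[:, :, 0, 0]
        P = cooccurrence(win, (0, 1), levels=8)
        assert np.allclose(P, P_ref)


class TestMetrics:
    def test_single_level_matrix(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        m = glcm_metrics(P)
        assert m["contrast"] == 0 and m["dissimilarity"] == 0
        assert m["homogeneity"] == 1 and m["asm"] == 1 and m["entropy"] == 0
        assert m["mean"] == 0 and m["variance"] == 0 and m["correlation"] == 0

    def test_two_level_antidiagonal_closed_form(self):
        m = glcm_metrics(np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert m["mean"] == pytest.approx(0.5, abs=1e-12)
        assert m["variance"] == pytest.approx(0.25, abs=1e-12)
        assert m["correlation"] == pytest.approx(-1.0, abs=1e-12)
        assert m["contrast"] == pytest.approx(1.0, abs=1e-12)
        assert m["homogeneity"] == pytest.approx(0.5, abs=1e-12)
        assert m["dissimilarity"] == pytest.approx(1.0, abs=1e-12)
        assert m["asm"] == pytest.approx(0.5, abs=1e-12)
        assert m["entropy"] == pytest.approx(np.log(2), abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_equals_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 9))
        C = rng.random((L, L))
        P = C + C.T
        P /= P.sum()
        m = glcm_metrics(P)
        ref = brute_metrics(P)
        for k in METRIC_NAMES:
            assert m[k] == pytest.approx(ref[k], abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_metric_ranges(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.random((6, 6))
        P = (C + C.T) / (C + C.T).sum()
        m = glcm_metrics(P)
        assert 0 < m["homogeneity"] <= 1
        assert 0 < m["asm"] <= 1
        assert 0 <= m["entropy"] <= 2 * np.log(6)
        assert m["contrast"] >= 0


class TestWindowed:
    def test_constant_raster_degenerate_bands(self):
        out = windowed_glcm(Raster(np.full((20, 20), 0.4)), GLCMConfig(window=5))
        v = out.values
        names = list(METRIC_NAMES)
        inner = ~out.mask[0]
        assert np.allclose(v[names.index("contrast")][inner], 0)
        assert np.allclose(v[names.index("homogeneity")][inner], 1)

    def test_border_trimmed_to_window_width(self):
        out = windowed_glcm(Raster(np.random.default_rng(0).random((25, 25))),
                            GLCMConfig(window=5))
        m = out.mask[0]
        assert m[:5].all() and m[-5:].all() and m[:, :5].all() and m[:, -5:].all()
        assert not m[5:-5, 5:-5].any()

    def test_fast_engine_matches_naive_with_mask(self):
        rng = np.random.default_rng(11)
        vals = rng.random((30, 30))
        mask = rng.random((30, 30)) < 0.15
        r = Raster(vals, mask)
        cfg = GLCMConfig(window=5, levels=8)
        fast = windowed_glcm(r, cfg, engine="fast")
        naive = windowed_glcm(r, cfg, engine="naive")
        assert np.array_equal(fast.mask, naive.mask)
        assert np.allclose(fast.values, naive.values, atol=1e-10, equal_nan=True)

    def test_window_larger_than_raster_rejected(self):
        with pytest.raises(ValueError, match="window"):
            windowed_glcm(Raster(np.ones((10, 10))), GLCMConfig(window=11))
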