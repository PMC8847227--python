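"""Segmentation primitives against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hempspec.io import HyperspectralCube
from hempspec.segment import (
    BandPair,
    SegmentationConfig,
    compute_nbd,
    intermode_threshold,
    locate_reference,
    make_band_pair,
    otsu_contrast,
    segment_scene,
    select_band_pair,
)
from hempspec.simulate import build_scene_design, render_scene

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def brute_force_otsu(values, n_candidates=256):
    """Per-candidate loop: partition actual values, score between/total."""
    v = np.asarray(values, float).ravel()
    v = v[np.isfinite(v)]
    edges = np.linspace(v.min(), v.max(), n_candidates + 1)
    total_var = v.var()
    best = None
    for t in 0.5 * (edges[:-1] + edges[1:]):
        g0, g1 = v[v <= t], v[v > t]
        if len(g0) == 0 or len(g1) == 0:
            continue
        w0 = len(g0) / len(v)
        score = w0 * (1 - w0) * (g0.mean() - g1.mean()) ** 2 / total_var
        if best is None or score > best[0]:
            best = (score, t)
    return best


def naive_peak_positions(h):
    runs, s = [], 0
    for i in range(1, len(h) + 1):
        if i == len(h) or h[i] != h[s]:
            runs.append((h[s], s, i - 1))
            s = i
    peaks = []
    for r, (val, a, b) in enumerate(runs):
        left = runs[r - 1][0] if r > 0 else float("-inf")
        right = runs[r + 1][0] if r < len(runs) - 1 else float("-inf")
        if val > left and val > right:
            peaks.append((a + b) / 2)
    return peaks


def naive_intermodes(values, bins=256, max_iter=10000):
    """Step-by-step reimplementation of the smoothing loop (scalar ops)."""
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    h = hist.astype(float)
    iterations = 0
    while True:
        peaks = naive_peak_positions(h)
        if len(peaks) == 2:
            break
        if len(peaks) < 2 or iterations >= max_iter:
            raise RuntimeError("no bimodal structure")
        h = np.array(
            [
                (h[max(i - 1, 0)] + h[i] + h[min(i + 1, len(h) - 1)]) / 3
                for i in range(len(h))
            ]
        )
        iterations += 1
    width = edges[1] - edges[0]
    pos = [edges[0] + width * (p + 0.5) for p in peaks]
    return 0.5 * (pos[0] + pos[1]), iterations


def exhaustive_pair_search(cube, n_candidates=256):
    """Double-loop over all ordered band pairs with the brute-force scorer."""
    best = None
    flat = cube.values.reshape(-1, cube.n_bands)
    for i1 in range(cube.n_bands):
        for i2 in range(i1):
            denom = flat[:, i1] + flat[:, i2]
            ok = denom > 1e-6 * (cube.values.max() - cube.values.min())
            nbd = (flat[ok, i1] - flat[ok, i2]) / denom[ok]
            if len(set(nbd.tolist())) < 2:
                continue
            res = brute_force_otsu(nbd, n_candidates)
            if res is None:
                continue
            key = (res[0], cube.wavelengths[i1], -cube.wavelengths[i2])
            if best is None or key > best[0]:
                best = (key, (i1, i2))
    return best[1], best[0][0]


# ---------------------------------------------------------------------------
# NBD
# ---------------------------------------------------------------------------


class TestNBD:
    def _cube(self, r1, r2):
        values = np.zeros((1, 1, 2))
        values[0, 0] = [r2, r1]
        return HyperspectralCube(values=values, wavelengths=[474.0, 898.0])

    def test_closed_form(self):
        cube = self._cube(0.5, 0.1)
        nbd = compute_nbd(cube, make_band_pair(cube, 898, 474))
        assert nbd.values[0, 0] == pytest.approx(0.4 / 0.6)

    def test_equal_bands_give_zero(self):
        cube = self._cube(0.3, 0.3)
        nbd = compute_nbd(cube, make_band_pair(cube, 898, 474))
        assert nbd.values[0, 0] == 0.0

    def test_zero_denominator_flagged_not_nan_propagated(self):
        values = np.zeros((1, 2, 2))
        values[0, 1] = [0.2, 0.4]
        cube = HyperspectralCube(values=values, wavelengths=[474.0, 898.0])
        nbd = compute_nbd(cube, make_band_pair(cube, 898, 474))
        assert not nbd.defined[0, 0] and np.isnan(nbd.values[0, 0])
        assert nbd.defined[0, 1]

    def test_reversed_pair_rejected(self):
        with pytest.raises(ValueError, match="lambda1 > lambda2"):
            BandPair(lambda1=474.0, lambda2=898.0, index1=0, index2=1)

    def test_absent_wavelength_rejected(self, small_scene):
        _, cube, _, _ = small_scene
        with pytest.raises(KeyError):
            make_band_pair(cube, 2000.0, 474.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_values_in_unit_band_for_any_nonnegative_cube(self, seed):
        r = np.random.default_rng(seed)
        values = r.gamma(1.0, 1.0, size=(4, 5, 3))
        cube = HyperspectralCube(values=values, wavelengths=[450.0, 550.0, 650.0])
        nbd = compute_nbd(cube, make_band_pair(cube, 650, 450))
        defined = nbd.values[nbd.defined]
        assert np.all(defined >= -1.0) and np.all(defined <= 1.0)


# ---------------------------------------------------------------------------
# Otsu contrast
# ---------------------------------------------------------------------------


class TestOtsuContrast:
    def test_two_valued_data_perfectly_separated(self):
        values = np.array([0.0] * 10 + [1.0] * 54)
        assert otsu_contrast(values).score == pytest.approx(1.0)

    def test_matches_brute_force_on_random_images(self):
        for seed in range(10):
            v = np.random.default_rng(seed).random(64)
            ours = otsu_contrast(v)
            best_score, best_t = brute_force_otsu(v)
            assert ours.score == pytest.approx(best_score, rel=1e-10)
            assert ours.threshold == pytest.approx(best_t, abs=1e-12)

    def test_constant_image_degenerate(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_contrast(np.full(32, 0.7))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        st.integers(0, 10_000),
        st.floats(0.1, 50.0),
        st.floats(-10.0, 10.0),
    )
    def test_affine_invariance(self, seed, scale, shift):
        v = np.random.default_rng(seed).random(128)
        a = otsu_contrast(v)
        b = otsu_contrast(scale * v + shift)
        assert b.score == pytest.approx(a.score, rel=1e-8)


# ---------------------------------------------------------------------------
# Band-pair selection
# ---------------------------------------------------------------------------


class TestBandPairSelection:
    def _toy_cube(self, seed=0, n_bands=8):
        """Only one band separates the two pixel classes; the rest are noise."""
        r = np.random.default_rng(seed)
        n_px = 60
        values = 0.5 + 0.01 * r.standard_normal((1, n_px, n_bands))
        values[0, : n_px // 2, 5] = 0.9 + 0.01 * r.standard_normal(n_px // 2)
        values[0, n_px // 2 :, 5] = 0.1 + 0.01 * abs(r.standard_normal(n_px // 2))
        wl = np.linspace(400, 1000, n_bands)
        return HyperspectralCube(values=np.abs(values), wavelengths=wl)

    def test_discriminative_band_is_selected(self):
        cube = self._toy_cube()
        pair, _, _ = select_band_pair(cube, stride=1)
        assert 5 in (pair.index1, pair.index2)

    def test_matches_exhaustive_double_loop(self):
        for seed in range(5):
            cube = self._toy_cube(seed=seed)
            pair, contrast, _ = select_band_pair(cube, stride=1)
            (i1, i2), best_score = exhaustive_pair_search(cube)
            assert (pair.index1, pair.index2) == (i1, i2)
            assert contrast.score == pytest.approx(best_score, rel=1e-10)

    def test_stride_subset_monotonicity(self):
        cube = self._toy_cube(n_bands=12)
        _, s1, _ = select_band_pair(cube, stride=1)
        _, s3, _ = select_band_pair(cube, stride=3)
        assert s1.score >= s3.score - 1e-12

    def test_too_few_bands_after_striding(self):
        cube = self._toy_cube()
        with pytest.raises(ValueError, match="striding"):
            select_band_pair(cube, stride=10)


# ---------------------------------------------------------------------------
# Intermodes thresholding
# ---------------------------------------------------------------------------


class TestIntermodes:
    def test_two_delta_peaks(self):
        values = np.array([0.0] * 50 + [0.8] * 50)
        thr, iters, _ = intermode_threshold(values, bins=9)
        # peaks sit in the outermost bins of [0, 0.8]; midpoint of their centers
        assert thr == pytest.approx(0.4, abs=0.05)
        assert iters == 0

    def test_already_bimodal_needs_no_smoothing(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 0.01, 500), rng.normal(1, 0.01, 500)])
        _, iters, _ = intermode_threshold(values, bins=16)
        assert iters == 0

    def test_matches_naive_oracle_on_random_mixtures(self):
        agree = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            n1, n2 = r.integers(50, 300, size=2)
            values = np.concatenate(
                [
                    r.normal(0.0, 0.08 + 0.1 * r.random(), n1),
                    r.normal(0.8, 0.08 + 0.1 * r.random(), n2),
                ]
            )
            try:
                expected = naive_intermodes(values, bins=64)
            except RuntimeError:
                with pytest.raises(RuntimeError):
                    intermode_threshold(values, bins=64)
                continue
            thr, iters, _ = intermode_threshold(values, bins=64)
            assert (thr, iters) == (pytest.approx(expected[0]), expected[1])
            agree += 1
        assert agree >= 90  # near-degenerate mixtures may legitimately fail both

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError):
            intermode_threshold(np.full(10, 3.0))

    def test_unimodal_input_raises_convergence_error(self):
        values = np.random.default_rng(1).normal(0, 1, 2000)
        with pytest.raises(RuntimeError):
            intermode_threshold(values, bins=32)


# ---------------------------------------------------------------------------
# Scene segmentation + reference localization
# ---------------------------------------------------------------------------


class TestSegmentScene:
    def test_iou_and_region_count_on_synthetic_scene(self, small_scene):
        design, cube, gt, meta = small_scene
        pair, _, _ = select_band_pair(cube, stride=10)
        result = segment_scene(cube, pair)
        truth = gt > 0
        iou = (result.mask & truth).sum() / (result.mask | truth).sum()
        assert iou >= 0.95
        assert result.regions.max() == 8

    def test_small_speck_removed(self, small_scene):
        design, cube, gt, meta = small_scene
        pair, _, _ = select_band_pair(cube, stride=10)
        result = segment_scene(cube, pair, SegmentationConfig(min_area=50))
        assert int(result.region_table["area"].min()) >= 50

    def test_regions_partition_mask(self, small_scene):
        design, cube, gt, meta = small_scene
        pair, _, _ = select_band_pair(cube, stride=10)
        result = segment_scene(cube, pair)
        assert np.array_equal(result.regions > 0, result.mask)

    def test_reference_roi_mode(self, small_scene):
        design, cube, gt, meta = small_scene
        pair, _, _ = select_band_pair(cube, stride=10)
        result = segment_scene(cube, pair)
        ref = locate_reference(cube, result, mode="roi", roi_rect=design.reference_rect)
        l0, p0, h, w = design.reference_rect
        expected = np.zeros(gt.shape, dtype=bool)
        expected[l0 : l0 + h, p0 : p0 + w] = True
        np.testing.assert_array_equal(ref.mask, expected)

    def test_reference_flatness_prefers_panel_over_leaves(self, small_scene):
        design, cube, gt, meta = small_scene
        pair, _, _ = select_band_pair(cube, stride=10)
        result = segment_scene(cube, pair)
        ref = locate_reference(cube, result, mode="flatness")
        l0, p0, h, w = design.reference_rect
        panel = np.zeros(gt.shape, dtype=bool)
        panel[l0 : l0 + h, p0 : p0 + w] = True
        overlap = (ref.mask & panel).sum() / ref.mask.sum()
        assert overlap > 0.9
        assert not np.any(ref.mask & (gt > 0))

    def test_no_panel_means_no_reference(self, class_models, wl120):
        design = build_scene_design(
            [("CW", "wk02", "leaf")] * 4, reference_rect=None, seed=5
        )
        cube, _, _ = render_scene(design, class_models, wl120)
        pair, _, _ = select_band_pair(cube, stride=10)
        result = segment_scene(cube, pair)
        assert locate_reference(cube, result, mode="flatness") is None

    def test_roi_outside_image_rejected(self, small_scene):
        design, cube, gt, meta = small_scene
        pair, _, _ = select_band_pair(cube, stride=10)
        result = segment_scene(cube, pair)
        with pytest.raises(ValueError, match="outside"):
            locate_reference(cube, result, mode="roi", roi_rect=(500, 500, 10, 10))
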