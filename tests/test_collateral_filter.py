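"""Oracle-checked tests of both collateral-filter backends."""

import math

import numpy as np
import pytest
from scipy import ndimage

from mrdenoise.collateral_filter import (
    FilterParams,
    TileSpec,
    agreement_probability,
    binary_entropy_terms,
    blend_image,
    collateral_filter,
    ensemble_weight,
    entropy_map,
    filter_reference,
    filter_tiled,
    median_image,
    median_weight,
    radiometric_weight,
    spatial_weight_buffer,
    weight_components,
)
from mrdenoise.image import Image2D
from mrdenoise.phantom_generator import PhantomSpec, make_phantom
from mrdenoise.quality_metrics import psnr

from conftest import make_image


# ---------------------------------------------------------------- oracles

def oracle_median(px, radius):
    """Brute-force per-pixel sort-and-pick median with edge replication."""
    pad = np.pad(px, radius, mode="edge")
    out = np.empty_like(px)
    m, n = px.shape
    for x in range(m):
        for y in range(n):
            window = pad[x : x + 2 * radius + 1, y : y + 2 * radius + 1]
            out[x, y] = np.sort(window.ravel())[window.size // 2]
    return out


def oracle_entropy(p_map, radius):
    """Double-loop windowed sum of binary-entropy terms, edge-replicated."""
    h = np.zeros_like(p_map)
    for x in range(p_map.shape[0]):
        for y in range(p_map.shape[1]):
            p = p_map[x, y]
            for q in (p, 1.0 - p):
                if q > 0:
                    h[x, y] += q * math.log(q)
    pad = np.pad(h, radius, mode="edge")
    out = np.empty_like(p_map)
    for x in range(p_map.shape[0]):
        for y in range(p_map.shape[1]):
            out[x, y] = -pad[x : x + 2 * radius + 1, y : y + 2 * radius + 1].sum()
    return out


def oracle_collateral(px, max_i, params):
    """Fully independent quadruple-loop re-derivation of the filter.

    Recomputes the median image, agreement probability, window entropy,
    all three kernels (with direct pow, not log-space) and the normalized
    weighted blend average per pixel from scratch.
    """
    n = params.radius
    m, w = px.shape
    med = oracle_median(px, n)
    p = (1.0 - np.abs(px - med) / max_i) ** 2 / 2.0 + 0.5
    ip = np.pad(px, n, mode="edge")
    mp = np.pad(med, n, mode="edge")
    pp = np.pad(p, n, mode="edge")
    out = np.empty_like(px)
    for x in range(m):
        for y in range(w):
            H = 0.0
            for dx in range(-n, n + 1):
                for dy in range(-n, n + 1):
                    pv = pp[x + n + dx, y + n + dy]
                    for q in (pv, 1.0 - pv):
                        if q > 0:
                            H -= q * math.log(q)
            H = max(H, 0.0)
            num = den = 0.0
            for dx in range(-n, n + 1):
                for dy in range(-n, n + 1):
                    iv = ip[x + n + dx, y + n + dy]
                    mv = mp[x + n + dx, y + n + dy]
                    ws = math.exp(-(dx**2 + dy**2) / (2 * params.sigma_s**2))
                    wr = math.exp(-((iv - px[x, y]) ** 2) / (2 * params.sigma_r**2))
                    wm = math.exp(-((mv - med[x, y]) ** 2) / (2 * params.sigma_m**2))
                    wgt = ws * wr ** (1.0 / (1.0 + H)) * wm**H
                    if params.beta_mode == "adaptive":
                        beta = 1.0 - pp[x + n + dx, y + n + dy]
                    else:
                        beta = params.beta
                    num += wgt * ((1.0 - beta) * iv + beta * mv)
                    den += wgt
            out[x, y] = num / den
    return out


# ----------------------------------------------------------------- median

class TestMedianImage:
    def test_constant_is_identity(self, constant_image):
        assert np.array_equal(median_image(constant_image).pixels, constant_image.pixels)

    def test_single_outlier_removed(self):
        img = Image2D(np.array([[0, 0, 0], [0, 255, 0], [0, 0, 0]], dtype=float), 255.0)
        assert median_image(img, 1).pixels[1, 1] == 0.0

    def test_matches_sort_oracle(self, rng):
        px = rng.integers(0, 256, size=(5, 5)).astype(float)
        img = Image2D(px, 255.0)
        assert np.array_equal(median_image(img, 1).pixels, oracle_median(px, 1))

    def test_invalid_radius(self, random_image):
        with pytest.raises(ValueError):
            median_image(random_image, 0)

    def test_max_intensity_preserved(self, random_image):
        assert median_image(random_image).max_intensity == random_image.max_intensity


# ---------------------------------------------------- spatial weight buffer

class TestSpatialWeightBuffer:
    def test_zero_offset_is_one(self):
        wsb = spatial_weight_buffer(FilterParams(radius=3))
        assert wsb[0, 0] == 1.0

    def test_unit_sigma_value(self):
        wsb = spatial_weight_buffer(FilterParams(radius=1, sigma_s=1.0))
        assert wsb[1, 0] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_symmetric_in_offsets(self):
        wsb = spatial_weight_buffer(FilterParams(radius=4, sigma_s=1.7))
        assert np.array_equal(wsb, wsb.T)

    def test_lookup_reproduces_direct_form(self, rng):
        params = FilterParams(radius=3, sigma_s=1.3)
        wsb = spatial_weight_buffer(params)
        for _ in range(20):
            mu = rng.integers(-3, 4, size=2)
            direct = math.exp(-(mu[0] ** 2 + mu[1] ** 2) / (2 * params.sigma_s**2))
            assert wsb[abs(mu[0]), abs(mu[1])] == pytest.approx(direct, rel=1e-15)


# ----------------------------------------------------------- range kernels

class TestRangeKernels:
    def test_equal_values_give_one(self):
        assert radiometric_weight(5.0, 5.0, 2.0) == 1.0
        assert median_weight(7.0, 7.0, 3.0) == 1.0

    def test_unit_standardized_difference(self):
        assert radiometric_weight(0.0, 2.0, 2.0) == pytest.approx(math.exp(-0.5))
        assert median_weight(0.0, 4.0, 2.0) == pytest.approx(math.exp(-2.0))

    def test_random_pairs_match_scalar_oracle(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0, 255, size=2)
            s = rng.uniform(0.5, 50)
            assert radiometric_weight(a, b, s) == pytest.approx(
                math.exp(-((b - a) ** 2) / (2 * s**2)), rel=1e-15)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            radiometric_weight(1.0, 2.0, 0.0)


# ---------------------------------------------------- agreement probability

class TestAgreementProbability:
    def test_full_agreement(self, random_image):
        p = agreement_probability(random_image, random_image)
        assert np.array_equal(p, np.ones(random_image.shape))

    def test_max_disagreement(self):
        img = Image2D(np.array([[0.0]]), 1.0)
        med = Image2D(np.array([[1.0]]), 1.0)
        assert agreement_probability(img, med)[0, 0] == 0.5

    def test_half_disagreement(self):
        img = Image2D(np.array([[0.0]]), 1.0)
        med = Image2D(np.array([[0.5]]), 1.0)
        assert agreement_probability(img, med)[0, 0] == pytest.approx(0.625)

    def test_range(self, rng):
        img = make_image(rng)
        med = median_image(img)
        p = agreement_probability(img, med)
        assert p.min() >= 0.5 and p.max() <= 1.0

    def test_zero_max_intensity_rejected(self):
        with pytest.raises(ValueError):
            Image2D(np.zeros((2, 2)), 0.0)


# -------------------------------------------------------------- entropy map

class TestEntropyMap:
    def test_perfect_agreement_zero_entropy(self):
        H = entropy_map(np.ones((8, 8)), FilterParams(radius=1))
        assert np.array_equal(H, np.zeros((8, 8)))

    def test_uniform_half_probability(self):
        H = entropy_map(np.full((8, 8), 0.5), FilterParams(radius=1))
        assert np.allclose(H, 9 * math.log(2), atol=1e-10)
        assert H[0, 0] == pytest.approx(6.2383, abs=1e-4)

    def test_matches_window_sum_oracle(self, rng):
        p = rng.uniform(0.5, 1.0, size=(9, 11))
        for radius in (1, 2):
            H = entropy_map(p, FilterParams(radius=radius))
            assert np.allclose(H, oracle_entropy(p, radius), atol=1e-10)

    def test_nonnegative(self, rng):
        p = rng.uniform(0.5, 1.0, size=(12, 12))
        assert entropy_map(p, FilterParams()).min() >= 0.0


# ---------------------------------------------------------- ensemble weight

class TestEnsembleWeight:
    def test_zero_entropy_drops_median_kernel(self):
        assert ensemble_weight(0.7, 0.4, 0.2, 0.0) == pytest.approx(0.7 * 0.4, rel=1e-12)

    def test_unit_range_kernels_give_spatial(self, rng):
        for h in (0.0, 1.0, 5.0, 40.0):
            assert ensemble_weight(0.3, 1.0, 1.0, h) == pytest.approx(0.3, rel=1e-12)

    def test_matches_pow_oracle(self, rng):
        for _ in range(100):
            ws, wr, wm = rng.uniform(0.01, 1.0, size=3)
            h = rng.uniform(0.0, 10.0)
            naive = ws * wr ** (1.0 / (1.0 + h)) * wm**h
            assert ensemble_weight(ws, wr, wm, h) == pytest.approx(naive, rel=1e-12)

    def test_no_underflow_at_large_entropy(self):
        # naive pow underflows: 1e-10 ** 600 == 0; log space stays finite logic-wise
        w = ensemble_weight(1.0, 1.0, 1e-10, 600.0)
        assert w == 0.0 or w > 0.0  # no nan/inf
        assert np.isfinite(w)


# ------------------------------------------------------------------- blend

class TestBlend:
    def _pair(self):
        img = Image2D(np.array([[10.0]]), 255.0)
        med = Image2D(np.array([[20.0]]), 255.0)
        return img, med

    def test_beta_zero_returns_input(self):
        img, med = self._pair()
        assert blend_image(img, med, FilterParams(beta=0.0))[0, 0] == 10.0

    def test_beta_one_returns_median(self):
        img, med = self._pair()
        assert blend_image(img, med, FilterParams(beta=1.0))[0, 0] == 20.0

    def test_beta_half_is_mean(self):
        img, med = self._pair()
        assert blend_image(img, med, FilterParams(beta=0.5))[0, 0] == 15.0

    def test_invalid_beta(self):
        img, med = self._pair()
        with pytest.raises(ValueError):
            blend_image(img, med, FilterParams(beta=1.5))

    def test_adaptive_uses_one_minus_p(self, rng):
        img = make_image(rng, (6, 6))
        med = median_image(img)
        p = agreement_probability(img, med)
        got = blend_image(img, med, FilterParams(beta_mode="adaptive"))
        expect = img.pixels + (1.0 - p) * (med.pixels - img.pixels)
        assert np.allclose(got, expect, atol=1e-15)


# -------------------------------------------------------- reference filter

class TestFilterReference:
    def test_constant_image_identity(self, constant_image):
        out = filter_reference(constant_image, FilterParams(sigma_r=0.1, sigma_m=0.1))
        assert np.array_equal(out.pixels, constant_image.pixels)

    @pytest.mark.parametrize("beta_mode,beta", [("scalar", 0.0), ("scalar", 0.4),
                                                ("scalar", 1.0), ("adaptive", 0.5)])
    def test_matches_quadruple_loop_oracle(self, rng, beta_mode, beta):
        px = rng.uniform(0, 255, size=(7, 7))
        img = Image2D(px, 255.0)
        params = FilterParams(radius=1, sigma_s=1.1, sigma_r=30.0, sigma_m=25.0,
                              beta=beta, beta_mode=beta_mode)
        got = filter_reference(img, params).pixels
        want = oracle_collateral(px, 255.0, params)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-12 * 255.0)

    def test_gaussian_limit(self, rng):
        px = rng.uniform(0, 1, size=(12, 14))
        img = Image2D(px, 1.0)
        params = FilterParams(radius=1, sigma_s=0.8, sigma_r=1e12, sigma_m=1e12, beta=0.0)
        got = filter_reference(img, params).pixels
        kernel = spatial_weight_buffer(params)
        offs = np.abs(np.arange(-1, 2))
        full = kernel[offs[:, None], offs[None, :]]
        pad = np.pad(px, 1, mode="edge")
        want = np.empty_like(px)
        for x in range(px.shape[0]):
            for y in range(px.shape[1]):
                win = pad[x : x + 3, y : y + 3]
                want[x, y] = (full * win).sum() / full.sum()
        assert np.allclose(got, want, rtol=1e-8)

    def test_invalid_sigma_rejected(self, random_image):
        with pytest.raises(ValueError):
            filter_reference(random_image, FilterParams(sigma_r=0.0))

    def test_output_in_range(self, rng):
        img = make_image(rng, (20, 20))
        out = filter_reference(img, FilterParams(sigma_r=0.05, sigma_m=0.05, beta=0.3))
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_range_bounded_by_window_blend_extremes(self, rng):
        img = make_image(rng, (10, 10))
        params = FilterParams(sigma_r=0.08, sigma_m=0.1, beta=0.35)
        med = median_image(img)
        blend = blend_image(img, med, params)
        out = filter_reference(img, params).pixels
        lo = ndimage.minimum_filter(blend, size=3, mode="nearest")
        hi = ndimage.maximum_filter(blend, size=3, mode="nearest")
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


# ------------------------------------------------------------ tiled filter

class TestFilterTiled:
    def test_single_tile_degenerates_to_reference(self, rng):
        img = make_image(rng, (9, 13))
        params = FilterParams(sigma_r=0.1, sigma_m=0.12, beta=0.6)
        ref = filter_reference(img, params).pixels
        got = filter_tiled(img, params, TileSpec(tile_side=32)).pixels
        assert np.abs(got - ref).max() < 1e-10

    def test_brainweb_sized_image(self, rng):
        img = Image2D(rng.uniform(0, 1, size=(181, 217)), 1.0)
        params = FilterParams(sigma_s=1.5, sigma_r=0.1, sigma_m=0.2, beta=0.4)
        ref = filter_reference(img, params).pixels
        got = filter_tiled(img, params, TileSpec(tile_side=16)).pixels
        assert np.abs(got - ref).max() < 1e-10

    def test_constant_image_identity(self, constant_image):
        out = filter_tiled(constant_image, FilterParams(sigma_r=0.1, sigma_m=0.1))
        assert np.array_equal(out.pixels, constant_image.pixels)

    @pytest.mark.parametrize("tile_side", [1, 3, 5, 16])
    def test_equivalence_over_tile_sizes(self, rng, tile_side):
        img = make_image(rng, (17, 23))
        params = FilterParams(radius=2, sigma_s=1.2, sigma_r=0.15, sigma_m=0.1,
                              beta_mode="adaptive")
        ref = filter_reference(img, params).pixels
        got = filter_tiled(img, params, TileSpec(tile_side=tile_side)).pixels
        assert np.abs(got - ref).max() < 1e-10

    def test_equivalence_random_images_and_params(self, rng):
        for _ in range(10):
            shape = (int(rng.integers(5, 64)), int(rng.integers(5, 64)))
            img = make_image(rng, shape)
            params = FilterParams(
                radius=int(rng.integers(1, 3)),
                sigma_s=float(rng.uniform(0.5, 3.0)),
                sigma_r=float(rng.uniform(0.02, 0.5)),
                sigma_m=float(rng.uniform(0.02, 0.5)),
                beta=float(rng.uniform(0, 1)),
            )
            tiles = TileSpec(tile_side=int(rng.integers(1, 33)))
            diff = np.abs(filter_tiled(img, params, tiles).pixels
                          - filter_reference(img, params).pixels).max()
            assert diff < 1e-10

    def test_invalid_tile_side(self, random_image):
        with pytest.raises(ValueError):
            filter_tiled(random_image, FilterParams(), TileSpec(tile_side=0))

    def test_backend_dispatch(self, random_image):
        params = FilterParams(sigma_r=0.1, sigma_m=0.1)
        a = collateral_filter(random_image, params, backend="reference").pixels
        b = collateral_filter(random_image, params, backend="tiled").pixels
        assert np.abs(a - b).max() < 1e-10
        with pytest.raises(ValueError):
            collateral_filter(random_image, params, backend="cuda")


# -------------------------------------------------------------- properties

class TestProperties:
    def test_entropy_zero_iff_median_equals_image(self):
        # a step image whose 3x3 medians equal the image -> H = 0 everywhere
        px = np.zeros((8, 8))
        px[:, 4:] = 1.0
        img = Image2D(px, 1.0)
        med = median_image(img)
        assert np.array_equal(med.pixels, px)
        p = agreement_probability(img, med)
        assert np.array_equal(entropy_map(p, FilterParams()), np.zeros((8, 8)))

    def test_entropy_positive_when_median_differs(self):
        px = np.zeros((5, 5))
        px[2, 2] = 1.0
        img = Image2D(px, 1.0)
        p = agreement_probability(img, median_image(img))
        H = entropy_map(p, FilterParams())
        assert H[2, 2] > 0.0

    def test_denoising_improves_psnr_at_5pct(self):
        pair = make_phantom(PhantomSpec(noise_level=0.05, seed=11))
        params = FilterParams(sigma_s=1.0, sigma_r=0.2, sigma_m=0.2, beta=0.5)
        restored = filter_tiled(pair.noisy, params)
        assert psnr(pair.clean, restored) > psnr(pair.clean, pair.noisy)

    def test_weight_components_in_unit_interval(self, rng):
        img = make_image(rng, (8, 8))
        wc = weight_components(img, FilterParams(sigma_r=0.1, sigma_m=0.1), (4, 4))
        for arr in (wc.ws, wc.wr, wc.wm, wc.ensemble):
            assert arr.min() > 0.0 and arr.max() <= 1.0
        assert wc.entropy >= 0.0
        assert wc.ensemble[1, 1] == pytest.approx(1.0)  # center weight
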