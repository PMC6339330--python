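"""Entropy-balanced bilateral/median ("collateral") filtering.

The filter combines three Gaussian kernels — spatial, radiometric and
median-radiometric — per window.  A per-pixel binary-entropy score ``H`` of
the agreement probability ``p`` between the image and its median-filtered
version steers the balance between the radiometric and median kernels:

    W = W_S * W_R ** (1 / (1 + H)) * W_M ** H

The output pixel is the W-weighted average of the blend
``(1 - beta) * I + beta * I_M`` over the window.

Two backends are provided:

``filter_reference``
    Straightforward whole-image evaluation.
``filter_tiled``
    A tiled/buffered schedule that precomputes the spatial weight table,
    per-tile entropy terms and per-tile blend values once per tile apron.
    It is algebraically equivalent to the reference backend and exists so a
    shared-memory GPU port is a mechanical translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import xlogy

from .image import Image2D

__all__ = [
    "FilterParams",
    "TileSpec",
    "WeightComponents",
    "median_image",
    "spatial_weight_buffer",
    "radiometric_weight",
    "median_weight",
    "agreement_probability",
    "entropy_map",
    "ensemble_weight",
    "blend_image",
    "filter_reference",
    "filter_tiled",
    "collateral_filter",
]

#: Weights are clamped here before taking logs so that raising a tiny kernel
#: value to a large entropy power cannot produce -inf intermediates.
_WEIGHT_FLOOR = 1e-300


@dataclass
class FilterParams:
    """Knobs of the collateral filter.

    ``radius`` gives a ``(2*radius+1)**2`` window (default 3x3).  The sigmas
    are the spatial, radiometric and median kernel widths.  ``beta`` blends
    the input with its median-filtered version; in ``adaptive`` mode the
    scalar is ignored and ``beta(x, y) = 1 - p(x, y)`` is used instead.
    """

    radius: int = 1
    sigma_s: float = 1.0
    sigma_r: float = 0.1
    sigma_m: float = 0.1
    beta: float = 0.5
    beta_mode: str = "scalar"

    def validate(self) -> None:
        if int(self.radius) != self.radius or self.radius < 1:
            raise ValueError(f"radius must be an integer >= 1, got {self.radius}")
        for name in ("sigma_s", "sigma_r", "sigma_m"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.beta_mode not in ("scalar", "adaptive"):
            raise ValueError(f"beta_mode must be 'scalar' or 'adaptive', got {self.beta_mode!r}")
        if self.beta_mode == "scalar" and not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")

    @property
    def window_side(self) -> int:
        return 2 * int(self.radius) + 1


@dataclass
class TileSpec:
    """Tiling contract for the buffered backend.

    Each tile produces ``tile_side x tile_side`` output pixels and reads an
    ``(tile_side + 2*halo)``-sided input apron.
    """

    tile_side: int = 16

    def validate(self) -> None:
        if int(self.tile_side) != self.tile_side or self.tile_side < 1:
            raise ValueError(f"tile_side must be an integer >= 1, got {self.tile_side}")


@dataclass
class WeightComponents:
    """Window-shaped weight matrices for a single center pixel (introspection aid)."""

    ws: np.ndarray
    wr: np.ndarray
    wm: np.ndarray
    entropy: float
    ensemble: np.ndarray


def _pad(arr: np.ndarray, n: int) -> np.ndarray:
    return np.pad(arr, n, mode="edge")


def median_image(img: Image2D, radius: int = 1) -> Image2D:
    """Median-filter with a ``(2*radius+1)**2`` window and edge replication."""
    if int(radius) != radius or radius < 1:
        raise ValueError(f"radius must be an integer >= 1, got {radius}")
    med = ndimage.median_filter(img.pixels, size=2 * int(radius) + 1, mode="nearest")
    return img.like(med)


def spatial_weight_buffer(params: FilterParams) -> np.ndarray:
    """Precomputed spatial Gaussian table indexed by absolute pixel offset.

    ``wsb[dx, dy] = exp(-(dx**2 + dy**2) / (2 * sigma_s**2))`` for
    ``0 <= dx, dy <= radius``; a window lookup with ``|mu - theta|``
    reproduces the per-pixel spatial kernel exactly.
    """
    params.validate()
    d = np.arange(params.radius + 1, dtype=np.float64)
    dx2 = d[:, None] ** 2
    dy2 = d[None, :] ** 2
    return np.exp(-(dx2 + dy2) / (2.0 * params.sigma_s**2))


def radiometric_weight(center_val, neighbor_val, sigma_r: float):
    """Gaussian similarity of two intensities (range kernel)."""
    if sigma_r <= 0:
        raise ValueError(f"sigma_r must be > 0, got {sigma_r}")
    diff = np.asarray(neighbor_val, dtype=np.float64) - np.asarray(center_val, dtype=np.float64)
    return np.exp(-(diff**2) / (2.0 * sigma_r**2))


def median_weight(center_med, neighbor_med, sigma_m: float):
    """Range kernel evaluated on the median-filtered image."""
    if sigma_m <= 0:
        raise ValueError(f"sigma_m must be > 0, got {sigma_m}")
    return radiometric_weight(center_med, neighbor_med, sigma_m)


def agreement_probability(img: Image2D, med: Image2D) -> np.ndarray:
    """Per-pixel probability that the image agrees with its median filter.

    ``p = (1 - |I - I_M| / MAX_I)**2 / 2 + 0.5``, which maps agreement to 1
    and maximal disagreement to 0.5.
    """
    if img.shape != med.shape:
        raise ValueError("image and median image must share shape")
    if img.max_intensity <= 0:
        raise ValueError("max_intensity must be positive")
    frac = np.abs(img.pixels - med.pixels) / img.max_intensity
    return (1.0 - frac) ** 2 / 2.0 + 0.5


def binary_entropy_terms(p_map: np.ndarray) -> np.ndarray:
    """Per-pixel ``p*log(p) + (1-p)*log(1-p)`` with the 0*log(0) = 0 convention.

    Natural logarithm; nonpositive by construction.
    """
    p = np.asarray(p_map, dtype=np.float64)
    return xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)


def entropy_map(p_map: np.ndarray, params: FilterParams) -> np.ndarray:
    """Windowed negative sum of the binary-entropy terms (edge-replicated)."""
    h = binary_entropy_terms(p_map)
    side = params.window_side
    total = ndimage.uniform_filter(h, size=side, mode="nearest") * float(side * side)
    return np.maximum(-total, 0.0)


def ensemble_weight(ws, wr, wm, entropy):
    """Combine the three kernels: ``W = ws * wr**(1/(1+H)) * wm**H``.

    Evaluated in log space so that ``wm**H`` cannot underflow for large
    windows or entropies.  Broadcasts over array inputs.
    """
    ws = np.maximum(np.asarray(ws, dtype=np.float64), _WEIGHT_FLOOR)
    wr = np.maximum(np.asarray(wr, dtype=np.float64), _WEIGHT_FLOOR)
    wm = np.maximum(np.asarray(wm, dtype=np.float64), _WEIGHT_FLOOR)
    h = np.asarray(entropy, dtype=np.float64)
    logw = np.log(ws) + np.log(wr) / (1.0 + h) + h * np.log(wm)
    return np.exp(logw)


def blend_image(img: Image2D, med: Image2D, params: FilterParams,
                p_map: np.ndarray | None = None) -> np.ndarray:
    """The per-pixel blend ``(1 - beta) * I + beta * I_M``.

    In adaptive mode ``beta = 1 - p`` so the median image is trusted more
    where the pixel disagrees with its median (outliers).
    """
    params.validate()
    if params.beta_mode == "adaptive":
        if p_map is None:
            p_map = agreement_probability(img, med)
        beta = 1.0 - p_map
    else:
        if params.beta == 0.0:
            return img.pixels.copy()
        if params.beta == 1.0:
            return med.pixels.copy()
        beta = params.beta
    # evaluated as I + beta*(I_M - I): identical algebraically, but exactly
    # the input wherever I == I_M (so flat images pass through unchanged)
    return img.pixels + beta * (med.pixels - img.pixels)


def _prepare(img: Image2D, params: FilterParams):
    """Shared precomputation: median image, agreement map, entropy map."""
    params.validate()
    med = median_image(img, params.radius)
    p = agreement_probability(img, med)
    h_terms = binary_entropy_terms(p)
    side = params.window_side
    entropy = np.maximum(
        -ndimage.uniform_filter(h_terms, size=side, mode="nearest") * float(side * side), 0.0
    )
    return med, p, entropy


def _filter_core(img: Image2D, med: Image2D, entropy: np.ndarray,
                 blend: np.ndarray, params: FilterParams) -> np.ndarray:
    """Whole-image weighted average given the precomputed maps."""
    n = int(params.radius)
    pixels = img.pixels
    med_px = med.pixels
    ip = _pad(pixels, n)
    mp = _pad(med_px, n)
    bp = _pad(blend, n)
    m, w = pixels.shape
    wsb = spatial_weight_buffer(params)

    inv_r = 1.0 / (2.0 * params.sigma_r**2)
    inv_m = 1.0 / (2.0 * params.sigma_m**2)
    inv_h = 1.0 / (1.0 + entropy)

    # The blend is anchored at the window center: out = b_c + sum(w*(b - b_c))/sum(w).
    # Algebraically identical to the plain weighted average, but exactly
    # idempotent on flat images (every difference term is exactly zero).
    num = np.zeros_like(pixels)
    den = np.zeros_like(pixels)
    for dx in range(-n, n + 1):
        for dy in range(-n, n + 1):
            i_nb = ip[n + dx : n + dx + m, n + dy : n + dy + w]
            m_nb = mp[n + dx : n + dx + m, n + dy : n + dy + w]
            b_nb = bp[n + dx : n + dx + m, n + dy : n + dy + w]
            logw = (
                np.log(wsb[abs(dx), abs(dy)])
                - (i_nb - pixels) ** 2 * inv_r * inv_h
                - entropy * ((m_nb - med_px) ** 2 * inv_m)
            )
            wgt = np.exp(logw)
            num += wgt * (b_nb - blend)
            den += wgt
    return blend + num / den


def filter_reference(img: Image2D, params: FilterParams) -> Image2D:
    """Reference (whole-image) collateral filter."""
    med, p, entropy = _prepare(img, params)
    blend = blend_image(img, med, params, p_map=p)
    out = _filter_core(img, med, entropy, blend, params)
    return img.like(out)


def filter_tiled(img: Image2D, params: FilterParams, tiles: TileSpec | None = None) -> Image2D:
    """Tiled collateral filter, algebraically equivalent to the reference.

    Per tile: the apron of the (globally) median-filtered image is read, the
    binary-entropy terms, tile entropies and blend values are computed once on
    the apron, and the weighted average runs over the tile only.  The spatial
    table is computed once per call.
    """
    if tiles is None:
        tiles = TileSpec()
    tiles.validate()
    params.validate()
    n = int(params.radius)
    s = int(tiles.tile_side)
    pixels = img.pixels
    m, w = pixels.shape
    max_i = img.max_intensity

    med_px = median_image(img, n).pixels  # the median image is a global input
    ip = _pad(pixels, n)
    mp = _pad(med_px, n)
    wsb = spatial_weight_buffer(params)

    inv_r = 1.0 / (2.0 * params.sigma_r**2)
    inv_m = 1.0 / (2.0 * params.sigma_m**2)
    win = params.window_side

    out = np.empty_like(pixels)
    for ti in range(0, m, s):
        for tj in range(0, w, s):
            th = min(s, m - ti)
            tw = min(s, w - tj)
            # apron reads from the padded arrays: (th + 2n) x (tw + 2n)
            ia = ip[ti : ti + th + 2 * n, tj : tj + tw + 2 * n]
            ma = mp[ti : ti + th + 2 * n, tj : tj + tw + 2 * n]

            # per-apron buffers: agreement, entropy terms, blend values
            frac = np.abs(ia - ma) / max_i
            pa = (1.0 - frac) ** 2 / 2.0 + 0.5
            hpb = xlogy(pa, pa) + xlogy(1.0 - pa, 1.0 - pa)
            if params.beta_mode == "adaptive":
                beta_buf = 1.0 - pa
                ba = ia + beta_buf * (ma - ia)
            elif params.beta == 0.0:
                ba = ia.copy()
            elif params.beta == 1.0:
                ba = ma.copy()
            else:
                ba = ia + params.beta * (ma - ia)

            # per-tile entropy: window sum of the buffered terms
            hg = ndimage.uniform_filter(hpb, size=win, mode="nearest")[
                n : n + th, n : n + tw
            ] * float(win * win)
            hg = np.maximum(-hg, 0.0)
            inv_h = 1.0 / (1.0 + hg)

            ic = ia[n : n + th, n : n + tw]
            mc = ma[n : n + th, n : n + tw]
            bc = ba[n : n + th, n : n + tw]
            num = np.zeros((th, tw))
            den = np.zeros((th, tw))
            for dx in range(-n, n + 1):
                for dy in range(-n, n + 1):
                    i_nb = ia[n + dx : n + dx + th, n + dy : n + dy + tw]
                    m_nb = ma[n + dx : n + dx + th, n + dy : n + dy + tw]
                    b_nb = ba[n + dx : n + dx + th, n + dy : n + dy + tw]
                    logw = (
                        np.log(wsb[abs(dx), abs(dy)])
                        - (i_nb - ic) ** 2 * inv_r * inv_h
                        - hg * ((m_nb - mc) ** 2 * inv_m)
                    )
                    wgt = np.exp(logw)
                    num += wgt * (b_nb - bc)
                    den += wgt
            out[ti : ti + th, tj : tj + tw] = bc + num / den
    return img.like(out)


def collateral_filter(img: Image2D, params: FilterParams, backend: str = "tiled",
                      tiles: TileSpec | None = None) -> Image2D:
    """Dispatch to a backend by name (``reference`` or ``tiled``)."""
    if backend == "reference":
        return filter_reference(img, params)
    if backend == "tiled":
        return filter_tiled(img, params, tiles)
    raise ValueError(f"unknown backend {backend!r}")


def weight_components(img: Image2D, params: FilterParams, center: tuple[int, int]) -> WeightComponents:
    """Window weight matrices for one center pixel — for tests and debugging."""
    med, p, entropy = _prepare(img, params)
    n = int(params.radius)
    cx, cy = center
    ip = _pad(img.pixels, n)
    mp = _pad(med.pixels, n)
    iwin = ip[cx : cx + 2 * n + 1, cy : cy + 2 * n + 1]
    mwin = mp[cx : cx + 2 * n + 1, cy : cy + 2 * n + 1]
    wsb = spatial_weight_buffer(params)
    offs = np.abs(np.arange(-n, n + 1))
    ws = wsb[offs[:, None], offs[None, :]]
    wr = radiometric_weight(img.pixels[cx, cy], iwin, params.sigma_r)
    wm = median_weight(med.pixels[cx, cy], mwin, params.sigma_m)
    h = float(entropy[cx, cy])
    return WeightComponents(ws=ws, wr=wr, wm=wm, entropy=h,
                            ensemble=ensemble_weight(ws, wr, wm, h))
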