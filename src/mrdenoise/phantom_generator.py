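"""Seeded brain-like phantom generation.

Stands in for a simulated MR database: piecewise-constant tissue anatomy
(background < CSF < GM < WM, optional lesions) with Fourier-perturbed
boundaries, slice-thickness smoothing, a smooth multiplicative bias field,
and Rician noise at a percent-of-maximum-intensity level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import Image2D

__all__ = [
    "PhantomSpec",
    "PhantomPair",
    "make_anatomy",
    "apply_bias_field",
    "add_rician_noise",
    "make_phantom",
    "make_corpus",
    "noise_class",
]

NOISE_LEVELS = (0.01, 0.03, 0.05, 0.07, 0.09)
BIAS_AMPLITUDES = (0.0, 0.20, 0.40)

#: noise-level percent -> class used by the two-stage automation
_CLASS_EDGES = {0.01: "low", 0.03: "low", 0.05: "median", 0.07: "median", 0.09: "high"}


def noise_class(level: float) -> str:
    """Map a noise level to {low, median, high}: low = 1,3%; median = 5,7%; high = 9%."""
    if level <= 0.04:
        return "low"
    if level <= 0.08:
        return "median"
    return "high"


@dataclass
class PhantomSpec:
    """Recipe for one phantom slice."""

    size: tuple[int, int] = (64, 64)
    tissue_intensities: tuple[float, ...] = (0.0, 0.25, 0.55, 0.80)  # bg, CSF, GM, WM
    lesion: bool = False
    thickness_smoothing: float = 1.0  # Gaussian sigma in pixels
    bias_amplitude: float = 0.0
    noise_level: float = 0.05
    seed: int = 0
    max_intensity: float = 1.0


@dataclass
class PhantomPair:
    """A clean/noisy pair plus the keys needed for corpus bookkeeping."""

    clean: Image2D
    noisy: Image2D
    spec: PhantomSpec
    anatomy_id: int = 0


def _perturbed_radius(phi: np.ndarray, base: float, rng: np.random.Generator,
                      rel_amp: float = 0.06) -> np.ndarray:
    r = np.full_like(phi, base)
    for k in range(2, 6):
        amp = rng.uniform(0.0, rel_amp) * base
        r += amp * np.cos(k * phi + rng.uniform(0.0, 2.0 * np.pi))
    return r


def make_anatomy(spec: PhantomSpec) -> Image2D:
    """Deterministic nested-blob anatomy, blurred by the slice-thickness width."""
    m, n = spec.size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:m, 0:n]
    cy = m / 2.0 + rng.uniform(-0.03, 0.03) * m
    cx = n / 2.0 + rng.uniform(-0.03, 0.03) * n
    # mildly anisotropic radial coordinate (head is an ellipse)
    ay = rng.uniform(0.85, 1.0)
    ax = rng.uniform(0.85, 1.0)
    dy = (yy - cy) / ay
    dx = (xx - cx) / ax
    rad = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)

    base = 0.46 * min(m, n)
    bg, csf, gm, wm = spec.tissue_intensities[:4]
    img = np.full((m, n), bg, dtype=np.float64)
    for frac, value in ((1.0, csf), (0.82, gm), (0.62, wm)):
        boundary = _perturbed_radius(phi, base * frac, rng)
        img[rad < boundary] = value

    if spec.lesion:
        for _ in range(rng.integers(1, 4)):
            lr = rng.uniform(0.04, 0.10) * min(m, n)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            dist = rng.uniform(0.0, 0.4) * base
            ly, lx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
            mask = (yy - ly) ** 2 + (xx - lx) ** 2 < lr**2
            img[mask] = np.clip(wm + rng.choice([-0.25, 0.15]), 0.0, 1.0)

    img *= spec.max_intensity  # tissue intensities are fractions of MAX_I
    if spec.thickness_smoothing > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.thickness_smoothing, mode="nearest")
    return Image2D(np.clip(img, 0.0, spec.max_intensity), spec.max_intensity)


def apply_bias_field(img: Image2D, amplitude: float, seed: int = 0) -> Image2D:
    """Multiply by a smooth polynomial field spanning ``[1 - a/2, 1 + a/2]``."""
    if not 0.0 <= amplitude < 1.0:
        raise ValueError(f"amplitude must lie in [0, 1), got {amplitude}")
    if amplitude == 0.0:
        return img.like(img.pixels.copy())
    m, n = img.shape
    rng = np.random.default_rng(seed)
    y = np.linspace(-1.0, 1.0, m)[:, None]
    x = np.linspace(-1.0, 1.0, n)[None, :]
    coef = rng.normal(size=6)
    poly = (coef[0] * x + coef[1] * y + coef[2] * x * y
            + coef[3] * x**2 + coef[4] * y**2 + coef[5])
    lo, hi = poly.min(), poly.max()
    unit = (poly - lo) / (hi - lo) if hi > lo else np.full_like(poly, 0.5)
    fieldmap = 1.0 + amplitude * (unit - 0.5)
    out = np.clip(img.pixels * fieldmap, 0.0, img.max_intensity)
    return img.like(out)


def add_rician_noise(img: Image2D, level: float, seed: int = 0) -> Image2D:
    """Rician noise: ``sqrt((I + g1)**2 + g2**2)`` with ``sigma = level * MAX_I``."""
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    if level == 0:
        return img.like(np.abs(img.pixels))
    rng = np.random.default_rng(seed)
    sigma = level * img.max_intensity
    g1 = rng.normal(0.0, sigma, size=img.shape)
    g2 = rng.normal(0.0, sigma, size=img.shape)
    noisy = np.hypot(img.pixels + g1, g2)
    return img.like(np.clip(noisy, 0.0, img.max_intensity))


def make_phantom(spec: PhantomSpec, anatomy_id: int = 0) -> PhantomPair:
    """Clean (anatomy + bias) and noisy (clean + Rician) images for one spec.

    The clean image is deterministic given the spec minus the noise level, so
    phantoms sharing an anatomy id differ only in their noise realization.
    """
    clean = make_anatomy(spec)
    clean = apply_bias_field(clean, spec.bias_amplitude, seed=spec.seed + 7919)
    noise_seed = spec.seed + 104729 + int(round(spec.noise_level * 1000))
    noisy = add_rician_noise(clean, spec.noise_level, seed=noise_seed)
    return PhantomPair(clean=clean, noisy=noisy, spec=spec, anatomy_id=anatomy_id)


def make_corpus(n_per_cell: int, noise_levels=NOISE_LEVELS, bias_amplitudes=(0.0,),
                thicknesses=(1.0,), size=(64, 64), seed: int = 0,
                lesion: bool = False) -> tuple[list[PhantomPair], pd.DataFrame]:
    """Full factorial corpus with shared anatomy across noise levels.

    Returns the phantom pairs and a label table (one row per pair) with a
    2:1 train/test split stratified by noise class in the ``split`` column.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[PhantomPair] = []
    rows = []
    aid = 0
    for thickness in thicknesses:
        for bias in bias_amplitudes:
            for _ in range(n_per_cell):
                anatomy_seed = int(rng.integers(0, 2**31 - 1))
                for level in noise_levels:
                    spec = PhantomSpec(
                        size=size, thickness_smoothing=thickness,
                        bias_amplitude=bias, noise_level=level,
                        seed=anatomy_seed, lesion=lesion,
                    )
                    pairs.append(make_phantom(spec, anatomy_id=aid))
                    rows.append({
                        "anatomy_id": aid, "noise_level": level,
                        "noise_class": noise_class(level),
                        "bias": bias, "thickness": thickness,
                        "seed": anatomy_seed,
                    })
                aid += 1
    labels = pd.DataFrame(rows)
    labels["split"] = _stratified_split(labels["noise_class"].to_numpy(), seed)
    return pairs, labels


def _stratified_split(classes: np.ndarray, seed: int, train_frac: float = 2.0 / 3.0) -> np.ndarray:
    rng = np.random.default_rng(seed + 1)
    split = np.empty(len(classes), dtype=object)
    for cls in np.unique(classes):
        idx = np.flatnonzero(classes == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"
    return split
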