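"""Restoration quality metrics: PSNR, SSIM and the relative PSNR error."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .image import Image2D

__all__ = ["psnr", "ssim", "relative_error"]

K1 = 0.01
K2 = 0.03


def _check_pair(reference: Image2D, restored: Image2D) -> None:
    if reference.shape != restored.shape:
        raise ValueError("reference and restored images must share shape")
    if reference.max_intensity != restored.max_intensity:
        raise ValueError("reference and restored images must share max_intensity")


def psnr(reference: Image2D, restored: Image2D) -> float:
    """Peak signal-to-noise ratio in dB: ``10*log10(MAX_I**2 / MSE)``.

    Identical images yield ``+inf`` (with a warning) rather than an error so
    parameter sweeps containing a perfect restoration do not crash.
    """
    _check_pair(reference, restored)
    mse = float(np.mean((restored.pixels - reference.pixels) ** 2))
    if mse == 0.0:
        warnings.warn("identical images: PSNR is infinite", RuntimeWarning, stacklevel=2)
        return float("inf")
    return 10.0 * np.log10(reference.max_intensity**2 / mse)


def ssim(reference: Image2D, restored: Image2D, mode: str = "windowed",
         window: int = 7) -> float:
    """Structural similarity with stabilizers ``C1=(K1*MAX_I)**2``, ``C2=(K2*MAX_I)**2``.

    ``global`` mode evaluates the single-statistic form over the whole image;
    ``windowed`` (default) averages the same statistic over sliding
    ``window x window`` neighborhoods, the standard reporting convention.
    """
    _check_pair(reference, restored)
    f = reference.pixels
    r = restored.pixels
    max_i = reference.max_intensity
    c1 = (K1 * max_i) ** 2
    c2 = (K2 * max_i) ** 2

    if mode == "global":
        mu_f = f.mean()
        mu_r = r.mean()
        var_f = f.var()
        var_r = r.var()
        cov = float(np.mean((f - mu_f) * (r - mu_r)))
        return float(
            (2 * mu_f * mu_r + c1) * (2 * cov + c2)
            / ((mu_f**2 + mu_r**2 + c1) * (var_f + var_r + c2))
        )
    if mode == "windowed":
        def box(a):
            return ndimage.uniform_filter(a, size=window, mode="reflect")

        mu_f = box(f)
        mu_r = box(r)
        var_f = box(f * f) - mu_f**2
        var_r = box(r * r) - mu_r**2
        cov = box(f * r) - mu_f * mu_r
        smap = ((2 * mu_f * mu_r + c1) * (2 * cov + c2)
                / ((mu_f**2 + mu_r**2 + c1) * (var_f + var_r + c2)))
        return float(smap.mean())
    raise ValueError(f"mode must be 'global' or 'windowed', got {mode!r}")


def relative_error(psnr_t: float, psnr_a: float) -> float:
    """Relative PSNR error in percent: ``|psnr_t - psnr_a| / psnr_t * 100``."""
    if not np.isfinite(psnr_t) or psnr_t <= 0:
        raise ValueError(f"psnr_t must be finite and > 0, got {psnr_t}")
    return abs(psnr_t - psnr_a) / psnr_t * 100.0
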