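"""The 2-D grayscale image carrier used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D"]


@dataclass
class Image2D:
    """A rectangular grid of nonnegative intensities with a declared ceiling.

    Parameters
    ----------
    pixels
        2-D array of intensities; coerced to ``float64``.
    max_intensity
        The maximum *possible* intensity of the carrier (``MAX_I``),
        not necessarily attained by ``pixels``.  Strictly positive.
    """

    pixels: np.ndarray
    max_intensity: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if not np.isfinite(self.max_intensity) or self.max_intensity <= 0:
            raise ValueError("max_intensity must be a finite positive number")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixel values must be finite")
        # tolerate round-off from upstream arithmetic, reject real violations
        eps = 1e-9 * self.max_intensity
        if arr.min() < -eps or arr.max() > self.max_intensity + eps:
            raise ValueError(
                "pixel values must lie in [0, max_intensity]; got range "
                f"[{arr.min()}, {arr.max()}] with max_intensity={self.max_intensity}"
            )
        object.__setattr__(self, "pixels", np.clip(arr, 0.0, self.max_intensity))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, max_intensity: float | None = None) -> "Image2D":
        """Wrap an array, inferring ``MAX_I`` from the dtype when possible."""
        arr = np.asarray(arr)
        if max_intensity is None:
            if np.issubdtype(arr.dtype, np.integer):
                max_intensity = float(np.iinfo(arr.dtype).max)
            else:
                mx = float(np.max(arr)) if arr.size else 1.0
                max_intensity = mx if mx > 0 else 1.0
        return cls(arr.astype(np.float64), float(max_intensity))

    def like(self, pixels: np.ndarray) -> "Image2D":
        """A new image sharing this image's ``max_intensity``."""
        return Image2D(pixels, self.max_intensity)
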