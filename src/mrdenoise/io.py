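"""Readers/writers for slices (PNG/TIFF), volumes (NIfTI) and run configs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml

from .image import Image2D

__all__ = ["read_slices", "write_slices", "load_config", "dump_json"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_slices(path, max_intensity: float | None = None) -> tuple[list[Image2D], dict]:
    """Read a grayscale slice or volume as a list of Image2D plus metadata.

    Volumes (NIfTI) are split along the last axis.  ``MAX_I`` defaults to the
    dtype maximum for integer images and the data maximum otherwise.
    """
    path = Path(path)
    if _is_nifti(path):
        nii = nib.load(str(path))
        data = np.asanyarray(nii.dataobj)
        if data.ndim == 2:
            data = data[..., None]
        if data.ndim != 3:
            raise ValueError(f"expected a 2-D or 3-D volume, got shape {data.shape}")
        if max_intensity is None:
            if np.issubdtype(data.dtype, np.integer):
                max_intensity = float(np.iinfo(data.dtype).max)
            else:
                max_intensity = float(max(data.max(), 1e-12))
        slices = [Image2D(np.clip(data[..., k].astype(np.float64), 0, max_intensity),
                          max_intensity)
                  for k in range(data.shape[-1])]
        meta = {"format": "nifti", "dtype": str(data.dtype), "affine": nii.affine,
                "shape": data.shape}
        return slices, meta
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and np.ptp(arr[..., :3], axis=-1).max() == 0:
            arr = arr[..., 0]  # gray stored as RGB
        else:
            raise ValueError("non-grayscale input image")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    img = Image2D.from_array(arr, max_intensity)
    return [img], {"format": "image", "dtype": str(arr.dtype), "shape": arr.shape}


def write_slices(path, slices: list[Image2D], meta: dict) -> None:
    """Write restored slices in the input's container and dtype (rounded)."""
    path = Path(path)
    dtype = np.dtype(meta.get("dtype", "float64"))

    def cast(a: np.ndarray) -> np.ndarray:
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            return np.clip(np.rint(a), info.min, info.max).astype(dtype)
        return a.astype(dtype)

    if meta.get("format") == "nifti":
        data = np.stack([cast(s.pixels) for s in slices], axis=-1)
        nib.save(nib.Nifti1Image(data, meta.get("affine")), str(path))
    else:
        if len(slices) != 1:
            raise ValueError("single-slice formats can hold exactly one image")
        iio.imwrite(path, cast(slices[0].pixels))


def load_config(path) -> dict:
    """Load a YAML (or JSON) run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_json(path, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dict__"):
            return {k: v for k, v in obj.__dict__.items() if not k.startswith("_")}
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=default)
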