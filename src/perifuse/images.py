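"""Grayscale image container and file I/O (8-bit PNG, single-frame DICOM)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = ["ImageTensor", "read_image", "write_png", "resize_square"]


@dataclass
class ImageTensor:
    """A single-channel image with intensities in [0, 1]."""

    pixels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def read_image(path: str | Path, subject_id: str = "") -> ImageTensor:
    """Load a grayscale PNG or a single-frame DICOM, scaled to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        if arr.ndim == 3:
            raise ValueError(f"{path}: multi-frame DICOM not supported")
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    else:
        # PNG has a known 8-bit dynamic range; dividing by 255 (rather than
        # min-max scaling) keeps the round trip faithful to quantization.
        arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return ImageTensor(pixels=arr, subject_id=subject_id or path.stem)


def write_png(img: ImageTensor, path: str | Path) -> None:
    """Write as 8-bit grayscale PNG (intensities quantized to 256 levels)."""
    arr = np.clip(img.pixels, 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def resize_square(img: ImageTensor, size: int) -> ImageTensor:
    """Bilinear resize to ``size x size``; no-op if already that shape."""
    h, w = img.shape
    if (h, w) == (size, size):
        return img
    zoomed = ndimage.zoom(img.pixels, (size / h, size / w), order=1)
    return ImageTensor(pixels=np.clip(zoomed, 0.0, 1.0), subject_id=img.subject_id)
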