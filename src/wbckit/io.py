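"""Reading and writing images and masks (8-bit PNG/TIFF/BMP)."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["read_image", "read_mask", "write_mask", "write_image"]


def read_image(path) -> np.ndarray:
    """Read an 8-bit color image as an HxWx3 uint8 array.

    Grayscale inputs are broadcast to three channels; an alpha channel
    is discarded.
    """
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def read_mask(path) -> np.ndarray:
    """Read a binary mask: any nonzero pixel is foreground."""
    m = iio.imread(path)
    if m.ndim == 3:
        m = m[..., 0]
    return m > 0


def write_mask(path, mask) -> None:
    """Write a boolean mask as a single-channel 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def write_image(path, img) -> None:
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))
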