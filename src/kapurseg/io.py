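"""Reading and writing images, label maps and histograms.

8-bit images travel as PNG; 12- and 16-bit images travel as unsigned 16-bit
TIFF with the *logical* bit depth declared by the caller (a 12-bit scan in a
16-bit container is the norm for medical data).  Label maps are written as
TIFF; histograms export to CSV with ``level,count,prob`` columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image as PILImage

from .histogram import GrayHistogram, GrayImage

__all__ = ["read_image", "write_image", "write_labels", "histogram_to_csv"]


def read_image(path: str | Path, bit_depth: int | None = None) -> GrayImage:
    """Load a grayscale PNG (8-bit) or TIFF (8/12/16-bit) as a GrayImage.

    ``bit_depth`` declares the logical depth; when omitted it defaults to 8
    for PNG and to the container width (8 or 16) for TIFF.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(path))
    elif suffix == ".png":
        arr = np.asarray(PILImage.open(path).convert("I"))
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    if arr.ndim == 3:
        arr = arr[..., 0]
    arr = arr.astype(np.int64)
    if bit_depth is None:
        bit_depth = 8 if arr.max() < 256 else 16
    return GrayImage(pixels=arr, bit_depth=bit_depth)


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write 8-bit data as PNG or TIFF, deeper data as 16-bit TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if image.bit_depth <= 8:
        arr = image.pixels.astype(np.uint8)
        if suffix == ".png":
            PILImage.fromarray(arr, mode="L").save(path)
            return
    elif suffix == ".png":
        raise ValueError("PNG output is limited to 8-bit images; use TIFF")
    else:
        arr = image.pixels.astype(np.uint16)
    if suffix not in (".tif", ".tiff"):
        raise ValueError(f"unsupported output format: {suffix}")
    tifffile.imwrite(path, arr)


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a class-index map as a compact unsigned TIFF."""
    dtype = np.uint8 if labels.max() < 256 else np.uint16
    tifffile.imwrite(Path(path), labels.astype(dtype))


def histogram_to_csv(hist: GrayHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "level": np.arange(hist.levels),
            "count": hist.counts,
            "prob": hist.probs,
        }
    ).to_csv(path, index=False)
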