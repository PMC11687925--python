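"""Full-reference quality metrics for original/segmented image pairs.

Three standard measures quantify how much a rendered segmentation degrades
the original image:

* **PSNR** — ``20 log10(MAX / sqrt(MSE))`` in dB.  By default ``MAX = 2**n``
  (the full count of representable levels); set ``max_convention="levels-1"``
  for the textbook ``2**n - 1``.
* **SSIM** — mean over local Gaussian windows (11x11, sigma 1.5) of the
  product of luminance, contrast and structure terms with the universal
  constants ``C1 = (0.01 D)^2, C2 = (0.03 D)^2, C3 = C2 / 2`` where
  ``D = 2**n - 1``.  A ``global`` mode computes a single window over the
  whole image and is handy for closed-form checks.
* **FSIM** — phase-congruency- and gradient-based similarity pooled with the
  phase-congruency maximum as weight.  Images are rescaled to the 0-255
  range before the transform so the standard stabilisers ``T1 = 0.85,
  T2 = 160`` apply at any bit depth.

All three are symmetric in their arguments (PSNR depends only on the
difference) and attain their maximum exactly for pixelwise-equal inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from ._phasecong import phase_congruency
from .histogram import GrayImage

__all__ = ["MetricsReport", "mse", "psnr", "ssim", "fsim", "compute_metrics"]

#: Scharr gradient kernel (x-direction); transpose for y.
_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0


@dataclass(frozen=True)
class MetricsReport:
    """PSNR (dB, ``inf`` for identical images), SSIM and FSIM of a pair."""

    mse: float
    psnr_db: float
    ssim: float
    fsim: float

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr_db": self.psnr_db if np.isfinite(self.psnr_db) else "inf",
            "ssim": self.ssim,
            "fsim": self.fsim,
        }


def _check_pair(a: GrayImage, b: GrayImage) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("images must have the same shape")
    if a.bit_depth != b.bit_depth:
        raise ValueError("images must have the same bit depth")


def mse(original: GrayImage, segmented: GrayImage) -> float:
    _check_pair(original, segmented)
    diff = original.pixels.astype(float) - segmented.pixels.astype(float)
    return float(np.mean(diff**2))


def psnr(
    original: GrayImage,
    segmented: GrayImage,
    max_convention: Literal["levels", "levels-1"] = "levels",
) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when the images are equal."""
    err = mse(original, segmented)
    if err == 0.0:
        return float("inf")
    peak = float(2**original.bit_depth)
    if max_convention == "levels-1":
        peak -= 1.0
    return float(20.0 * np.log10(peak / np.sqrt(err)))


def _gaussian_window_stats(arr: np.ndarray, sigma: float, truncate: float) -> np.ndarray:
    return ndimage.gaussian_filter(arr, sigma=sigma, truncate=truncate)


def ssim(
    original: GrayImage,
    segmented: GrayImage,
    window: Literal["gaussian", "global"] = "gaussian",
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Structural similarity index of the pair.

    ``gaussian`` mode pools the per-pixel luminance*contrast*structure map
    over 11x11 Gaussian-weighted windows (sigma 1.5), cropping the half-window
    border before averaging.  ``global`` mode treats the whole image as one
    window with plain (population) moments.
    """
    _check_pair(original, segmented)
    x = original.pixels.astype(float)
    y = segmented.pixels.astype(float)
    d = float(2**original.bit_depth - 1)
    c1 = (k1 * d) ** 2
    c2 = (k2 * d) ** 2
    c3 = c2 / 2.0

    if window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
        cov = float(np.mean((x - mu_x) * (y - mu_y)))
        lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
        con = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
        struct = (cov + c3) / (sd_x * sd_y + c3)
        return float(lum * con * struct)
    if window != "gaussian":
        raise ValueError(f"unknown window mode: {window!r}")

    truncate = 3.5  # radius 5 at sigma 1.5 -> 11x11 support
    win = 2 * int(truncate * sigma + 0.5) + 1
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    mu_x = _gaussian_window_stats(x, sigma, truncate)
    mu_y = _gaussian_window_stats(y, sigma, truncate)
    var_x = np.maximum(_gaussian_window_stats(x * x, sigma, truncate) - mu_x**2, 0.0)
    var_y = np.maximum(_gaussian_window_stats(y * y, sigma, truncate) - mu_y**2, 0.0)
    cov = _gaussian_window_stats(x * y, sigma, truncate) - mu_x * mu_y
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    struct = (cov + c3) / (sd_x * sd_y + c3)
    s_map = lum * con * struct
    pad = (win - 1) // 2
    return float(s_map[pad:-pad, pad:-pad].mean())


def fsim(
    original: GrayImage,
    segmented: GrayImage,
    t1: float = 0.85,
    t2: float = 160.0,
    eps: float = 1e-12,
) -> float:
    """Feature similarity index of the pair, in [0, 1].

    Phase-congruency similarity ``S_PC`` and Scharr-gradient similarity
    ``S_GM`` are combined as ``S_L = S_PC * S_GM`` and pooled with the
    pointwise phase-congruency maximum::

        FSIM = sum(S_L * PC_m) / sum(PC_m),  PC_m = max(PC_1, PC_2)

    Inputs are rescaled to 0-255 so the stabilisers ``t1``/``t2`` keep their
    standard values at any bit depth.  Images are average-pooled down to
    ~256 px on the short side first (no-op for small images).  Two equal
    constant images (zero congruency everywhere) define FSIM = 1.
    """
    _check_pair(original, segmented)
    d = float(2**original.bit_depth - 1)
    x = original.pixels.astype(float) * (255.0 / d)
    y = segmented.pixels.astype(float) * (255.0 / d)

    f = max(1, round(min(x.shape) / 256))
    if f > 1:
        x = ndimage.uniform_filter(x, size=f)[::f, ::f]
        y = ndimage.uniform_filter(y, size=f)[::f, ::f]

    pc1 = phase_congruency(x)
    pc2 = phase_congruency(y)
    g1 = np.hypot(
        ndimage.convolve(x, _SCHARR_X, mode="nearest"),
        ndimage.convolve(x, _SCHARR_X.T, mode="nearest"),
    )
    g2 = np.hypot(
        ndimage.convolve(y, _SCHARR_X, mode="nearest"),
        ndimage.convolve(y, _SCHARR_X.T, mode="nearest"),
    )
    s_pc = (2.0 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_gm = (2.0 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    s_l = s_pc * s_gm
    pc_m = np.maximum(pc1, pc2)
    denom = float(pc_m.sum())
    if denom < eps:
        if np.array_equal(original.pixels, segmented.pixels):
            return 1.0
        return float((s_l * pc_m).sum() / (denom + eps))
    return float((s_l * pc_m).sum() / denom)


def compute_metrics(
    original: GrayImage,
    segmented: GrayImage,
    max_convention: Literal["levels", "levels-1"] = "levels",
) -> MetricsReport:
    """All three metrics for an original/rendered-segmentation pair."""
    return MetricsReport(
        mse=mse(original, segmented),
        psnr_db=psnr(original, segmented, max_convention=max_convention),
        ssim=ssim(original, segmented),
        fsim=fsim(original, segmented),
    )
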