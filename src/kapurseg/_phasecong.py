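"""Log-Gabor phase congruency transform (internal helper for FSIM).

Phase congruency marks image locations where Fourier components of many
frequencies arrive in phase — a contrast-invariant notion of "feature"
(edges, lines) that FSIM uses both as a similarity channel and as its
pooling weight.  This is the standard multi-scale, multi-orientation
log-Gabor construction: for each orientation a bank of log-Gabor filters
produces even/odd responses whose summed energy, noise-compensated and
weighted by a frequency-spread sigmoid, is normalised by the total response
amplitude.  The per-orientation maps are summed into a single congruency
map in [0, ~norient).
"""

from __future__ import annotations

import numpy as np

__all__ = ["phase_congruency"]


def _lowpass_filter(shape: tuple[int, int], cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    rows, cols = shape
    xr = (np.arange(cols) - cols // 2) / cols
    yr = (np.arange(rows) - rows // 2) / rows
    x, y = np.meshgrid(xr, yr)
    radius = np.fft.ifftshift(np.sqrt(x**2 + y**2))
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(
    image: np.ndarray,
    nscale: int = 4,
    norient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    d_theta_on_sigma: float = 1.2,
    k: float = 2.0,
    cutoff: float = 0.5,
    g: float = 10.0,
    epsilon: float = 1e-4,
) -> np.ndarray:
    """Phase-congruency map of a 2-D image.

    Parameters follow the conventional FSIM filter bank: 4 scales starting at
    wavelength 6 with octave spacing, 4 orientations, log-Gabor bandwidth
    ``sigma_onf = 0.55``, noise-compensation factor ``k = 2`` and a sigmoid
    frequency-spread weighting (``cutoff = 0.5``, gain 10).
    """
    im = np.asarray(image, dtype=float)
    rows, cols = im.shape
    imfft = np.fft.fft2(im)

    xr = (np.arange(cols) - cols // 2) / cols
    yr = (np.arange(rows) - rows // 2) / rows
    x, y = np.meshgrid(xr, yr)
    radius = np.fft.ifftshift(np.sqrt(x**2 + y**2))
    radius[0, 0] = 1.0  # avoid log(0) at DC; the DC gain is zeroed below
    theta = np.fft.ifftshift(np.arctan2(-y, x))
    sintheta = np.sin(theta)
    costheta = np.cos(theta)

    lp = _lowpass_filter((rows, cols))
    log_gabor = []
    for s in range(nscale):
        wavelength = min_wavelength * mult**s
        fo = 1.0 / wavelength
        lg = np.exp(-np.log(radius / fo) ** 2 / (2.0 * np.log(sigma_onf) ** 2)) * lp
        lg[0, 0] = 0.0
        log_gabor.append(lg)

    theta_sigma = np.pi / norient / d_theta_on_sigma
    total_pc = np.zeros((rows, cols))
    for o in range(norient):
        angl = o * np.pi / norient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))

        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        max_an = np.zeros((rows, cols))
        eos = []
        tau = 0.0
        for s in range(nscale):
            eo = np.fft.ifft2(imfft * (log_gabor[s] * spread))
            an = np.abs(eo)
            eos.append(eo)
            sum_an += an
            sum_e += eo.real
            sum_o += eo.imag
            if s == 0:
                # Rayleigh-based noise estimate from the smallest scale
                tau = np.median(an) / np.sqrt(np.log(4.0))
                max_an = an.copy()
            else:
                np.maximum(max_an, an, out=max_an)

        x_energy = np.sqrt(sum_e**2 + sum_o**2) + epsilon
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros((rows, cols))
        for eo in eos:
            energy += eo.real * mean_e + eo.imag * mean_o - np.abs(
                eo.real * mean_o - eo.imag * mean_e
            )

        total_tau = tau * (1.0 - (1.0 / mult) ** nscale) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        t = (noise_mean + k * noise_sigma) / 1.7  # empirical energy/amplitude rescale
        energy = np.maximum(energy - t, 0.0)

        width = (sum_an / (max_an + epsilon)) / nscale
        weight = 1.0 / (1.0 + np.exp(g * (cutoff - width)))
        total_pc += weight * energy / (sum_an + epsilon)
    return total_pc
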