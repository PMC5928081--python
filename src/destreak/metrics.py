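"""PSNR and SSIM image-quality metrics.

Both metrics are reported against the full-view FBP reconstruction (the
gold-standard reference) with a fixed peak of 4095, the nominal maximum of
12-bit stored CT data.  Using a fixed peak (rather than a per-image maximum)
keeps PSNR comparable across images and view counts.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .phantoms import Image2D, INTENSITY_SCALE_12BIT

__all__ = ["psnr", "ssim", "SSIM_WINDOW", "SSIM_SIGMA"]

#: Gaussian window parameters of the canonical SSIM formulation.
SSIM_WINDOW = 11
SSIM_SIGMA = 1.5


def _pixels(img) -> np.ndarray:
    a = img.pixels if isinstance(img, Image2D) else np.asarray(img)
    return np.asarray(a, dtype=np.float64)


def psnr(test, reference, peak: float = INTENSITY_SCALE_12BIT) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(peak^2 / MSE).

    Larger is better; identical images return +inf.
    """
    a, b = _pixels(test), _pixels(reference)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(test, reference, peak: float = INTENSITY_SCALE_12BIT) -> float:
    """Mean structural similarity over an 11x11 Gaussian window (sigma 1.5).

    Standard stabilizers C1 = (0.01 peak)^2, C2 = (0.03 peak)^2; the mean is
    taken over windows fully inside the image.  Ideal value 1; negative local
    values (possible for anticorrelated structure) are retained in the mean.
    """
    a, b = _pixels(test), _pixels(reference)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    pad = (SSIM_WINDOW - 1) // 2
    if min(a.shape) < SSIM_WINDOW:
        raise ValueError(f"images must be at least {SSIM_WINDOW} px per side")
    # 11-tap Gaussian window == gaussian_filter with truncate such that
    # the kernel radius is (window - 1) / 2
    truncate = pad / SSIM_SIGMA
    blur = lambda im: ndimage.gaussian_filter(im, SSIM_SIGMA, truncate=truncate)
    mu_a = blur(a)
    mu_b = blur(b)
    var_a = blur(a * a) - mu_a * mu_a
    var_b = blur(b * b) - mu_b * mu_b
    cov = blur(a * b) - mu_a * mu_b
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    s = num / den
    return float(s[pad:-pad, pad:-pad].mean())
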