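"""Image-quality metrics.

Reference-based: MSE, PSNR (``10 log10((2**n - 1)**2 / MSE)``) and SSIM.
SSIM is computed by default from *global* image statistics (one mean,
variance and covariance per image) with constants ``c1 = (k1 (2**n-1))**2``
and ``c2 = (k2 (2**n-1))**2``, ``k1 = 0.01``, ``k2 = 0.03``; the familiar
sliding-window variant is available as an explicitly marked extension.

Reference-free: the local signal-to-noise ratio.  The frame is tiled into
non-overlapping 16 x 16 patches and each patch contributes ``SNR = mu /
sigma`` (population standard deviation); the mean local SNR averages the
patches.  Because SNR scales with the square root of dose, the squared
ratio of two mean local SNRs estimates the relative dose between two
acquisition regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_io import ImageFrame

__all__ = ["LocalSNRResult", "mse", "psnr", "ssim", "local_snr", "relative_dose"]


def _resolve(image, reference, bit_depth):
    def arr_of(x):
        return x.pixels if isinstance(x, ImageFrame) else np.asarray(x, dtype=float)

    a, b = arr_of(image), arr_of(reference)
    if a.shape != b.shape:
        raise ValueError("image and reference must have the same shape")
    depths = {
        x.bit_depth for x in (image, reference) if isinstance(x, ImageFrame)
    }
    if len(depths) > 1:
        raise ValueError("image and reference must share one bit depth")
    if depths:
        if bit_depth is not None and bit_depth != next(iter(depths)):
            raise ValueError("explicit bit_depth conflicts with the frames'")
        bit_depth = next(iter(depths))
    if bit_depth is None:
        raise ValueError("bit_depth is required when passing bare arrays")
    return a, b, int(bit_depth)


def mse(image, reference, bit_depth: int | None = None) -> float:
    """Mean squared error over all M*N pixels."""
    a, b, _ = _resolve(image, reference, bit_depth)
    return float(np.mean((a - b) ** 2))


def psnr(image, reference, bit_depth: int | None = None) -> float:
    """Peak signal-to-noise ratio in dB; identical images give ``inf``."""
    a, b, n = _resolve(image, reference, bit_depth)
    err = float(np.mean((a - b) ** 2))
    if err == 0.0:
        return math.inf
    peak = float(2**n - 1)
    return 10.0 * math.log10(peak**2 / err)


def ssim(
    image,
    reference,
    k1: float = 0.01,
    k2: float = 0.03,
    bit_depth: int | None = None,
    windowed: bool = False,
    win_size: int = 7,
) -> float:
    """Structural similarity in [-1, 1]; equals 1 for identical images.

    The default is the single global statistic form.  ``windowed=True``
    switches to the standard sliding-window mean SSIM (an extension beyond
    the global formula, computed via scikit-image).
    """
    a, b, n = _resolve(image, reference, bit_depth)
    peak = float(2**n - 1)
    if windowed:
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(a, b, data_range=peak, win_size=win_size, K1=k1, K2=k2)
        )
    c1 = (k1 * peak) ** 2
    c2 = (k2 * peak) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a = a.var()  # population statistics
    var_b = b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


@dataclass
class LocalSNRResult:
    """Per-tile SNR values plus their mean.

    ``per_patch`` holds ``(tile_row, tile_col, mu, sigma, snr)``.  Tiles
    with zero standard deviation carry no SNR and are excluded from the
    mean (counted in ``n_excluded``); if every tile is excluded the mean is
    NaN.
    """

    per_patch: list[tuple[int, int, float, float, float]]
    mean_snr: float
    n_excluded: int
    patch_size: int


def local_snr(frame, patch_size: int = 16) -> LocalSNRResult:
    """Reference-free local SNR averaged over non-overlapping tiles.

    Partial tiles at the right/bottom border are dropped.  Raises if the
    frame is smaller than a single tile.
    """
    if patch_size < 2:
        raise ValueError("patch_size must be >= 2")
    arr = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)
    rows, cols = arr.shape
    tr, tc = rows // patch_size, cols // patch_size
    if tr < 1 or tc < 1:
        raise ValueError("frame is smaller than a single tile")
    tiles = (
        arr[: tr * patch_size, : tc * patch_size]
        .reshape(tr, patch_size, tc, patch_size)
        .transpose(0, 2, 1, 3)
        .reshape(tr, tc, -1)
    )
    mu = tiles.mean(axis=2)
    sigma = tiles.std(axis=2)  # population std
    per_patch = []
    values = []
    n_excluded = 0
    for i in range(tr):
        for j in range(tc):
            if sigma[i, j] == 0.0:
                n_excluded += 1
                continue
            snr = float(mu[i, j] / sigma[i, j])
            per_patch.append((i, j, float(mu[i, j]), float(sigma[i, j]), snr))
            values.append(snr)
    mean_snr = float(np.mean(values)) if values else math.nan
    return LocalSNRResult(per_patch=per_patch, mean_snr=mean_snr, n_excluded=n_excluded, patch_size=patch_size)


def relative_dose(snr_num: float, snr_den: float) -> float:
    """Squared SNR ratio: the dose ratio implied by ``SNR ∝ sqrt(dose)``."""
    if snr_num <= 0 or snr_den <= 0:
        raise ValueError("SNR values must be positive")
    return (snr_num / snr_den) ** 2
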