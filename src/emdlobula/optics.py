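"""Peripheral-eye front end: Gaussian blur and downsampling.

Each stimulus frame is low-pass filtered with a truncated 2D Gaussian
(12 × 12 pixels, σ = 3.5 px by default) and decimated by a factor η = 6,
emulating the optics of the fly compound eye.  The blur standard deviation
maps to the photoreceptor acceptance angle Δρ (full width at half maximum of
the angular sensitivity) and the decimation factor to the interommatidial
angle Δϕ (angular spacing of neighboring sampling points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "OpticsConfig",
    "gaussian_kernel_1d",
    "gaussian_kernel",
    "acceptance_angle",
    "interommatidial_angle",
    "preprocess",
    "downsample_mask",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class OpticsConfig:
    sigma_px: float = 3.5
    kernel_size_px: int = 12
    downsample_factor: int = 6
    deg_per_pixel: float = 0.33

    def __post_init__(self):
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if self.kernel_size_px < 1 or self.downsample_factor < 1:
            raise ValueError("kernel size and downsample factor must be >= 1")

    @property
    def acceptance_angle_deg(self) -> float:
        return acceptance_angle(self.sigma_px, self.deg_per_pixel)

    @property
    def interommatidial_angle_deg(self) -> float:
        return interommatidial_angle(self.downsample_factor, self.deg_per_pixel)

    @property
    def deg_per_unit(self) -> float:
        """Angular spacing of the downsampled (EMD) grid."""
        return self.downsample_factor * self.deg_per_pixel


def acceptance_angle(sigma_px: float, deg_per_pixel: float) -> float:
    """Δρ = 2·sqrt(2·ln 2)·σ (FWHM of the blur), in degrees."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be nonnegative")
    return _FWHM * sigma_px * deg_per_pixel


def interommatidial_angle(eta: int, deg_per_pixel: float) -> float:
    """Δϕ = η pixels, in degrees."""
    if eta < 1:
        raise ValueError("downsample factor must be >= 1")
    return eta * deg_per_pixel


def gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    """1D Gaussian sampled at offsets from the kernel center (size−1)/2.

    For an even size the center falls on a half-integer grid offset, making
    the sampled kernel exactly symmetric.  Normalized to unit sum.
    """
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Separable 2D blur kernel, unit sum."""
    k = gaussian_kernel_1d(size, sigma)
    return np.outer(k, k)


def preprocess(frame: np.ndarray, cfg: OpticsConfig) -> np.ndarray:
    """Blur with the truncated Gaussian, then decimate every η-th pixel.

    Reflective boundary padding avoids dark rims at the frame edges that
    would otherwise register as spurious motion.  The output keeps values in
    [0, 1] (unit-sum kernel) and has shape ceil(input/η).
    """
    frame = np.asarray(frame, dtype=float)
    if min(frame.shape) < cfg.kernel_size_px:
        raise ValueError("frame smaller than the blur kernel")
    k = gaussian_kernel_1d(cfg.kernel_size_px, cfg.sigma_px)
    blurred = correlate1d(frame, k, axis=0, mode="reflect")
    blurred = correlate1d(blurred, k, axis=1, mode="reflect")
    eta = cfg.downsample_factor
    return blurred[::eta, ::eta]


def downsample_mask(gt_mask: np.ndarray, eta: int) -> np.ndarray:
    """Majority vote of each η×η block: foreground iff > 50 % of its source
    pixels are foreground.  Blocks are anchored at the decimation samples
    (indices 0, η, 2η, …); edge blocks may be partial."""
    gt_mask = np.asarray(gt_mask, dtype=bool)
    rows = -(-gt_mask.shape[0] // eta)
    cols = -(-gt_mask.shape[1] // eta)
    counts = np.add.reduceat(
        np.add.reduceat(gt_mask.astype(np.int32), np.arange(0, gt_mask.shape[0], eta), axis=0),
        np.arange(0, gt_mask.shape[1], eta),
        axis=1,
    )
    sizes = np.outer(
        np.diff(np.append(np.arange(0, gt_mask.shape[0], eta), gt_mask.shape[0])),
        np.diff(np.append(np.arange(0, gt_mask.shape[1], eta), gt_mask.shape[1])),
    )
    assert counts.shape == (rows, cols)
    return counts > 0.5 * sizes
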