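"""Multi-scale Laplacian-of-Gaussian (LoG) bandpass filtering of axial slices.

The spatial scale filter (SSF) value is the physical width, in mm, of the
image structures a band emphasizes: SSF 2 picks out fine texture, SSF 6
coarse texture, and SSF 0 means no filtering at all. Each SSF maps to a
Gaussian width ``sigma_mm = sigma_per_ssf * ssf``; the default ratio
``1/(2*sqrt(2))`` makes the LoG zero-crossing circle of the kernel exactly
``ssf`` mm in diameter, so a bright blob of diameter ≈ SSF produces its
strongest center response at the matching scale.

Responses are scale-normalized (multiplied by sigma^2) so bands at different
scales are comparable, and negated so bright structures give positive
responses. The discrete kernel is mean-subtracted to be exactly zero-sum:
constant images map to exactly zero. Borders use mirror extension.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy import ndimage

#: the study's spatial scale filter levels, mm; 0 = unfiltered
SSF_LEVELS = (0, 2, 3, 4, 5, 6)

#: default Gaussian width per mm of SSF (zero-crossing diameter == SSF)
DEFAULT_SIGMA_PER_SSF = 1.0 / (2.0 * np.sqrt(2.0))


@functools.lru_cache(maxsize=64)
def _log_kernel_cached(
    ssf_mm: float, sy: float, sx: float, sigma_per_ssf: float, truncate: float
) -> np.ndarray:
    kernel = _build_log_kernel(ssf_mm, sy, sx, sigma_per_ssf, truncate)
    kernel.setflags(write=False)
    return kernel


def log_kernel(
    ssf_mm: float,
    spacing_mm_inplane: tuple[float, float],
    sigma_per_ssf: float = DEFAULT_SIGMA_PER_SSF,
    truncate: float = 4.0,
) -> np.ndarray:
    """Discrete negated, scale-normalized, zero-sum LoG kernel for one SSF.

    Parameters
    ----------
    ssf_mm : float
        Spatial scale filter value in mm (> 0).
    spacing_mm_inplane : (float, float)
        Pixel size (row, col) in mm.
    sigma_per_ssf : float
        Ratio sigma_mm / ssf_mm.
    truncate : float
        Kernel half-width in units of sigma.
    """
    if ssf_mm <= 0:
        raise ValueError("ssf must be positive for kernel construction")
    sy, sx = (float(s) for s in spacing_mm_inplane)
    if sy <= 0 or sx <= 0:
        raise ValueError("spacing must be positive")
    return _log_kernel_cached(float(ssf_mm), sy, sx, float(sigma_per_ssf), float(truncate))


def _build_log_kernel(
    ssf_mm: float, sy: float, sx: float, sigma_per_ssf: float, truncate: float
) -> np.ndarray:
    sigma_mm = sigma_per_ssf * float(ssf_mm)
    sig_y, sig_x = sigma_mm / sy, sigma_mm / sx  # in pixels
    ry = max(1, int(np.ceil(truncate * sig_y)))
    rx = max(1, int(np.ceil(truncate * sig_x)))
    y = np.arange(-ry, ry + 1)[:, None]
    x = np.arange(-rx, rx + 1)[None, :]
    g = np.exp(-(y**2) / (2 * sig_y**2) - (x**2) / (2 * sig_x**2))
    g /= g.sum()
    # Laplacian of the Gaussian, negated, scale-normalized by sigma^2 (px^2,
    # geometric mean across the two axes for anisotropic pixels)
    lap = g * ((y**2 - sig_y**2) / sig_y**4 + (x**2 - sig_x**2) / sig_x**4)
    kernel = -(sig_y * sig_x) * lap
    kernel -= kernel.mean()  # exact zero-sum: constants map to exactly 0
    return kernel


def log_filter_slice(
    slice_pixels: np.ndarray,
    spacing_mm_inplane: tuple[float, float],
    ssf: int | float,
    sigma_per_ssf: float = DEFAULT_SIGMA_PER_SSF,
    truncate: float = 4.0,
    allowed_levels: tuple = SSF_LEVELS,
) -> np.ndarray:
    """Filter one axial slice at one SSF level.

    SSF 0 returns the input unchanged (as float). SSF > 0 returns the
    negated-LoG bandpass response, same shape as the input, signed values.

    Raises
    ------
    ValueError
        For SSF values outside ``allowed_levels`` or slices smaller than 8x8.
    """
    pixels = np.asarray(slice_pixels, dtype=np.float64)
    if pixels.ndim != 2:
        raise ValueError(f"expected 2D slice, got {pixels.ndim}D")
    if pixels.shape[0] < 8 or pixels.shape[1] < 8:
        raise ValueError(f"slice {pixels.shape} smaller than 8x8")
    if allowed_levels is not None and ssf not in allowed_levels:
        raise ValueError(f"unknown SSF value {ssf}; allowed {allowed_levels}")
    if ssf == 0:
        return pixels.copy()
    kernel = log_kernel(ssf, spacing_mm_inplane, sigma_per_ssf, truncate)
    return ndimage.convolve(pixels, kernel, mode="mirror")


def log_filter_volume(
    voxels: np.ndarray,
    spacing_mm_inplane: tuple[float, float],
    levels: tuple = SSF_LEVELS,
    sigma_per_ssf: float = DEFAULT_SIGMA_PER_SSF,
    truncate: float = 4.0,
) -> dict[int, np.ndarray]:
    """SSF responses of every axial slice of a volume, keyed by SSF level.

    Equivalent to :func:`log_filter_slice` applied slice by slice (the
    kernels are symmetric, so FFT convolution and direct correlation agree
    to floating-point accuracy); one FFT pass over the whole volume per
    level keeps cohort extraction fast.
    """
    from scipy import fft

    vox = np.asarray(voxels, dtype=np.float64)
    if vox.ndim != 3:
        raise ValueError("expected 3D volume")
    out: dict[int, np.ndarray] = {}
    kernels = {
        ssf: log_kernel(ssf, spacing_mm_inplane, sigma_per_ssf, truncate)
        for ssf in levels
        if ssf != 0
    }
    if 0 in levels:
        out[0] = vox.copy()
    if not kernels:
        return out
    # mirror-pad once by the largest kernel radius; one forward FFT of the
    # slice batch is shared by every scale
    ry = max(k.shape[0] // 2 for k in kernels.values())
    rx = max(k.shape[1] // 2 for k in kernels.values())
    padded = np.pad(vox, ((0, 0), (ry, ry), (rx, rx)), mode="reflect")
    ny, nx = padded.shape[1:]
    fy = fft.next_fast_len(ny + 2 * ry)
    fx = fft.next_fast_len(nx + 2 * rx)
    F = fft.rfft2(padded, s=(fy, fx), axes=(1, 2))
    nz, oy, ox = vox.shape
    for ssf, kernel in kernels.items():
        K = fft.rfft2(kernel, s=(fy, fx))
        full = fft.irfft2(F * K[None, :, :], s=(fy, fx), axes=(1, 2))
        ky, kx = kernel.shape[0] // 2, kernel.shape[1] // 2
        # center of the full convolution, offset by the mirror padding
        out[ssf] = full[:, ry + ky : ry + ky + oy, rx + kx : rx + kx + ox].copy()
    return out


def log_filter_bank(
    slice_pixels: np.ndarray,
    spacing_mm_inplane: tuple[float, float],
    levels: tuple = SSF_LEVELS,
    sigma_per_ssf: float = DEFAULT_SIGMA_PER_SSF,
    truncate: float = 4.0,
) -> dict[int, np.ndarray]:
    """All SSF responses for one slice, keyed by SSF level."""
    return {
        ssf: log_filter_slice(
            slice_pixels, spacing_mm_inplane, ssf, sigma_per_ssf, truncate, allowed_levels=levels
        )
        for ssf in levels
    }
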