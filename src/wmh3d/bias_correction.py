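"""Homodyne bias-field correction for FLAIR volumes.

The radiofrequency bias field is a smooth multiplicative modulation of
the image.  Its estimate is obtained by low-pass filtering the image in
2D k-space slice by slice; dividing the original image by the (modal-
intensity normalised) low-pass image cancels the modulation:

    u(x) = v(x) / b(x),      b(x) = LPF(v'(x)) / kappa,

where v'(x) is the original image extrapolated beyond the brain edge by
iterated grayscale dilation (to suppress the ringing a hard brain/air
edge would inject into the low-pass estimate), and kappa is the modal
brain intensity of the low-pass image, so that b ~= 1 in modal tissue
and u keeps the intensity scale of v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage as ndi

from .volume_io import BinaryMask, Volume, same_grid

__all__ = [
    "BiasParams",
    "dilate_edges",
    "low_pass",
    "compute_kappa",
    "correct_bias",
    "effective_window",
]

#: in-plane matrix size the window-size defaults refer to
REFERENCE_MATRIX = 512


@dataclass
class BiasParams:
    """Parameters of the homodyne correction.

    dilation_iterations
        Number of in-plane 3x3 grayscale dilations used to extrapolate
        the image beyond the brain edge (default 20).
    lpf_window_px
        Full width, in k-space pixels on a 512 in-plane matrix, of the
        centred Hanning low-pass window; scaled proportionally to the
        actual matrix size (default 32).
    kappa_bins
        Histogram bins used for the modal-intensity constant kappa
        (default 256).
    b_floor
        Lower clamp on the bias estimate before division; only relevant
        outside the dilated band where the low-pass image decays to 0.
    """

    dilation_iterations: int = 20
    lpf_window_px: int = 32
    kappa_bins: int = 256
    b_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")
        if self.lpf_window_px < 2:
            raise ValueError("lpf_window_px must be >= 2")
        if self.kappa_bins < 2:
            raise ValueError("kappa_bins must be >= 2")


def effective_window(window_px_at_512: float, shape: tuple[int, ...]) -> int:
    """Scale a window size quoted on a 512 in-plane matrix to this grid.

    The window is a k-space width, so it scales with the matrix size:
    130 px on 512^2 corresponds to ~41 px on 160^2.
    """
    n = min(shape[0], shape[1])
    w = int(round(window_px_at_512 * n / REFERENCE_MATRIX))
    return int(min(max(w, 2), n))


_FOOT_2D = np.ones((3, 3, 1), dtype=bool)  # in-plane 3x3, slice-wise


def dilate_edges(vol: Volume, brain: BinaryMask, params: BiasParams | None = None) -> Volume:
    """Extrapolate the brain image outward by iterated grayscale dilation.

    Inside the brain the image is untouched; each iteration extends the
    support by one in-plane voxel ring filled with the local grayscale
    maximum; beyond the dilated band the image is 0.
    """
    params = params or BiasParams()
    same_grid(vol, brain)
    if not brain.data.any():
        raise ValueError("brain mask is empty")
    cur = np.where(brain.data, vol.data, 0.0)
    support = brain.data.copy()
    for _ in range(params.dilation_iterations):
        grown = ndi.binary_dilation(support, structure=_FOOT_2D)
        dil = ndi.grey_dilation(cur, footprint=_FOOT_2D)
        cur = np.where(support, cur, np.where(grown, dil, 0.0))
        support = grown
    return vol.like(cur)


def _raised_cosine(n: int, width: int) -> np.ndarray:
    """1D Hanning window of full width ``width`` centred on the DC bin of
    an fftshifted length-n axis; exactly 1 at DC, 0 outside the width."""
    d = np.arange(n) - n // 2
    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * d / width))
    w[np.abs(d) > width / 2.0] = 0.0
    return w


def low_pass(vol: Volume, window_px: int) -> Volume:
    """Slice-wise k-space Hanning low-pass; returns the magnitude image.

    Each 2D slice is Fourier transformed, multiplied by a centred 2D
    Hanning window of full width ``window_px`` (zero outside), inverse
    transformed, and the magnitude taken.  The DC gain is exactly 1, so
    constant images are fixed points.
    """
    nx, ny = vol.shape[0], vol.shape[1]
    if not (2 <= window_px <= min(nx, ny)):
        raise ValueError(
            f"window_px must be in [2, {min(nx, ny)}] for shape {vol.shape}, got {window_px}"
        )
    w2d = np.outer(_raised_cosine(nx, window_px), _raised_cosine(ny, window_px))
    spec = sfft.fftshift(sfft.fft2(vol.data, axes=(0, 1)), axes=(0, 1))
    spec *= w2d[:, :, None]
    out = np.abs(sfft.ifft2(sfft.ifftshift(spec, axes=(0, 1)), axes=(0, 1)))
    return vol.like(out)


def compute_kappa(vol: Volume, brain: BinaryMask, bins: int = 256) -> float:
    """Modal brain intensity: centre of the most populated histogram bin.

    The histogram uses ``bins`` equal-width bins spanning the 1st-99th
    percentile of the brain intensities; ties are broken toward the
    lowest-intensity bin.  A constant brain trivially yields that value.
    """
    same_grid(vol, brain)
    vals = vol.data[brain.data]
    if vals.size == 0:
        raise ValueError("brain mask is empty")
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        # degenerate (near-)constant histogram: the mode is the value itself
        return float(np.median(vals))
    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    idx = int(np.argmax(hist))  # argmax takes the first (lowest) maximal bin
    return float(0.5 * (edges[idx] + edges[idx + 1]))


def correct_bias(
    vol: Volume, brain: BinaryMask, params: BiasParams | None = None
) -> tuple[Volume, Volume]:
    """Homodyne correction; returns (u, b) = (corrected image, bias estimate).

    b = LPF(v')/kappa with kappa the modal intensity of LPF(v') over the
    brain, floored at ``params.b_floor``; u = v/b inside the brain and 0
    outside, guaranteed finite.
    """
    params = params or BiasParams()
    same_grid(vol, brain)
    v_prime = dilate_edges(vol, brain, params)
    window = effective_window(params.lpf_window_px, vol.shape)
    lpf = low_pass(v_prime, window)
    kappa = compute_kappa(lpf, brain, params.kappa_bins)
    if kappa <= 0:
        raise ValueError("modal intensity kappa is non-positive; cannot normalise")
    b = np.maximum(lpf.data / kappa, params.b_floor)
    u = np.where(brain.data, vol.data / b, 0.0)
    if not np.all(np.isfinite(u)):
        raise RuntimeError("bias-corrected image contains non-finite values")
    return vol.like(u), vol.like(b)
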