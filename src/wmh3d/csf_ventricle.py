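"""CSF segmentation and ventricle isolation.

On FLAIR, CSF is the dark class inside the brain; Otsu's criterion on
the brain-interior histogram separates it from parenchyma.  Because the
subarachnoid (sulcal) and ventricular systems are both CSF, the
ventricles are isolated geometrically: a deep erosion of the brain mask
(25 mm ball by default) removes everything near the surface, and the
largest connected CSF component surviving the erosion is labelled the
ventricular system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import _morph
from .volume_io import BinaryMask, Volume, same_grid

__all__ = ["CsfParams", "otsu_threshold", "segment_csf", "extract_ventricles"]

OTSU_BINS = 256


@dataclass
class CsfParams:
    """Ventricle-extraction parameters.

    erosion_radius_mm
        Physical radius of the erosion ball (default 25 mm; equals a
        50-pixel in-plane radius at 0.5 mm resolution).  Realised as an
        anisotropic ellipsoid in voxel units via the Euclidean distance
        transform.
    connectivity
        Connected-component connectivity for the ventricle selection
        (1 = 6-connected faces; conservative, prevents diagonal leakage
        from the sulci).
    """

    erosion_radius_mm: float = 25.0
    connectivity: int = 1

    def __post_init__(self) -> None:
        if self.erosion_radius_mm <= 0:
            raise ValueError("erosion_radius_mm must be positive")


def otsu_threshold(values: np.ndarray, bins: int = OTSU_BINS) -> float:
    """Threshold maximizing between-class variance on a ``bins``-bin histogram.

    Returns the bin edge separating the two classes (values strictly
    above the edge are the upper class).  Requires at least two distinct
    values.  Ties on the criterion resolve to the lowest threshold.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("Otsu threshold undefined for constant input")
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    hist = hist.astype(np.float64)
    total = hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    # cumulative weights and means for every candidate split after bin t
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    m0 = np.cumsum(hist * centers)[:-1]
    m1 = (hist * centers).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    crit = np.full(bins - 1, -np.inf)
    crit[valid] = w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    if not np.isfinite(crit).any():
        raise ValueError("Otsu threshold undefined: all mass in one bin")
    # the criterion is exactly flat across empty bins between the classes;
    # take the first bin of the maximal plateau (relative tolerance guards
    # against float noise breaking the tie arbitrarily)
    cmax = crit.max()
    t = int(np.argmax(crit >= cmax - 1e-9 * abs(cmax)))
    return float(edges[t + 1])


def segment_csf(u: Volume, brain: BinaryMask) -> BinaryMask:
    """CSF mask: brain voxels below the Otsu threshold of the brain histogram."""
    same_grid(u, brain)
    if not brain.data.any():
        raise ValueError("brain mask is empty")
    thr = otsu_threshold(u.data[brain.data])
    return BinaryMask(brain.data & (u.data < thr), u.spacing)


def extract_ventricles(
    csf: BinaryMask, brain: BinaryMask, params: CsfParams | None = None
) -> BinaryMask:
    """Largest connected CSF component surviving a deep brain erosion.

    Returns an empty mask when nothing survives (e.g. purely peripheral
    CSF, or an erosion radius beyond the brain half-width); callers must
    treat that as 'ventricles not found', not as an error.
    """
    params = params or CsfParams()
    same_grid(csf, brain)
    core = _morph.binary_erosion_mm(brain.data, params.erosion_radius_mm, brain.spacing)
    candidate = core & csf.data
    vent = _morph.largest_component(candidate, connectivity=params.connectivity)
    return BinaryMask(vent, csf.spacing)
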