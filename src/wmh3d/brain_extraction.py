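"""Brain masking: a simple intensity+morphology surrogate, or a
user-supplied mask.

Skull stripping proper is out of scope here; on skull-free data (and on
phantoms) an Otsu foreground followed by mm-calibrated opening, closing,
hole filling and largest-component selection produces a single connected
brain mask.  For real acquisitions a precomputed mask from any external
tool can be loaded instead — downstream stages depend only on the mask
contract, not on how it was made.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from . import _morph
from .csf_ventricle import otsu_threshold
from .volume_io import BinaryMask, Volume, read_mask

__all__ = ["extract_brain", "load_external_mask"]


def extract_brain(
    vol: Volume,
    opening_radius_mm: float = 2.0,
    closing_radius_mm: float = 4.0,
) -> BinaryMask:
    """Otsu-foreground brain mask with morphological cleanup.

    Pipeline: global Otsu threshold -> binary opening (removes thin
    bright debris) -> binary closing + hole filling (bridges sulcal CSF
    grooves and fills the dark ventricular interior) -> largest
    connected component.  Raises on constant images, where Otsu is
    undefined.
    """
    thr = otsu_threshold(vol.data.ravel())
    fg = vol.data > thr
    if not fg.any():
        raise ValueError("no foreground voxels above the Otsu threshold")
    fg = _morph.binary_opening_mm(fg, opening_radius_mm, vol.spacing)
    fg = _morph.binary_closing_mm(fg, closing_radius_mm, vol.spacing)
    fg = ndi.binary_fill_holes(fg)
    fg = _morph.largest_component(fg, connectivity=3)
    if not fg.any():
        raise ValueError("brain extraction produced an empty mask")
    return BinaryMask(fg, vol.spacing)


def load_external_mask(path: str | Path, vol: Volume) -> BinaryMask:
    """Load a mask from NIfTI and binarize it (nonzero -> True).

    The mask must live on the same grid as ``vol``.
    """
    mask = read_mask(path)
    if mask.shape != vol.shape:
        raise ValueError(
            f"external mask shape {mask.shape} does not match volume shape {vol.shape}"
        )
    return BinaryMask(mask.data, vol.spacing)
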