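"""Synthetic FLAIR-like head phantoms with full ground truth.

The phantom is an ellipsoidal brain containing the tissue contrast that
drives every stage of the lesion pipeline: dark sulcal CSF grooves at
the surface, a thin bright gray-matter ribbon, mid-intensity white
matter, a single connected central ventricular system, and hyperintense
ellipsoidal lesions planted in the white matter.  A smooth multiplicative
bias field and additive Gaussian noise complete the image.  Every tissue
compartment is returned as an exact mask, and every lesion carries a
manifest row (volume, intensity, periventricular/deep category), so each
pipeline stage has an unambiguous oracle.

Geometry model
--------------
Sulci are modelled as narrow CSF fissures: radial grooves of depth
``sulcal_depth_mm`` occupying a ``sulcal_fraction`` of regularly spaced
angular wedges, the way real sulci are narrow relative to the gyri
between them.  The gray-matter ribbon is the thin band lining the
outer surface and the groove walls; everything deeper is white matter
except the central ventricle ellipsoid (dark, connected, disjoint from
the sulci).  Lesions must sit wholly inside deep white matter, pairwise
disjoint and clear of the sulcal CSF by more than the 2 mm
false-positive cut (otherwise the pipeline is entitled to remove them
and the ground truth would be ambiguous); violations raise rather than
silently corrupting the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import _morph
from .volume_io import BinaryMask, LabelMap, Volume, voxel_volume_ml

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "apply_bias_field",
]


@dataclass(frozen=True)
class LesionSpec:
    """One planted lesion: centre offset from the volume centre (mm),
    ellipsoid semi-axes (mm), and its nominal FLAIR intensity."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    intensity: float = 180.0


def _default_lesions() -> tuple[LesionSpec, ...]:
    # two periventricular (~1 mm gap to the ventricle wall), three deep,
    # and one sub-0.025 mL lesion exercising the small-lesion path
    return (
        LesionSpec((12.0, 0.0, 0.0), (4.0, 4.0, 4.0)),
        LesionSpec((0.0, -14.5, 0.0), (3.5, 3.5, 3.5)),
        LesionSpec((-18.0, 9.0, 13.0), (5.0, 5.0, 5.0)),
        LesionSpec((16.0, -12.0, -16.0), (4.0, 4.0, 4.0)),
        LesionSpec((0.0, 18.0, -22.0), (3.0, 3.0, 3.0)),
        LesionSpec((-14.0, -16.0, 16.0), (1.4, 1.4, 1.4)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; the defaults emulate the acquisition the
    pipeline targets (0.5 mm in-plane, 1.0 mm slices) at desk scale."""

    shape: tuple[int, int, int] = (160, 160, 96)
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    csf_mean: float = 40.0
    wm_mean: float = 100.0
    gm_mean: float = 130.0
    noise_sigma: float = 5.0
    bias_amplitude: float = 0.2
    bias_scale_mm: float = 40.0
    brain_semi_axes_mm: tuple[float, float, float] = (36.0, 36.0, 42.0)
    ventricle_semi_axes_mm: tuple[float, float, float] = (7.0, 10.0, 12.0)
    sulcal_depth_mm: float = 4.0
    sulcal_fraction: float = 0.25
    gm_thickness_mm: float = 1.5
    n_sulci: int = 24
    #: lesions must clear sulcal CSF by more than this margin (mm); must
    #: exceed the pipeline's 2 mm sulcal false-positive cut
    lesion_csf_margin_mm: float = 2.0
    #: periventricular cut applied to truth geometry (mm)
    pv_dist_mm: float = 3.0
    lesions: tuple[LesionSpec, ...] = field(default_factory=_default_lesions)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.csf_mean < self.wm_mean < self.gm_mean):
            raise ValueError("intensity ordering CSF < WM < GM is required")
        for les in self.lesions:
            if les.intensity < self.gm_mean:
                raise ValueError("lesion intensity must be >= GM mean")
            if les.intensity <= 1.2 * self.wm_mean + 4.0 * self.noise_sigma:
                raise ValueError(
                    "lesion intensity must exceed 1.2*WM + 4*sigma to be detectable"
                )
        if self.gm_thickness_mm > 3.0:
            raise ValueError("gray-matter ribbon must stay thin (<= 3 mm)")
        if not (0.0 < self.sulcal_fraction <= 0.5):
            raise ValueError("sulcal_fraction must be in (0, 0.5]")
        if not (0.0 <= self.bias_amplitude <= 0.5):
            raise ValueError("bias amplitude must be in [0, 0.5]")


@dataclass
class PhantomBundle:
    """A phantom volume plus its complete ground truth."""

    flair: Volume
    ideal: Volume  # noise-free, bias-free tissue image
    bias: Volume  # the multiplicative truth field (1 everywhere if amplitude 0)
    truth_brain: BinaryMask
    truth_csf: BinaryMask  # sulcal CSF only
    truth_ventricle: BinaryMask
    truth_gm: BinaryMask
    truth_wm: BinaryMask
    truth_lesions: LabelMap
    manifest: pd.DataFrame
    spec: PhantomSpec


def _coords_mm(shape, spacing):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xm, ym, zm, center, semi) -> np.ndarray:
    return (
        ((xm - center[0]) / semi[0]) ** 2
        + ((ym - center[1]) / semi[1]) ** 2
        + ((zm - center[2]) / semi[2]) ** 2
    ) <= 1.0


def apply_bias_field(
    vol: Volume, amplitude: float, scale_mm: float, seed: int
) -> tuple[Volume, Volume]:
    """Multiply a volume by a smooth random field of mean 1.

    The field is Gaussian-smoothed white noise (sigma = ``scale_mm``),
    centred and scaled so that over the support of the image (voxels
    with intensity > 0) it has mean exactly 1 and range within
    [1 - amplitude, 1 + amplitude].
    """
    if not (0.0 <= amplitude <= 0.5):
        raise ValueError("amplitude must be in [0, 0.5]")
    if scale_mm <= 0:
        raise ValueError("scale_mm must be positive")
    if amplitude == 0.0:
        ones = vol.like(np.ones_like(vol.data))
        return vol.like(vol.data.copy()), ones
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(vol.shape)
    sigma_vox = [scale_mm / s for s in vol.spacing]
    g = ndi.gaussian_filter(g, sigma=sigma_vox)
    support = vol.data > 0
    if not support.any():
        support = np.ones(vol.shape, dtype=bool)
    g = g - g[support].mean()
    peak = np.abs(g[support]).max()
    if peak == 0:
        g = np.zeros_like(g)
    else:
        g = g / peak
    bias = np.clip(1.0 + amplitude * g, 1.0 - amplitude, 1.0 + amplitude)
    return vol.like(vol.data * bias), vol.like(bias)


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Generate a phantom bundle; identical specs give bit-identical output."""
    spec = spec or PhantomSpec()
    shape, spacing = spec.shape, spec.spacing
    xm, ym, zm = _coords_mm(shape, spacing)

    brain = _ellipsoid(xm, ym, zm, (0, 0, 0), spec.brain_semi_axes_mm)
    depth = _morph.depth_mm(brain, spacing)

    ventricle = _ellipsoid(xm, ym, zm, (0, 0, 0), spec.ventricle_semi_axes_mm)
    ventricle &= brain

    # narrow radial CSF fissures occupying sulcal_fraction of each
    # angular period; sin(n*theta) > cos(pi*f) selects a fraction f
    theta = np.arctan2(ym, xm)
    wedge = np.sin(spec.n_sulci * theta) > np.cos(np.pi * spec.sulcal_fraction)
    sulci = brain & (depth <= spec.sulcal_depth_mm) & wedge

    # gray matter lines the outer surface and the groove walls
    near_surface = depth <= spec.gm_thickness_mm
    near_sulci = _morph.distance_to_set_mm(sulci, spacing) <= spec.gm_thickness_mm
    gm = brain & ~sulci & ~ventricle & (near_surface | near_sulci)
    interior = brain & ~sulci & ~gm & ~ventricle

    # lesion masks, validated against overlap and clearance margins
    dist_sulci = _morph.distance_to_set_mm(sulci, spacing)
    lesion_labels = np.zeros(shape, dtype=np.int32)
    for i, les in enumerate(spec.lesions, start=1):
        m = _ellipsoid(xm, ym, zm, les.center_mm, les.semi_axes_mm)
        if not m.any():
            raise ValueError(f"lesion {i} lies outside the volume")
        if np.any(m & (lesion_labels > 0)):
            raise ValueError(f"lesion {i} overlaps a previously planted lesion")
        if np.any(m & ~interior):
            raise ValueError(f"lesion {i} extends outside deep white matter")
        if dist_sulci[m].min() <= spec.lesion_csf_margin_mm:
            raise ValueError(
                f"lesion {i} lies within {spec.lesion_csf_margin_mm} mm of sulcal "
                "CSF; ground truth would be ambiguous under the sulcal cut"
            )
        lesion_labels[m] = i

    wm = interior & (lesion_labels == 0)

    ideal = np.zeros(shape)
    ideal[sulci | ventricle] = spec.csf_mean
    ideal[gm] = spec.gm_mean
    ideal[wm] = spec.wm_mean
    for i, les in enumerate(spec.lesions, start=1):
        ideal[lesion_labels == i] = les.intensity

    ideal_vol = Volume(ideal, spacing)
    biased, bias = apply_bias_field(
        ideal_vol, spec.bias_amplitude, spec.bias_scale_mm, spec.seed
    )
    noise_rng = np.random.default_rng((spec.seed + 1) % 2**31)
    flair = biased.data + (
        noise_rng.standard_normal(shape) * spec.noise_sigma if spec.noise_sigma > 0 else 0.0
    )
    flair = np.clip(flair, 0.0, None)

    # ground-truth category from the exact geometry
    dist_vent = _morph.distance_to_set_mm(ventricle, spacing)
    vox_ml = voxel_volume_ml(spacing)
    rows = []
    for i, les in enumerate(spec.lesions, start=1):
        m = lesion_labels == i
        n_vox = int(m.sum())
        cx, cy, cz = (float(c) for c in np.mean(np.argwhere(m), axis=0))
        d = float(dist_vent[m].min())
        rows.append(
            {
                "label": i,
                "center_x": cx,
                "center_y": cy,
                "center_z": cz,
                "voxel_count": n_vox,
                "volume_ml": n_vox * vox_ml,
                "mean_intensity": les.intensity,
                "dist_ventricle_mm": d,
                "category": "PVH" if d < spec.pv_dist_mm else "DWMH",
            }
        )
    manifest = pd.DataFrame(rows)

    return PhantomBundle(
        flair=Volume(flair, spacing),
        ideal=ideal_vol,
        bias=bias,
        truth_brain=BinaryMask(brain, spacing),
        truth_csf=BinaryMask(sulci, spacing),
        truth_ventricle=BinaryMask(ventricle, spacing),
        truth_gm=BinaryMask(gm, spacing),
        truth_wm=BinaryMask(wm, spacing),
        truth_lesions=LabelMap(lesion_labels, spacing),
        manifest=manifest,
        spec=spec,
    )


def lesion_free_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Convenience: the default phantom with no lesions planted."""
    return replace(PhantomSpec(seed=seed, lesions=()), **overrides)


def uniform_head(
    shape: tuple[int, int, int] = (160, 160, 96),
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
    intensity: float = 100.0,
    noise_sigma: float = 0.0,
    bias_amplitude: float = 0.0,
    bias_scale_mm: float = 40.0,
    semi_axes_mm: tuple[float, float, float] = (36.0, 36.0, 42.0),
    seed: int = 0,
) -> tuple[Volume, BinaryMask, Volume]:
    """A structureless head: one ellipsoid of uniform tissue intensity.

    Returns (volume, brain mask, truth bias field).  This isolates the
    smooth multiplicative field as the only spatial modulation, which is
    the working assumption of the homodyne bias estimator; it is the
    right substrate for field parameter-recovery and flat-field
    fixed-point checks, free of the anatomy leakage a structured brain
    adds.
    """
    xm, ym, zm = _coords_mm(shape, spacing)
    brain = _ellipsoid(xm, ym, zm, (0, 0, 0), semi_axes_mm)
    vol = Volume(np.where(brain, float(intensity), 0.0), spacing)
    biased, field = apply_bias_field(vol, bias_amplitude, bias_scale_mm, seed)
    data = biased.data
    if noise_sigma > 0:
        rng = np.random.default_rng((seed + 1) % 2**31)
        data = np.clip(data + rng.standard_normal(shape) * noise_sigma, 0.0, None)
    return Volume(data, spacing), BinaryMask(brain, spacing), field
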