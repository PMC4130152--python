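"""End-to-end orchestration of the seven-stage lesion pipeline.

Stages, in order: (1) brain mask (surrogate extraction or external);
(2) homodyne bias-field correction; (3) CSF segmentation and ventricle
isolation; (4) high-spatial-frequency suppression, thresholding and
false-positive filtering; (5) small-lesion recovery; (6) region growing
to actual lesion extent; (7) PVH/DWMH classification and reporting.
Every stage is a pure function of the input volume and the
configuration, so re-running is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import brain_extraction, csf_ventricle, lesion_analysis, wmh_core
from .bias_correction import BiasParams, correct_bias
from .csf_ventricle import CsfParams
from .lesion_analysis import FilterParams
from .volume_io import (
    BinaryMask,
    LabelMap,
    Volume,
    read_volume,
    write_labelmap,
    write_mask,
    write_volume,
)
from .wmh_core import SuppressionParams

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("wmh3d")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults are the calibrated operating point
    (W = 130 px, lambda = 1.2, p = 1.2, FA <= 0.6, 2.0 mm sulcal cut,
    3.0 mm periventricular cut, 100-voxel small-lesion gate, 25 mm
    erosion, 20 dilation iterations)."""

    bias: BiasParams = field(default_factory=BiasParams)
    csf: CsfParams = field(default_factory=CsfParams)
    suppression: SuppressionParams = field(default_factory=SuppressionParams)
    filters: FilterParams = field(default_factory=FilterParams)
    brain_opening_mm: float = 2.0
    brain_closing_mm: float = 4.0
    save_intermediate: bool = False

    _SECTIONS = {"bias": BiasParams, "csf": CsfParams, "suppression": SuppressionParams,
                 "filters": FilterParams}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        scalar_fields = {
            f.name for f in dataclasses.fields(cls) if f.name not in cls._SECTIONS
        }
        for key, value in data.items():
            if key in cls._SECTIONS:
                sub_cls = cls._SECTIONS[key]
                known = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown keys in config section '{key}': {sorted(unknown)}")
                kwargs[key] = sub_cls(**value)
            elif key in scalar_fields:
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class PipelineResult:
    summary: dict
    records: list
    lesions: LabelMap
    brain: BinaryMask
    csf: BinaryMask
    ventricle: BinaryMask
    u: Volume
    bias: Volume
    stats: wmh_core.WMStats
    threshold: float


def _stage(name: str):
    """Log a stage boundary; failures are re-raised with the stage named."""
    log.info("stage: %s", name)


def run_pipeline(
    flair: str | Path | Volume,
    config: PipelineConfig | None = None,
    brain_mask: BinaryMask | str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full seven-stage pipeline on one FLAIR volume.

    ``brain_mask`` skips the extraction surrogate.  When ``out_dir`` is
    given, masks, label map, per-lesion CSV, removal log and summary
    JSON are written there.  An empty ventricle extraction is a warning
    (all lesions become DWMH), not an error.
    """
    config = config or PipelineConfig()
    vol = flair if isinstance(flair, Volume) else read_volume(flair)

    _stage("1/7 brain mask")
    if brain_mask is None:
        brain = brain_extraction.extract_brain(
            vol, config.brain_opening_mm, config.brain_closing_mm
        )
    elif isinstance(brain_mask, BinaryMask):
        brain = brain_mask
    else:
        brain = brain_extraction.load_external_mask(brain_mask, vol)
    log.info("brain voxels: %d", brain.count())

    _stage("2/7 bias field correction")
    u, b = correct_bias(vol, brain, config.bias)

    _stage("3/7 CSF and ventricle extraction")
    csf = csf_ventricle.segment_csf(u, brain)
    ventricle = csf_ventricle.extract_ventricles(csf, brain, config.csf)
    if not ventricle.data.any():
        log.warning("ventricle extraction empty: all lesions will classify as DWMH")
    sulcal = BinaryMask(csf.data & ~ventricle.data, u.spacing)
    log.info("csf voxels: %d, ventricle voxels: %d", csf.count(), ventricle.count())

    _stage("4/7 high-frequency suppression and candidate filtering")
    stats = wmh_core.estimate_wm_stats(u, brain, csf, config.bias.kappa_bins)
    threshold = wmh_core.wmh_threshold(
        stats, p=config.suppression.p, noise_mult=config.suppression.noise_mult
    )
    log.info(
        "S_WM=%.3f sigma_WM=%.3f threshold=%.3f", stats.s_wm, stats.sigma_wm, threshold
    )
    u_prime = wmh_core.suppress_high_frequency(u, brain, config.suppression)
    candidates = wmh_core.label_candidates(
        u_prime, threshold, brain, config.suppression.connectivity
    )
    large, removed_large = lesion_analysis.filter_false_positives(
        candidates, u, ventricle, sulcal, config.filters
    )
    log.info(
        "large-path candidates: %d, kept: %d", candidates.n_labels, large.n_labels
    )

    _stage("5/7 small lesion detection")
    small, removed_small = lesion_analysis.detect_small_lesions(
        u, stats, brain, ventricle, sulcal, config.filters,
        p=config.suppression.p, noise_mult=config.suppression.noise_mult,
        exclude=large, connectivity=config.suppression.connectivity,
    )
    log.info("small-path lesions kept: %d", small.n_labels)

    _stage("6/7 region growing")
    seeds = lesion_analysis.merge_label_maps(large, small)
    lesions = lesion_analysis.region_grow(seeds, u, stats, brain, config.filters)

    _stage("7/7 classification and reporting")
    records = lesion_analysis.classify_lesions(
        lesions, u, ventricle, sulcal, config.filters
    )
    summary = lesion_analysis.summarize(records, brain, csf, ventricle)
    summary["s_wm"] = stats.s_wm
    summary["sigma_wm"] = stats.sigma_wm
    summary["wmh_threshold"] = threshold
    log.info("lesions: %d, total volume %.4f mL", summary["lesion_count"],
             summary["total_wmh_volume_ml"])

    result = PipelineResult(
        summary=summary, records=records, lesions=lesions, brain=brain,
        csf=csf, ventricle=ventricle, u=u, bias=b, stats=stats,
        threshold=threshold,
    )
    if out_dir is not None:
        _write_outputs(result, removed_large, removed_small, Path(out_dir), config)
    return result


def _write_outputs(res, removed_large, removed_small, out_dir: Path,
                   config: PipelineConfig) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    affine = res.u.affine
    write_labelmap(res.lesions, out_dir / "lesions.nii.gz", affine)
    write_mask(res.brain, out_dir / "brain.nii.gz", affine)
    write_mask(res.csf, out_dir / "csf.nii.gz", affine)
    write_mask(res.ventricle, out_dir / "ventricle.nii.gz", affine)
    if config.save_intermediate:
        write_volume(res.u, out_dir / "bias_corrected.nii.gz")
        write_volume(res.bias, out_dir / "bias_field.nii.gz")
    lesion_analysis.records_to_frame(res.records).to_csv(
        out_dir / "lesions.csv", index=False
    )
    frames = [f for f in (removed_large, removed_small) if not f.empty]
    removed = (
        pd.concat(frames, ignore_index=True)
        if frames
        else removed_large  # keep the header columns for an empty log
    )
    removed.to_csv(out_dir / "removed.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(res.summary, indent=2, sort_keys=True) + "\n"
    )
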