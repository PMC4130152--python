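"""Shared fixtures: phantoms and pipeline runs are expensive, so they are
generated once per session and shared read-only across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from wmh3d import bias_correction, phantom, pipeline

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """Default phantom: six lesions (two periventricular), bias 0.2, noise 5."""
    return phantom.generate_phantom(phantom.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def bundle_lesion_free():
    return phantom.generate_phantom(phantom.lesion_free_spec(seed=11))


@pytest.fixture(scope="session")
def bundle_nobias():
    """Phantom without bias field: intensities are tissue means + noise."""
    return phantom.generate_phantom(phantom.PhantomSpec(seed=5, bias_amplitude=0.0))


@pytest.fixture(scope="session")
def corrected(bundle):
    """Bias-corrected image and field estimate, using the truth brain mask."""
    u, b = bias_correction.correct_bias(bundle.flair, bundle.truth_brain)
    return u, b


@pytest.fixture(scope="session")
def pipeline_default(bundle):
    """Full pipeline on the default phantom, surrogate brain extraction."""
    return pipeline.run_pipeline(bundle.flair)


@pytest.fixture(scope="session")
def pipeline_truth_mask(bundle):
    """Full pipeline with the truth brain mask supplied externally."""
    return pipeline.run_pipeline(bundle.flair, brain_mask=bundle.truth_brain)


@pytest.fixture(scope="session")
def pipeline_lesion_free(bundle_lesion_free):
    return pipeline.run_pipeline(bundle_lesion_free.flair)


@pytest.fixture(scope="session")
def uniform_biased():
    """Structureless head with noise and a 20% bias field (field recovery)."""
    vol, brain, field = phantom.uniform_head(
        noise_sigma=5.0, bias_amplitude=0.2, bias_scale_mm=40.0, seed=3
    )
    return vol, brain, field


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom
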