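"""Shared fixtures: phantoms and pipeline runs reused across the suite."""

import numpy as np
import pytest

from mr2sct import phantom as phantom_mod
from mr2sct import pipeline as pipeline_mod


def dice_masks(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 1.0 if denom == 0 else 2.0 * (a & b).sum() / denom


@pytest.fixture(scope="session")
def ph_small_noisy():
    """128^3 / 1.5 mm head phantom at the default degradation."""
    cfg = phantom_mod.PhantomConfig(shape=(128,) * 3, spacing_mm=(1.5,) * 3)
    return phantom_mod.generate_phantom(cfg, seed=0)


@pytest.fixture(scope="session")
def ph_small_clean():
    """Same head with zero noise and no bias field."""
    cfg = phantom_mod.PhantomConfig(
        shape=(128,) * 3, spacing_mm=(1.5,) * 3, noise_sigma=0.0, bias_amplitude=0.0
    )
    return phantom_mod.generate_phantom(cfg, seed=0)


@pytest.fixture(scope="session")
def ph_default():
    """192^3 / 1 mm phantom: the full-resolution recovery benchmark."""
    cfg = phantom_mod.PhantomConfig(shape=(192,) * 3, spacing_mm=(1.0,) * 3)
    return phantom_mod.generate_phantom(cfg, seed=0)


@pytest.fixture(scope="session")
def run_small_noisy(ph_small_noisy):
    return pipeline_mod.run_pipeline(ph_small_noisy.mr, ph_small_noisy.contours)


@pytest.fixture(scope="session")
def run_small_clean(ph_small_clean):
    return pipeline_mod.run_pipeline(ph_small_clean.mr, ph_small_clean.contours)


@pytest.fixture(scope="session")
def run_default(ph_default):
    return pipeline_mod.run_pipeline(ph_default.mr, ph_default.contours)
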