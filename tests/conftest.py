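"""Shared fixtures: the expensive phantom analyses are built once per session."""

import numpy as np
import pytest

from lv4dflow import AnalysisConfig, analyze_dataset
from lv4dflow.phantom import PhantomSpec, generate_phantom, realize


@pytest.fixture(scope="session")
def reference_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def reference_dataset(reference_spec):
    """Noise-free, offset-free default phantom."""
    return realize(reference_spec)


@pytest.fixture(scope="session")
def reference_analysis(reference_dataset):
    ds = reference_dataset
    return analyze_dataset(
        ds.field, ds.segmentation, ds.subject,
        AnalysisConfig(background_correction=False),
    )


@pytest.fixture(scope="session")
def noisy_analyses():
    """Five independent noise realisations at 3 cm/s, fully analysed."""
    out = []
    for seed in range(5):
        ds = realize(PhantomSpec(noise_sigma=3.0, seed=seed))
        res = analyze_dataset(
            ds.field, ds.segmentation, ds.subject,
            static_mask=ds.truth.static_mask,
        )
        out.append((ds, res))
    return out


@pytest.fixture(scope="session")
def small_uniform_field():
    """Tiny uniform-velocity field for sampler/integrator unit tests."""
    from lv4dflow import VelocityField4D

    data = np.zeros((8, 8, 8, 4, 3))
    data[..., 0] = 10.0  # cm/s along x
    return VelocityField4D(data, 3.0, 52.0)
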