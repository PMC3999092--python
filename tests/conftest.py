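"""Shared fixtures: small phantoms and prepared subjects.

Phantoms here are deliberately smaller than the package defaults so the
unit suite stays fast; the acceptance tests build their own cohorts at
the protocol's scale.
"""

from dataclasses import replace

import numpy as np
import pytest

from plaqseg.experiment import ExperimentConfig, prepare_subject
from plaqseg.phantom import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        n_slices=4,
        grid_shape=(48, 48),
        lumen_radius_mm=2.0,
        wall_thickness_mm=2.5,
        misreg_amplitude_mm=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def aligned_bundle(small_spec):
    """Same phantom without misregistration (reference == truth)."""
    return generate_phantom(replace(small_spec, misreg_amplitude_mm=0.0, seed=5))


@pytest.fixture(scope="session")
def fast_config() -> ExperimentConfig:
    return ExperimentConfig(seed=1)


@pytest.fixture(scope="session")
def prepared_subject(aligned_bundle, fast_config):
    return prepare_subject(aligned_bundle, fast_config)


@pytest.fixture(scope="session")
def tiny_cohort(small_spec):
    """Three aligned small subjects for cross-validation tests."""
    return generate_cohort(
        3, base_spec=replace(small_spec, misreg_amplitude_mm=0.0), base_seed=21
    )
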