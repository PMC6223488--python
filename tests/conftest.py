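"""Shared fixtures: test-scale phantoms and derived atlas cohorts.

The test suite works at a reduced grid (48 x 48 x 32 voxels, 4 mm
isotropic) covering the same 192 x 192 x 128 mm field of view as the
full-resolution phantom, so every structure keeps its physical size.
Expensive fixtures are session-scoped and deterministic.
"""

import numpy as np
import pytest

from atlasseg.phantom import PhantomSpec, make_atlas_cohort, make_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(48, 48, 32), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def phantom48(small_spec):
    """Base test phantom: (image, {structure: mask})."""
    return make_phantom(small_spec, seed=11)


@pytest.fixture(scope="session")
def cohort3(phantom48):
    """Three atlas cases derived from the base phantom."""
    img, masks = phantom48
    return make_atlas_cohort(img, masks, n=3, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
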