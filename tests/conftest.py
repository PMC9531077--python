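"""Shared fixtures: phantom templates and populations at two resolutions.

The full-resolution template (~9000 vertices) is used for measurement-accuracy
tests; the small template (~2000 vertices) keeps registration and pipeline
tests fast.  Both are session-scoped — template construction is deterministic.
"""

import numpy as np
import pytest

from bonessm.phantom import PhantomSpec, PopulationModel, make_template, sample_population


@pytest.fixture(scope="session")
def template():
    return make_template(PhantomSpec())


@pytest.fixture(scope="session")
def small_template():
    return make_template(PhantomSpec(mesh_resolution=2000))


@pytest.fixture(scope="session")
def small_population(small_template):
    model = PopulationModel(small_template)
    return model, sample_population(model, 8, seed=11)


@pytest.fixture(scope="session")
def noise_free_population(small_template):
    model = PopulationModel(small_template, noise_sd=0.0)
    return model, sample_population(model, 6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rotation(rng):
    """Uniform random proper rotation (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
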