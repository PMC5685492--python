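"""Shared fixtures: small phantoms and label-map constructions.

Everything is generated programmatically and seeded; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import brainseg as bs


@pytest.fixture(scope="session")
def adult_small():
    """Noisy adult-contrast phantom on a 32^3 grid."""
    return bs.generate_phantom(bs.adult_spec(grid_shape=(32, 32, 32), seed=11))


@pytest.fixture(scope="session")
def adult_noiseless():
    """Zero-noise adult phantom: grey == class mean everywhere in the brain."""
    spec = bs.PhantomSpec(
        grid_shape=(32, 32, 32),
        class_intensity={1: (60.0, 0.0), 2: (110.0, 0.0), 3: (170.0, 0.0)},
        seed=5,
    )
    return bs.generate_phantom(spec)


@pytest.fixture(scope="session")
def training_small():
    """Ten perturbed training subjects on a 32^3 grid (adult contrast)."""
    return bs.generate_training_set(bs.adult_spec(grid_shape=(32, 32, 32), seed=21), 10)


def random_labelmap(shape, n_labels=3, seed=0, background=False):
    """Uniform random label map; labels 1..n_labels (optionally with 0s)."""
    rng = np.random.default_rng(seed)
    lo = 0 if background else 1
    vals = rng.integers(lo, n_labels + 1, size=shape).astype(np.int16)
    return bs.LabelMap(vals)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
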