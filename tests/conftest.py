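"""Shared fixtures: tiny phantom datasets generated at test time."""

import numpy as np
import pytest

from ringspm import synthetic
from ringspm.dataset import load_all
from ringspm.synthetic import generate_phantom_dataset


@pytest.fixture(scope="session")
def small_separable(tmp_path_factory):
    """Six patients, two slices each, widely separated tumor textures."""
    out = tmp_path_factory.mktemp("sep")
    cfg = synthetic.separable_config(
        seed=11, n_patients=6, slices_per_patient=2,
        image_size=96, margin=20, tumor_radius_range=(8, 12),
    )
    manifest = generate_phantom_dataset(cfg, out)
    return cfg, manifest


@pytest.fixture(scope="session")
def small_separable_slices(small_separable):
    _, manifest = small_separable
    return load_all(manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, size=48, r_range=(5, 12), irregularity=0.3):
    """A random star-convex mask with margin from the border."""
    r = rng.uniform(*r_range)
    pad = int(np.ceil(r * 1.5)) + 2
    center = (rng.uniform(pad, size - pad), rng.uniform(pad, size - pad))
    return synthetic.generate_tumor_mask((size, size), center, r, irregularity, rng)
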