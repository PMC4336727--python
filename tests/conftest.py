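"""Shared fixtures: a small synthetic canopy and a trained mini pipeline.

Everything is generated programmatically and seeded; the mini pipeline uses
a reduced vocabulary (k = 60) and patch count so unit tests stay fast while
exercising the identical code paths as the full-scale configuration.
"""

import numpy as np
import pytest

from paddyflower.classifier import train_model
from paddyflower.features import dense_multiscale_sift
from paddyflower.synthetic import CanopySpec, render_canopy, sample_patches
from paddyflower.vocabulary import nonzero_descriptors, train_codebook


@pytest.fixture(scope="session")
def train_canopy():
    spec = CanopySpec(width=700, height=560, n_flowering=10, seed=101)
    return render_canopy(spec)


@pytest.fixture(scope="session")
def patch_db(train_canopy):
    img, gt = train_canopy
    return sample_patches(img, gt, n_pos=14, n_neg=14, patch_px_range=(60, 140), seed=11)


@pytest.fixture(scope="session")
def mini_codebook(patch_db):
    descs = np.vstack([
        nonzero_descriptors(dense_multiscale_sift(p.patch.luminance)) for p in patch_db
    ])
    return train_codebook(descs, k=60, n_restarts=2, seed=5)


@pytest.fixture(scope="session")
def mini_model(patch_db, mini_codebook):
    return train_model(patch_db, mini_codebook, seed=7)


@pytest.fixture(scope="session")
def test_canopy():
    """Held-out canopy with flowering panicles, distinct from the training one."""
    spec = CanopySpec(width=700, height=560, n_flowering=5, seed=7)
    return render_canopy(spec)
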