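"""Shared fixtures: phantom datasets and the desk-scale trained model.

The expensive session fixtures (phantom tree on disk, a trained full model)
are created lazily, so unit-test-only runs never pay for training.
"""

import numpy as np
import pytest

from msdrcn import build_ms_drcn, desk_config
from msdrcn.data import stratified_split
from msdrcn.phantom import generate_dataset
from msdrcn.training import desk_train_config, train

DESK_SIZE = 64
DESK_SPECKLE = 0.3


@pytest.fixture(scope="session")
def phantom_root(tmp_path_factory):
    """250 phantoms per class at 64x64 with speckle sigma 0.3."""
    root = tmp_path_factory.mktemp("phantoms") / "ds"
    manifest = generate_dataset(250, root, global_seed=0,
                                speckle_sigma=DESK_SPECKLE,
                                height=DESK_SIZE, width=DESK_SIZE)
    return root, manifest


@pytest.fixture(scope="session")
def desk_split(phantom_root):
    """200 train / 50 validation per class."""
    _, manifest = phantom_root
    return stratified_split(manifest, 0.2, seed=0)


@pytest.fixture(scope="session")
def trained_full_model(desk_split):
    """The full model trained on the desk benchmark (10 epochs, seed 0)."""
    train_m, val_m = desk_split
    model = build_ms_drcn(desk_config(seed=0), "ms-drcn")
    result = train(model, train_m, val_m, desk_train_config(epochs=10, seed=0),
                   verbose=False)
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
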