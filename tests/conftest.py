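"""Shared fixtures: a tiny synthetic screen and a scaled-down model config.

Everything is generated programmatically and cached per session; no data
files ship with the tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from synergynet.config import TrainConfig, small_model_config
from synergynet.model import FeatureStore, SynergyModel
from synergynet.synthetic import SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    """8 drugs x 6 cell lines, 120 examples — enough for smoke training."""
    spec = SyntheticSpec(n_drugs=8, n_cells=6, n_examples=120, seed=3)
    return make_dataset(spec, tmp_path_factory.mktemp("tiny"))


@pytest.fixture(scope="session")
def small_config():
    return small_model_config(seed=1)


@pytest.fixture(scope="session")
def tiny_store(tiny_bundle, small_config):
    return FeatureStore(tiny_bundle.drugs, small_config)


@pytest.fixture(scope="session")
def tiny_model(tiny_bundle, small_config):
    return SynergyModel(small_config, tiny_bundle.expr_width,
                        tiny_bundle.mut_width, len(tiny_bundle.cells))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def quick_train_config():
    return TrainConfig(epochs=3, batch_size=32, seed=7, val_fraction=0.2,
                       patience=10)
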