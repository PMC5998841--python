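"""Shared fixtures: all data are generated programmatically at test time."""

import numpy as np
import pytest

from angiotrack import synthgen as sg
from angiotrack import detect as dt


@pytest.fixture(scope="session")
def bench_config():
    """The standard scaled-down study conditions."""
    return sg.SimulationConfig.benchmark()


@pytest.fixture(scope="session")
def small_scene_config():
    """A small scene that renders quickly (registration/pipeline tests)."""
    return sg.SimulationConfig.benchmark(image_shape=(600, 800),
                                         n_initial_cells=3, rng_seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_scene_config):
    """Rendered frames + detections + transforms for one small slot."""
    return sg.simulate_dataset(small_scene_config)


@pytest.fixture(scope="session")
def bench_dataset(bench_config):
    """Trajectory-level dataset (no rendering) at benchmark scale."""
    import dataclasses
    cfg = dataclasses.replace(bench_config, rng_seed=3)
    return sg.simulate_dataset(cfg, render=False)


@pytest.fixture(scope="session")
def trained_detector(bench_config):
    """Patch CNN trained once on a synthetic template bank."""
    patches, labels = sg.make_template_bank(bench_config, n_cell=40,
                                            n_noncell=40)
    bank, bank_labels = dt.augment_templates(patches, labels, rng_seed=0)
    model, _ = dt.train_classifier(bank, bank_labels, rng_seed=0,
                                   epochs=3, cross_validate=False)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
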