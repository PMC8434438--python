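"""Shared fixtures: synthetic rooms, a trained classifier and one full
benchmark run (computed once per session, reused by several tests)."""

import warnings

import numpy as np
import pytest

import depthact as da
from depthact import pipeline, synthetic
from depthact.config import PipelineConfig

warnings.filterwarnings(
    "ignore", message=".*probability.*", category=FutureWarning)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_room():
    """Noiseless reference room: (spec, background depth, region labels)."""
    spec = synthetic.default_room(noise_sigma=0.0, hole_rate=0.0)
    depth, regions = synthetic.render_background(spec)
    return spec, depth, regions


@pytest.fixture(scope="session")
def trained_model(cfg):
    """SVM trained on the synthetic labelled scripts (study conditions)."""
    return pipeline.train_benchmark_model(cfg, seed=1)


@pytest.fixture(scope="session")
def benchmark_run(cfg, trained_model):
    """One recognised 600-frame day sequence: (result, ground truth)."""
    return pipeline.run_benchmark(cfg, trained_model, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
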