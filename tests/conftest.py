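"""Shared fixtures: small backbones, small stimulus sets, and session-scoped
runs of the heavier pipeline experiments (reused across test modules)."""

import numpy as np
import pytest

from emosel import pipeline
from emosel.backbone import build_backbone, mini_cnn_spec
from emosel.synth import SynthStimulusConfig, generate_affective_set


@pytest.fixture(scope="session")
def tiny_backbone():
    """A 2-layer, 6/8-filter mini-cnn for fast mechanism tests."""
    return build_backbone(
        mini_cnn_spec(conv_channels=(6, 8), kernel_sizes=(3, 3), input_size=16, seed=11)
    )


@pytest.fixture(scope="session")
def small_set():
    """A 30-image synthetic affective set (10 per category, 16x16)."""
    return generate_affective_set(
        SynthStimulusConfig(image_size=16, n_per_category=10, seed=5, dataset="small")
    )


@pytest.fixture(scope="session")
def recovery():
    """The planted high-effect-size fixture run once per session."""
    return pipeline.run_recovery(seed=1)


@pytest.fixture(scope="session")
def manipulation_outcome(recovery):
    """Enhancement sweep + lesion + matched lesion controls on the recovered
    pleasant set (full 51-point alpha grid)."""
    return pipeline.run_manipulation_fixture(recovery, seed=1)


@pytest.fixture(scope="session")
def null_runs():
    """Ten full-pipeline runs at effect size 0."""
    return pipeline.null_calibration(seed=3, n_seeds=10)


@pytest.fixture(scope="session")
def emergence_runs():
    """Object-pretrained vs random-weight mini-cnn contrast over 5 seeds."""
    return pipeline.trained_vs_random(seed=2, n_seeds=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
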