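"""Shared fixtures: a small synthetic study generated once per session."""

import warnings

import numpy as np
import pytest

from talkerlearn import StudyConfig, behavior
from talkerlearn import synthetic_data as sd

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """Six participants, 3 sentences per talker (12 trials per block)."""
    return StudyConfig(
        n_participants=6, n_sentences=3, trials_per_block=12, rng_seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Complete small study: features, ground truth, scored trials, traces."""
    cfg = small_config
    seed = cfg.rng_seed
    features = {
        lang: sd.gen_talkers(cfg, seed, lang) for lang in cfg.language_names
    }
    truth = sd.build_ground_truth(cfg, features, seed)
    trials = behavior.score_accuracy(sd.gen_behavior(cfg, truth, seed))
    traces = sd.gen_pupil(cfg, trials, truth, seed)
    return {
        "config": cfg,
        "features": features,
        "truth": truth,
        "trials": trials,
        "traces": traces,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
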