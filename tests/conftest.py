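"""Shared fixtures.

The session-scoped ``study`` fixture generates the severity-coupled corpus
and trains the FiLM classifier once; it backs the direction-match and
capability tests.  Everything else uses small, cheap objects.
"""

import numpy as np
import pytest

from acamspeech import pipeline, synthio
from acamspeech.model import AqFilmClassifier, ModelConfig

STUDY_SEED = 1


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """An untrained classifier (deterministic init)."""
    return AqFilmClassifier(ModelConfig(seed=0))


@pytest.fixture(scope="session")
def clean_utterance():
    r = np.random.default_rng(7)
    return synthio.gen_keyword_waveform(synthio.make_keyword_spec(2), r,
                                        severity=70.0)


@pytest.fixture(scope="session")
def study():
    """Full severity-coupled corpus + trained classifier (built once)."""
    return pipeline.run_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_test_split(study):
    return [u for u, s in zip(study.utterances, study.splits) if s == "test"]
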