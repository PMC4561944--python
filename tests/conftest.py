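from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

import pytest

from cardex.lexicons import load_lexicons
from cardex.pipeline import train_pipeline
from cardex.synthetic_data import (GenConfig, generate_notes, sectionizer_training,
                                   smoking_training, time_training)

TRAIN_SEED = 11


@pytest.fixture(scope="session")
def lex():
    return load_lexicons()


@pytest.fixture(scope="session")
def train_cfg():
    return GenConfig(seed=TRAIN_SEED, n_patients=40, notes_per_patient=3)


@pytest.fixture(scope="session")
def train_notes(train_cfg):
    return generate_notes(train_cfg)


@pytest.fixture(scope="session")
def pipe(train_cfg, train_notes, lex):
    """One fully trained pipeline shared by the model-dependent tests."""
    return train_pipeline(
        sectionizer_training(train_notes),
        smoking_training(train_cfg),
        time_training(train_notes),
        lex=lex,
        seed=TRAIN_SEED,
    )


@pytest.fixture(scope="session")
def heldout_notes():
    return generate_notes(GenConfig(seed=23, n_patients=15, notes_per_patient=2))
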