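import numpy as np
import pytest

from adr_speech.corpus_io import Token, TokenKind
from adr_speech.synthetic_data import SyntheticConfig, generate_cohort


def word_token(surface, start, end, lemma=None, pos=None):
    return Token(
        kind=TokenKind.WORD, surface=surface, start=start, end=end,
        lemma=lemma, pos=pos,
    )


def pause_token(start, end):
    return Token(kind=TokenKind.PAUSE, surface="", start=start, end=end)


@pytest.fixture(scope="session")
def small_cohort():
    """A small fully synthetic cohort with all class effects at defaults."""
    return generate_cohort(SyntheticConfig(n_train_per_class=6, n_test_per_class=3, seed=42))


@pytest.fixture()
def rng():
    # fresh stream per test: results never depend on test execution order
    return np.random.default_rng(12345)
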