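import numpy as np
import pytest

from speechtrf.lexicon import build_lexicon
from speechtrf.transcript import PhonemeToken, TimeAlignedTranscript, WordToken


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ab_lexicon():
    """The two-word cohort lexicon {AB: 3, AC: 1}."""
    return build_lexicon(
        {"ab": ["A", "B"], "ac": ["A", "C"]},
        {"ab": 3, "ac": 1},
    )


def make_word(orth, phones, t0, dur_each):
    toks = []
    t = t0
    for p in phones:
        toks.append(PhonemeToken(p, t, t + dur_each))
        t += dur_each
    return WordToken(orth, tuple(toks), t0, t)


@pytest.fixture
def ab_transcript():
    """One segment containing the words 'ab' then 'ac'."""
    w1 = make_word("ab", ["A", "B"], 0.5, 0.1)
    w2 = make_word("ac", ["A", "C"], 0.8, 0.1)
    return TimeAlignedTranscript("seg", 2.0, (w1, w2))
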