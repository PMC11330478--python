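"""Envelope chain, impulse channels and the cohort model."""

import numpy as np
import pytest

from speechtrf.features import (
    FEATURE_NAMES,
    FeatureError,
    MODEL_SPECS,
    assemble_features,
    envelope_onsets,
    extract_envelope,
    onset_impulses,
    phoneme_entropy,
    phoneme_surprisal,
    unigram_provider,
    word_frequency,
    word_surprisal,
    FeatureChannel,
)
from speechtrf.lexicon import build_lexicon
from speechtrf.transcript import TimeAlignedTranscript

from .conftest import make_word


# ---------------------------------------------------------------------------
# envelope
# ---------------------------------------------------------------------------


def test_envelope_of_silence_is_zero():
    env = extract_envelope(np.zeros(32000), 16000)
    assert env.values.shape == (256,)
    assert np.max(np.abs(env.values)) < 1e-10


def test_envelope_of_steady_tone_has_no_dc():
    t = np.arange(0, 8.0, 1 / 16000)
    env = extract_envelope(np.sin(2 * np.pi * 1000 * t), 16000)
    # constant amplitude -> flat envelope (DC ~0.6 after compression) is
    # removed by the 0.5 Hz high-pass; only small filter ripple remains
    inner = env.values[256:-256]
    assert np.max(np.abs(inner)) < 0.01


def test_am_tone_envelope_peaks_at_modulation_rate():
    fs = 16000
    t = np.arange(0, 8.0, 1 / fs)
    am = (1 + 0.9 * np.sin(2 * np.pi * 4.0 * t)) * np.sin(2 * np.pi * 1000 * t)
    env = extract_envelope(am, fs)
    spec = np.abs(np.fft.rfft(env.values - env.values.mean()))
    freqs = np.fft.rfftfreq(len(env.values), 1 / 128)
    assert abs(freqs[np.argmax(spec)] - 4.0) < 0.2


@pytest.mark.parametrize("wave,rate,match", [
    (np.zeros((100, 2)), 16000, "mono"),
    (np.zeros(100), 8000, "10 kHz"),
])
def test_envelope_input_validation(wave, rate, match):
    with pytest.raises(FeatureError, match=match):
        extract_envelope(wave, rate)


def test_envelope_onsets_closed_forms():
    # strictly decreasing -> all zeros
    dec = FeatureChannel("envelope", np.linspace(1, 0, 100), "continuous")
    assert np.all(envelope_onsets(dec).values == 0)
    # rising ramp of slope s (per second) -> constant value s
    s = 3.0
    ramp = FeatureChannel("envelope", s * np.arange(100) / 128.0, "continuous")
    out = envelope_onsets(ramp).values
    assert np.allclose(out[1:], s)
    # unit step at sample k -> single impulse of height 128
    step = np.zeros(100)
    step[40:] = 1.0
    out = envelope_onsets(FeatureChannel("envelope", step, "continuous")).values
    assert out[40] == pytest.approx(128.0)
    assert np.count_nonzero(out) == 1


# ---------------------------------------------------------------------------
# impulse channels
# ---------------------------------------------------------------------------


def test_onset_impulses_rounding_and_scaling(caplog):
    ch = onset_impulses([1.0], 45.0)
    assert ch.values[128] == 1.0
    assert np.count_nonzero(ch.values) == 1
    ch = onset_impulses([1.0], 45.0, values=[2.5])
    assert ch.values[128] == 2.5
    with caplog.at_level("WARNING"):
        ch = onset_impulses([1.0, 1.001], 45.0)
    assert ch.values[128] == 2.0  # collision sums
    assert any("collide" in r.message for r in caplog.records)
    with pytest.raises(FeatureError, match="outside"):
        onset_impulses([45.0], 45.0)


# ---------------------------------------------------------------------------
# lexical statistics
# ---------------------------------------------------------------------------


def test_word_frequency_closed_forms():
    lex = build_lexicon({"a": ["x"], "b": ["y"]}, {"a": 3, "b": 1})
    tr = TimeAlignedTranscript(
        "s", 1.0, (make_word("b", ["y"], 0.1, 0.1),)
    )
    assert word_frequency(tr, lex)[0] == pytest.approx(2.0)  # -log2(1/4)
    single = build_lexicon({"a": ["x"]}, {"a": 7})
    tr1 = TimeAlignedTranscript("s", 1.0, (make_word("a", ["x"], 0.1, 0.1),))
    assert word_frequency(tr1, single)[0] == pytest.approx(0.0)


def test_word_surprisal_unigram_equals_frequency(ab_lexicon, ab_transcript):
    ws = word_surprisal(ab_transcript, unigram_provider(ab_lexicon))
    wf = word_frequency(ab_transcript, ab_lexicon)
    assert np.allclose(ws, wf)


def test_word_surprisal_validates_probabilities(ab_transcript):
    assert word_surprisal(ab_transcript, lambda w, c: 1.0)[0] == 0.0
    with pytest.raises(FeatureError):
        word_surprisal(ab_transcript, lambda w, c: 0.0)
    with pytest.raises(FeatureError):
        word_surprisal(ab_transcript, lambda w, c: 1.5)


def test_cohort_surprisal_closed_forms(ab_lexicon, ab_transcript):
    # words: 'ab' (A B), 'ac' (A C); frequencies 3 and 1
    s = phoneme_surprisal(ab_transcript, ab_lexicon)
    # position 1: all words start with A -> P=1 -> 0 bits
    assert s[0] == pytest.approx(0.0)
    # 'ab' position 2: P(B | cohort {ab:3, ac:1}) = 3/4
    assert s[1] == pytest.approx(-np.log2(3 / 4))
    assert s[2] == pytest.approx(0.0)
    # 'ac' position 2: P(C) = 1/4 -> 2 bits
    assert s[3] == pytest.approx(2.0)


def test_cohort_entropy_closed_forms(ab_lexicon, ab_transcript):
    h = phoneme_entropy(ab_transcript, ab_lexicon)
    h0 = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
    # word-initial position: whole-lexicon cohort
    assert h[0] == pytest.approx(h0)
    # after hearing A B, the cohort is {ab} alone -> 0 bits
    assert h[1] == pytest.approx(h0)  # cohort before pos 2 is still {ab, ac}
    # equal-frequency cohort of 8 -> 3 bits
    lex8 = build_lexicon(
        {f"w{i}": [str(i)] for i in range(8)}, {f"w{i}": 5 for i in range(8)}
    )
    tr = TimeAlignedTranscript("s", 1.0, (make_word("w3", ["3"], 0.1, 0.1),))
    assert phoneme_entropy(tr, lex8)[0] == pytest.approx(3.0)
    # frequencies {4,2,1,1} -> 1.75 bits
    lex4 = build_lexicon(
        {"a": ["1"], "b": ["2"], "c": ["3"], "d": ["4"]},
        {"a": 4, "b": 2, "c": 1, "d": 1},
    )
    tr = TimeAlignedTranscript("s", 1.0, (make_word("a", ["1"], 0.1, 0.1),))
    assert phoneme_entropy(tr, lex4)[0] == pytest.approx(1.75)


def test_cohort_strict_vs_lenient_on_unseen_prefix(ab_lexicon):
    """A pronunciation leaving the lexicon errors in strict mode and backs
    off to the uniform phoneme distribution in lenient mode."""
    from speechtrf.features import _cohort_distributions

    with pytest.raises(FeatureError):
        list(_cohort_distributions(("A", "D"), ab_lexicon, strict=True))
    probs = [p for p, _ in _cohort_distributions(("A", "D"), ab_lexicon,
                                                 strict=False)]
    # alphabet {A, B, C}: uniform back-off probability 1/3
    assert probs[1] == pytest.approx(1 / 3)
    # out-of-lexicon transcript words are an error
    tr = TimeAlignedTranscript("s", 1.0, (make_word("zz", ["Z"], 0.1, 0.1),))
    with pytest.raises(FeatureError, match="not in lexicon"):
        phoneme_surprisal(tr, ab_lexicon)


def test_cohort_chain_rule_matches_brute_force(rng):
    """Summed per-phoneme surprisal telescopes to -log2 of the prefix-pooled
    word probability, checked against direct enumeration on random lexicons."""
    alphabet = list("abcdef")
    for trial in range(10):
        n = int(rng.integers(5, 50))
        prons, freqs = {}, {}
        for i in range(n):
            length = int(rng.integers(2, 5))
            prons[f"w{i}"] = [str(rng.choice(alphabet)) for _ in range(length)]
            freqs[f"w{i}"] = int(rng.integers(1, 100))
        lex = build_lexicon(prons, freqs)
        word = f"w{int(rng.integers(0, n))}"
        pron = lex[word].pronunciation
        tr = TimeAlignedTranscript(
            "s", 5.0, (make_word(word, list(pron), 0.1, 0.05),)
        )
        total = sum(e.frequency for e in lex.entries.values())
        # brute force: pool every lexicon word whose pronunciation starts
        # with this word's full pronunciation
        pooled = sum(
            e.frequency
            for e in lex.entries.values()
            if e.pronunciation[: len(pron)] == tuple(pron)
        )
        expected = -np.log2(pooled / total)
        assert phoneme_surprisal(tr, lex).sum() == pytest.approx(expected)


# ---------------------------------------------------------------------------
# model specs and assembly
# ---------------------------------------------------------------------------


def test_model_feature_inventories():
    assert MODEL_SPECS["acoustic"].features_of_interest == ("envelope", "envelope_onsets")
    assert MODEL_SPECS["seg_word"].features_of_interest == ("word_onsets",)
    assert MODEL_SPECS["seg_phoneme"].features_of_interest == ("phoneme_onsets",)
    assert MODEL_SPECS["ling_word"].features_of_interest == ("word_surprisal", "word_frequency")
    assert MODEL_SPECS["ling_phoneme"].features_of_interest == ("phoneme_surprisal", "phoneme_entropy")
    # the segmentation models are not regressed out of each other
    assert "phoneme_onsets" not in MODEL_SPECS["seg_word"].nuisance_features
    assert "word_onsets" not in MODEL_SPECS["seg_phoneme"].nuisance_features
    for spec in MODEL_SPECS.values():
        assert not set(spec.features_of_interest) & set(spec.nuisance_features)


def test_assemble_features_builds_scaled_impulses(ab_lexicon, ab_transcript):
    env = FeatureChannel("envelope", np.zeros(256), "continuous")
    fs = assemble_features(ab_transcript, env, ab_lexicon)
    assert set(fs.channels) == set(FEATURE_NAMES)
    wf = fs.channels["word_frequency"].values
    onset_idx = int(round(0.5 * 128))
    assert wf[onset_idx] == pytest.approx(-np.log2(3 / 4))
    ws = fs.channels["word_surprisal"].values
    assert ws[onset_idx] == pytest.approx(-np.log2(3 / 4))  # unigram default
    wo = fs.channels["word_onsets"].values
    assert wo[onset_idx] == 1.0
    assert np.count_nonzero(wo) == 2
    assert np.count_nonzero(fs.channels["phoneme_onsets"].values) == 4
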