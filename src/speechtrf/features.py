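"""Speech regressors for the five encoding models.

Ten channels in eight names: a continuous gammatone envelope and its
half-wave-rectified derivative (acoustic model), unit impulses at word and
phoneme onsets (segmentation models), and scaled impulses carrying word
surprisal / word frequency and cohort-model phoneme surprisal / entropy
(linguistic models). All channels are sampled at 128 Hz over one segment.

The cohort model: while a word unfolds phoneme by phoneme, the "active
cohort" is the set of lexicon words whose pronunciation starts with the
phonemes heard so far, weighted by corpus frequency. Phoneme surprisal is
-log2 of the frequency-weighted probability of the next phoneme given that
cohort; phoneme entropy is the Shannon entropy over cohort words, indexing
lexical competition. At a word's first phoneme the cohort is the whole
lexicon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from scipy import signal

from .lexicon import PhoneticLexicon
from .transcript import TimeAlignedTranscript

logger = logging.getLogger(__name__)

SAMPLE_RATE = 128
FEATURE_NAMES = (
    "envelope",
    "envelope_onsets",
    "word_onsets",
    "phoneme_onsets",
    "word_surprisal",
    "word_frequency",
    "phoneme_surprisal",
    "phoneme_entropy",
)


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureChannel:
    """One named regressor sampled at 128 Hz."""

    name: str
    values: np.ndarray
    kind: str  # "continuous" | "impulse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.kind not in ("continuous", "impulse"):
            raise FeatureError(f"unknown channel kind {self.kind!r}")


@dataclass(frozen=True)
class SpeechFeatureSet:
    """All channels of one segment; channel lengths must agree."""

    segment_id: str
    channels: Mapping[str, FeatureChannel]
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        lengths = {len(c.values) for c in self.channels.values()}
        if len(lengths) > 1:
            raise FeatureError(f"channel lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())).values)

    def subset(self, names: Sequence[str]) -> "SpeechFeatureSet":
        return SpeechFeatureSet(
            self.segment_id, {n: self.channels[n] for n in names}, self.sample_rate
        )

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        """Stack the named channels into a (n_channels, n_samples) array."""
        return np.stack([self.channels[n].values for n in names])


# ---------------------------------------------------------------------------
# Model specifications: features of interest vs nuisance features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    model_name: str
    features_of_interest: tuple[str, ...]
    nuisance_features: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.features_of_interest) & set(self.nuisance_features):
            raise FeatureError("interest and nuisance feature sets overlap")


_ALL = set(FEATURE_NAMES)
_INTEREST = {
    "acoustic": ("envelope", "envelope_onsets"),
    "seg_word": ("word_onsets",),
    "seg_phoneme": ("phoneme_onsets",),
    "ling_word": ("word_surprisal", "word_frequency"),
    "ling_phoneme": ("phoneme_surprisal", "phoneme_entropy"),
}
# The two segmentation models are not regressed out of each other.
_KEEP = {"seg_word": {"phoneme_onsets"}, "seg_phoneme": {"word_onsets"}}

MODEL_SPECS: dict[str, ModelSpec] = {
    name: ModelSpec(
        model_name=name,
        features_of_interest=interest,
        nuisance_features=tuple(
            f
            for f in FEATURE_NAMES
            if f not in interest and f not in _KEEP.get(name, ())
        ),
    )
    for name, interest in _INTEREST.items()
}
MODEL_NAMES = tuple(MODEL_SPECS)


# ---------------------------------------------------------------------------
# Acoustic channels
# ---------------------------------------------------------------------------


def load_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV file as (float waveform, rate).

    Integer PCM is rescaled to [-1, 1]; stereo input is an error.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise FeatureError(f"{path}: expected mono audio, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), int(rate)


def _butter_filtfilt(x: np.ndarray, cutoff, fs: float, btype: str) -> np.ndarray:
    sos = signal.butter(3, cutoff, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)


def _erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Center frequencies equally spaced on the ERB-number scale."""
    erb = lambda f: 21.4 * np.log10(4.37 * f / 1000.0 + 1.0)
    erb_inv = lambda e: (10 ** (e / 21.4) - 1.0) * 1000.0 / 4.37
    return erb_inv(np.linspace(erb(f_lo), erb(f_hi), n))


def extract_envelope(
    waveform: np.ndarray,
    rate: float,
    duration: float | None = None,
    *,
    n_bands: int = 28,
    f_lo: float = 50.0,
    f_hi: float = 5000.0,
    compression: float = 0.3,
) -> FeatureChannel:
    """Gammatone-filterbank speech envelope at 128 Hz.

    Chain: downsample to 15 kHz (anti-alias low-pass at 5 kHz) -> 28-channel
    gammatone filterbank, 50-5000 Hz on the ERB scale -> per-channel half-wave
    rectification and power-law compression (exponent 0.3) -> average across
    channels -> downsample to 128 Hz (anti-alias at 42.7 Hz) -> band-pass
    0.5-25 Hz (order-3 Butterworth, forward-backward) -> truncate or zero-pad
    to ``duration`` seconds.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise FeatureError("waveform must be mono (1-D)")
    if rate < 10_000:
        raise FeatureError(f"sampling rate {rate} Hz < 10 kHz")
    fs_mid = 15_000.0
    x = _butter_filtfilt(waveform, fs_mid / 3.0, rate, "lowpass")
    x = _resample(x, rate, fs_mid)

    env = np.zeros_like(x)
    for cf in _erb_space(f_lo, f_hi, n_bands):
        b, a = signal.gammatone(cf, "iir", fs=fs_mid)
        band = signal.lfilter(b, a, x)
        env += np.maximum(band, 0.0) ** compression
    env /= n_bands

    env = _butter_filtfilt(env, SAMPLE_RATE / 3.0, fs_mid, "lowpass")
    env = _resample(env, fs_mid, SAMPLE_RATE)
    env = _butter_filtfilt(env, (0.5, 25.0), SAMPLE_RATE, "bandpass")

    if duration is None:
        duration = len(waveform) / rate
    n_out = int(round(duration * SAMPLE_RATE))
    if len(env) >= n_out:
        env = env[:n_out]
    else:
        env = np.pad(env, (0, n_out - len(env)))
    return FeatureChannel("envelope", env, "continuous")


def envelope_onsets(envelope: FeatureChannel) -> FeatureChannel:
    """Half-wave rectified derivative of the envelope (acoustic edges)."""
    v = envelope.values
    d = np.zeros_like(v)
    d[1:] = np.diff(v) * SAMPLE_RATE
    return FeatureChannel("envelope_onsets", np.maximum(d, 0.0), "continuous")


# ---------------------------------------------------------------------------
# Event (impulse) channels
# ---------------------------------------------------------------------------


def onset_impulses(
    times: Sequence[float],
    duration: float,
    values: Sequence[float] | None = None,
    *,
    name: str = "onsets",
) -> FeatureChannel:
    """Impulse train: value 1 (or per-event scalars) at the nearest sample.

    Events that round to the same sample sum, with a warning.
    """
    n = int(round(duration * SAMPLE_RATE))
    out = np.zeros(n)
    if values is None:
        values = np.ones(len(times))
    if len(values) != len(times):
        raise FeatureError("values and event times differ in length")
    seen: set[int] = set()
    for t, v in zip(times, values):
        if not 0.0 <= t < duration:
            raise FeatureError(f"event time {t} s outside [0, {duration}) s")
        idx = min(int(round(t * SAMPLE_RATE)), n - 1)
        if idx in seen:
            logger.warning("two events collide on sample %d; values summed", idx)
        seen.add(idx)
        out[idx] += v
    return FeatureChannel(name, out, "impulse")


# ---------------------------------------------------------------------------
# Lexical statistics
# ---------------------------------------------------------------------------


class SurprisalProvider(Protocol):
    """Left-context word predictor: P(word | preceding words) in (0, 1]."""

    def __call__(self, word: str, context: Sequence[str]) -> float: ...


def unigram_provider(lexicon: PhoneticLexicon) -> Callable[[str, Sequence[str]], float]:
    """Context-free provider: P(word) = relative corpus frequency."""

    def p(word: str, context: Sequence[str]) -> float:
        return lexicon.relative_frequency(word)

    return p


def word_frequency(
    transcript: TimeAlignedTranscript, lexicon: PhoneticLexicon
) -> np.ndarray:
    """-log2 relative unigram frequency per word (high frequency -> low value)."""
    out = []
    for w in transcript.words:
        if w.orthography not in lexicon:
            raise FeatureError(f"word {w.orthography!r} not in lexicon")
        out.append(-np.log2(lexicon.relative_frequency(w.orthography)))
    return np.asarray(out)


def word_surprisal(
    transcript: TimeAlignedTranscript, provider: SurprisalProvider
) -> np.ndarray:
    """-log2 P(word | left context) per word, from a pluggable provider."""
    out = []
    context: list[str] = []
    for w in transcript.words:
        p = provider(w.orthography, tuple(context))
        if not 0.0 < p <= 1.0:
            raise FeatureError(
                f"provider probability {p} for {w.orthography!r} outside (0, 1]"
            )
        out.append(-np.log2(p))
        context.append(w.orthography)
    return np.asarray(out)


def _cohort_distributions(
    pronunciation: Sequence[str], lexicon: PhoneticLexicon, *, strict: bool
):
    """Yield (P(phoneme_k | cohort), cohort word->frequency) per position k.

    The cohort before position k holds the lexicon words whose pronunciation
    starts with the word's first k-1 phonemes; at k=1 it is the whole lexicon.
    """
    entries = list(lexicon.entries.values())
    alphabet_size = len(lexicon.phoneme_alphabet)
    for k, phoneme in enumerate(pronunciation):
        prefix = tuple(pronunciation[:k])
        cohort = [e for e in entries if tuple(e.pronunciation[:k]) == prefix]
        total = sum(e.frequency for e in cohort)
        if total == 0:
            if strict:
                raise FeatureError(
                    f"empty cohort for prefix {prefix!r} + {phoneme!r}"
                )
            logger.warning(
                "empty cohort for prefix %r; backing off to uniform", prefix
            )
            yield 1.0 / alphabet_size, {}
            continue
        match = sum(
            e.frequency
            for e in cohort
            if len(e.pronunciation) > k and e.pronunciation[k] == phoneme
        )
        if match == 0:
            if strict:
                raise FeatureError(
                    f"phoneme {phoneme!r} unseen after prefix {prefix!r}"
                )
            logger.warning(
                "zero-probability continuation %r after %r; uniform back-off",
                phoneme, prefix,
            )
            yield 1.0 / alphabet_size, {}
            continue
        yield match / total, {e.word: e.frequency for e in cohort}


def _word_cohort_values(
    pron: tuple[str, ...], lexicon: PhoneticLexicon, strict: bool
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """(surprisal, entropy) sequences for one pronunciation, memoized per
    lexicon (the same words recur throughout a transcript)."""
    cache = lexicon.__dict__.setdefault("_cohort_cache", {})
    key = (pron, strict)
    if key in cache:
        return cache[key]
    surps, ents = [], []
    for p, cohort in _cohort_distributions(pron, lexicon, strict=strict):
        surps.append(float(-np.log2(p)))
        if not cohort:
            ents.append(0.0)
            continue
        freqs = np.array(list(cohort.values()), dtype=float)
        q = freqs / freqs.sum()
        ents.append(float(-(q * np.log2(q)).sum()))
    cache[key] = (tuple(surps), tuple(ents))
    return cache[key]


def phoneme_surprisal(
    transcript: TimeAlignedTranscript,
    lexicon: PhoneticLexicon,
    *,
    strict: bool = True,
) -> np.ndarray:
    """Cohort-model surprisal, -log2 P(phoneme | active cohort), per phoneme."""
    out = []
    for w in transcript.words:
        pron = _pronunciation_for(w, lexicon)
        out.extend(_word_cohort_values(pron, lexicon, strict)[0])
    return np.asarray(out)


def phoneme_entropy(
    transcript: TimeAlignedTranscript,
    lexicon: PhoneticLexicon,
    *,
    strict: bool = True,
) -> np.ndarray:
    """Shannon entropy (bits) over frequency-weighted words of the cohort."""
    out = []
    for w in transcript.words:
        pron = _pronunciation_for(w, lexicon)
        out.extend(_word_cohort_values(pron, lexicon, strict)[1])
    return np.asarray(out)


def _pronunciation_for(word, lexicon: PhoneticLexicon) -> tuple[str, ...]:
    if word.orthography not in lexicon:
        raise FeatureError(f"word {word.orthography!r} not in lexicon")
    pron = lexicon[word.orthography].pronunciation
    if len(pron) != len(word.phonemes):
        raise FeatureError(
            f"word {word.orthography!r}: transcript has {len(word.phonemes)} "
            f"phonemes but lexicon pronunciation has {len(pron)}"
        )
    return pron


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_features(
    transcript: TimeAlignedTranscript,
    envelope_channel: FeatureChannel,
    lexicon: PhoneticLexicon,
    *,
    surprisal: SurprisalProvider | None = None,
    strict_cohort: bool = True,
) -> SpeechFeatureSet:
    """Build all eight channels for one segment.

    Impulse channels place unit (segmentation) or scalar-scaled (linguistic)
    impulses at word/phoneme onsets; the word-surprisal provider defaults to
    the bundled unigram model.
    """
    dur = transcript.duration
    n = int(round(dur * SAMPLE_RATE))
    env = envelope_channel.values
    if len(env) != n:
        raise FeatureError(
            f"envelope length {len(env)} != segment samples {n}"
        )
    provider = surprisal or unigram_provider(lexicon)
    w_on = transcript.word_onsets
    p_on = transcript.phoneme_onsets
    channels = {
        "envelope": FeatureChannel("envelope", env, "continuous"),
        "envelope_onsets": envelope_onsets(envelope_channel),
        "word_onsets": onset_impulses(w_on, dur, name="word_onsets"),
        "phoneme_onsets": onset_impulses(p_on, dur, name="phoneme_onsets"),
        "word_surprisal": onset_impulses(
            w_on, dur, word_surprisal(transcript, provider), name="word_surprisal"
        ),
        "word_frequency": onset_impulses(
            w_on, dur, word_frequency(transcript, lexicon), name="word_frequency"
        ),
        "phoneme_surprisal": onset_impulses(
            p_on, dur, phoneme_surprisal(transcript, lexicon, strict=strict_cohort),
            name="phoneme_surprisal",
        ),
        "phoneme_entropy": onset_impulses(
            p_on, dur, phoneme_entropy(transcript, lexicon, strict=strict_cohort),
            name="phoneme_entropy",
        ),
    }
    return SpeechFeatureSet(transcript.segment_id, channels)
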