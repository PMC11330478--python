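"""Synthetic cohort: lexicon, transcripts, regressors and simulated EEG.

The generator emulates the structure of a natural-listening EEG study: 44
older participants (25 with normal and 19 with low cognitive-screening
scores, a pure-tone-average hearing covariate), 25 audiobook segments of
45 s sampled at 128 Hz, and nine midline electrodes. EEG is built by the
same forward model the analysis assumes,

    EEG_e(t) = sum_f w_{f,e} * g_{p,f} * (k_f (*) x_f^z)(t) + noise,

with smooth ground-truth kernels k_f on the -200..600 ms lag axis, spatial
weights w, an optional participant gain g on the word-onset kernel
(1 + group_effect * [low group] + pta_effect * PTA_z) emulating a
hearing-dependent word-segmentation response, and 1/f ("pink") noise
band-passed to 0.5-25 Hz scaled to a configured signal-to-noise variance
ratio in that band. Everything is a pure function of the configuration,
including its master seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .features import (
    FeatureChannel,
    SAMPLE_RATE,
    SpeechFeatureSet,
    assemble_features,
)
from .design import LAG_MS, N_LAGS
from .lexicon import LexiconEntry, PhoneticLexicon
from .transcript import PhonemeToken, TimeAlignedTranscript, WordToken


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration and metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    moca_score: int
    pta: float  # dB HL, four-frequency average
    age: float

    def __post_init__(self) -> None:
        if not 0 <= self.moca_score <= 30:
            raise SyntheticError(f"MoCA score {self.moca_score} outside 0-30")
        if self.pta < 0:
            raise SyntheticError("PTA must be >= 0 dB HL")

    @property
    def moca_group(self) -> str:
        """'low' below the clinical cutoff of 26, else 'normal'."""
        return "low" if self.moca_score < 26 else "normal"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: 44 participants (25/19), 25 x 45 s segments."""

    n_participants: int = 44
    n_low: int = 19
    n_segments: int = 25
    segment_duration: float = 45.0
    sample_rate: int = SAMPLE_RATE
    n_electrodes: int = 9
    snr: float = 10.0
    pta_effect: float = -0.3
    group_effect: float = 0.0
    master_seed: int = 0
    n_words: int = 500
    alphabet_size: int = 20
    zipf_exponent: float = 1.5
    phoneme_dur_median: float = 0.08
    phoneme_dur_sigma: float = 0.4
    surprisal_context_sd: float = 3.0  # bits of contextual surprisal jitter

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_segments, self.n_electrodes) < 1:
            raise SyntheticError("counts must be positive")
        if not 0 < self.n_low < self.n_participants:
            raise SyntheticError("n_low must be within (0, n_participants)")
        if self.sample_rate != SAMPLE_RATE:
            raise SyntheticError(f"sample rate fixed at {SAMPLE_RATE} Hz")
        n = self.segment_duration * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise SyntheticError("segment_duration x sample_rate must be integral")

    @property
    def n_samples(self) -> int:
        return int(round(self.segment_duration * self.sample_rate))


ELECTRODES_9 = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")


def electrode_labels(n: int) -> tuple[str, ...]:
    if n <= len(ELECTRODES_9):
        return ELECTRODES_9[:n]
    return ELECTRODES_9 + tuple(f"X{i}" for i in range(n - len(ELECTRODES_9)))


# ---------------------------------------------------------------------------
# Lexicon and transcripts
# ---------------------------------------------------------------------------


def make_lexicon(
    n_words: int = 500,
    alphabet_size: int = 20,
    zipf_exponent: float = 1.5,
    seed: int | np.random.SeedSequence = 0,
) -> PhoneticLexicon:
    """Random lexicon: geometric-length pronunciations, Zipf frequencies.

    Ranked frequencies follow ``round(1000 / rank**s)`` floored at 1; a zero
    exponent gives equal frequencies.
    """
    if n_words < 2:
        raise SyntheticError("need at least 2 words")
    if alphabet_size < 2:
        raise SyntheticError("need at least 2 phonemes")
    rng = np.random.default_rng(seed)
    letters = list(string.ascii_lowercase)
    alphabet = [
        letters[i] if i < 26 else f"q{i}" for i in range(alphabet_size)
    ]
    entries: dict[str, LexiconEntry] = {}
    rank = 1
    while len(entries) < n_words:
        length = 2 + rng.geometric(0.4) - 1  # min 2, mean 3.5 phonemes
        pron = tuple(rng.choice(alphabet) for _ in range(length))
        word = "".join(pron)
        if word in entries:
            continue
        freq = max(1, int(round(1000.0 / rank**zipf_exponent)))
        entries[word] = LexiconEntry(word, pron, freq)
        rank += 1
    return PhoneticLexicon(entries=entries)


def make_transcripts(
    lexicon: PhoneticLexicon,
    n_segments: int,
    duration: float,
    seed: int | np.random.SeedSequence = 0,
    *,
    phoneme_dur_median: float = 0.08,
    phoneme_dur_sigma: float = 0.4,
    initial_silence: float = 0.467,
) -> list[TimeAlignedTranscript]:
    """Sample word sequences frequency-proportionally and lay them out in time.

    Phoneme durations are log-normal (median ~80 ms); short inter-word gaps
    plus occasional pauses keep segments >= 90% filled with speech. Each
    segment opens with ~467 ms of silence, mirroring the stimulus-onset
    jitter of audiobook segments.
    """
    if duration <= 1.0:
        raise SyntheticError("segment duration must exceed 1 s")
    rng = np.random.default_rng(seed)
    words = list(lexicon.entries.values())
    probs = np.array([e.frequency for e in words], dtype=float)
    probs /= probs.sum()
    out = []
    for s in range(n_segments):
        t = initial_silence
        toks: list[WordToken] = []
        while True:
            entry = words[rng.choice(len(words), p=probs)]
            durs = rng.lognormal(np.log(phoneme_dur_median), phoneme_dur_sigma,
                                 size=len(entry.pronunciation))
            if t + durs.sum() > duration:
                break
            phs = []
            pt = t
            for lab, d in zip(entry.pronunciation, durs):
                phs.append(PhonemeToken(lab, pt, pt + d))
                pt += d
            toks.append(WordToken(entry.word, tuple(phs), t, pt))
            gap = rng.exponential(0.008)
            if rng.random() < 0.06:
                gap += 0.18  # occasional sentence-like pause
            t = pt + gap
        out.append(
            TimeAlignedTranscript(segment_id=f"seg{s:02d}", duration=duration,
                                  words=tuple(toks))
        )
    return out


# ---------------------------------------------------------------------------
# Ground-truth kernels and EEG synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroundTruthKernelSet:
    """Per-feature lag kernels and per-electrode spatial weights."""

    kernels: Mapping[str, np.ndarray]  # feature -> (103,) lag kernel
    spatial: Mapping[str, np.ndarray]  # feature -> (n_electrodes,) weights

    def __post_init__(self) -> None:
        for name, k in self.kernels.items():
            if len(k) != N_LAGS:
                raise SyntheticError(
                    f"kernel {name!r} has {len(k)} lags, expected {N_LAGS} "
                    "(support must lie within the -200..600 ms axis)"
                )
            if not np.all(np.isfinite(k)):
                raise SyntheticError(f"kernel {name!r} has non-finite values")

    def scaled(self, feature: str, gain: float) -> "GroundTruthKernelSet":
        kernels = dict(self.kernels)
        kernels[feature] = kernels[feature] * gain
        return GroundTruthKernelSet(kernels=kernels, spatial=self.spatial)


def _gauss(mu_ms: float, sd_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((LAG_MS - mu_ms) / sd_ms) ** 2)


_CLUSTER_WEIGHTS = {
    # (frontal, central, parietal) emphasis per feature
    "envelope": (1.0, 0.8, 0.5),
    "envelope_onsets": (1.0, 0.8, 0.5),
    "word_onsets": (0.8, 1.0, 0.6),
    "phoneme_onsets": (0.8, 1.0, 0.6),
    "word_surprisal": (0.8, 1.0, 0.6),
    "word_frequency": (0.8, 1.0, 0.6),
    "phoneme_surprisal": (0.8, 1.0, 0.6),
    "phoneme_entropy": (0.8, 1.0, 0.6),
}


def default_truth(n_electrodes: int = 9) -> GroundTruthKernelSet:
    """Smooth, plausible response shapes: a P1-N1-P2 chain for the acoustic
    features, early peaks for segmentation, N400-like deflections for the
    lexical features. Amplitudes make the acoustic model the strongest, as
    in natural speech data."""
    kernels = {
        "envelope": 1.0 * _gauss(50, 30) - 0.7 * _gauss(120, 40) + 0.5 * _gauss(220, 60),
        "envelope_onsets": 0.8 * _gauss(60, 25) - 0.5 * _gauss(140, 40),
        "word_onsets": 1.5 * _gauss(100, 40) - 1.2 * _gauss(400, 80),
        "phoneme_onsets": 0.5 * _gauss(40, 30) - 0.3 * _gauss(250, 70),
        "word_surprisal": 0.2 * _gauss(150, 50) - 0.4 * _gauss(400, 80),
        "word_frequency": -0.25 * _gauss(350, 80),
        "phoneme_surprisal": 0.3 * _gauss(120, 50) - 0.2 * _gauss(300, 80),
        "phoneme_entropy": 0.2 * _gauss(180, 60),
    }
    spatial = {}
    for name, (wf, wc, wp) in _CLUSTER_WEIGHTS.items():
        full = np.array([0.95 * wf, wf, 0.95 * wf,
                         0.95 * wc, wc, 0.95 * wc,
                         0.95 * wp, wp, 0.95 * wp])
        if n_electrodes <= 9:
            spatial[name] = full[:n_electrodes]
        else:
            spatial[name] = np.resize(full, n_electrodes)
    return GroundTruthKernelSet(kernels=kernels, spatial=spatial)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise band-passed to 0.5-25 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLE_RATE)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * scale, n)
    sos = signal.butter(3, (0.5, 25.0), btype="bandpass", fs=SAMPLE_RATE,
                        output="sos")
    x = signal.sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _convolve_lagged(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """y(t) = sum_tau k(tau) x(t - tau) over the -26..76 sample lag axis."""
    full = signal.fftconvolve(x, kernel)
    lo = -int(np.round(LAG_MS[0] / 1000 * SAMPLE_RATE))  # 26
    return full[lo : lo + len(x)]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_eeg(
    feature_sets: Sequence[SpeechFeatureSet],
    truth: GroundTruthKernelSet,
    config: SyntheticConfig,
    *,
    seed: int | np.random.SeedSequence = 0,
    snr: float | None = None,
) -> np.ndarray:
    """Forward-simulate one participant's EEG, (segments, electrodes, samples).

    Per electrode, the noise-free signal is the sum over features of the
    lag-axis convolution of the z-scored regressor with the feature kernel,
    scaled by the spatial weight; pink noise is added at the configured
    signal-to-noise variance ratio measured in the 0.5-25 Hz band (pooled
    over segments). With zero kernels the noise has unit variance.
    """
    snr = config.snr if snr is None else snr
    S = len(feature_sets)
    E = config.n_electrodes
    T = feature_sets[0].n_samples
    sig = np.zeros((S, E, T))
    for s, fs in enumerate(feature_sets):
        for name, kernel in truth.kernels.items():
            if name not in fs.channels:
                continue
            w = truth.spatial[name]
            if len(w) != E:
                raise SyntheticError("spatial weights do not match n_electrodes")
            y = _convolve_lagged(_zscore(fs.channels[name].values), kernel)
            sig[s] += w[:, None] * y[None, :]

    sos = signal.butter(3, (0.5, 25.0), btype="bandpass", fs=SAMPLE_RATE,
                        output="sos")
    band = signal.sosfiltfilt(sos, sig, axis=-1)
    var_sig = band.var(axis=(0, 2))  # per electrode, pooled over segments

    eeg = sig.copy()
    if np.isfinite(snr):
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        seg_seeds = ss.spawn(S)
        noise_scale = np.where(var_sig > 0, np.sqrt(var_sig / snr), 1.0)
        for s in range(S):
            rng = np.random.default_rng(seg_seeds[s])
            for e in range(E):
                eeg[s, e] += noise_scale[e] * _pink_noise(T, rng)
    return eeg


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    participants: list[ParticipantMeta]
    lexicon: PhoneticLexicon
    transcripts: list[TimeAlignedTranscript]
    feature_sets: list[SpeechFeatureSet]
    eeg: np.ndarray  # (participants, segments, electrodes, samples)
    truth_base: GroundTruthKernelSet
    word_onset_gains: np.ndarray  # (participants,)

    @property
    def electrodes(self) -> tuple[str, ...]:
        return electrode_labels(self.config.n_electrodes)

    @property
    def pta_z(self) -> np.ndarray:
        pta = np.array([p.pta for p in self.participants])
        return (pta - pta.mean()) / pta.std()

    def truth_for(self, i: int) -> GroundTruthKernelSet:
        return self.truth_base.scaled("word_onsets", float(self.word_onset_gains[i]))

    @property
    def truth(self) -> list[GroundTruthKernelSet]:
        return [self.truth_for(i) for i in range(len(self.participants))]


def make_participants(
    config: SyntheticConfig, seed: int | np.random.SeedSequence
) -> list[ParticipantMeta]:
    """MoCA scores around the 26-point cutoff, ages in the late 60s/early
    70s, and a truncated-normal PTA (mean 20, sd 12 dB HL) shared by both
    groups, matching the cohort the generator emulates."""
    rng = np.random.default_rng(seed)
    n_normal = config.n_participants - config.n_low
    out = []
    for i in range(config.n_participants):
        low = i >= n_normal
        moca = int(rng.integers(20, 26)) if low else int(rng.integers(26, 31))
        age = float(np.clip(rng.normal(71.7 if low else 68.6, 6.0), 60, 85))
        pta = float(max(0.0, rng.normal(20.0, 12.0)))
        out.append(ParticipantMeta(f"p{i:02d}", moca, pta, age))
    return out


def synthetic_envelope(
    n_samples: int, rng: np.random.Generator
) -> FeatureChannel:
    """Synthetic envelope: modulation-rich noise band-limited to 0.5-25 Hz.

    A flat in-band spectrum keeps the lagged envelope design well
    conditioned (real speech envelopes carry modulation energy across the
    whole band the analysis uses); the channel is unit-variance.
    """
    sos = signal.butter(3, (0.5, 25.0), btype="bandpass", fs=SAMPLE_RATE,
                        output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return FeatureChannel("envelope", x / sd if sd > 0 else x, "continuous")


def contextual_provider(lexicon: PhoneticLexicon, rng: np.random.Generator,
                        sd_bits: float = 3.0):
    """Surprisal provider emulating a contextual language model.

    Real word surprisal (e.g. from a masked language model) correlates with
    unigram frequency but carries substantial context-driven variance; here
    each token's probability is its relative frequency attenuated by a
    half-normal number of extra bits, which decorrelates the word-surprisal
    channel from the word-frequency channel as in natural text.
    """

    def p(word: str, context) -> float:
        extra = abs(rng.normal(0.0, sd_bits))
        return lexicon.relative_frequency(word) * 2.0**-extra

    return p


def make_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic cohort deterministically from the config."""
    config = config or SyntheticConfig()
    root = np.random.SeedSequence(config.master_seed)
    lex_ss, trans_ss, env_ss, meta_ss, eeg_ss, surp_ss = root.spawn(6)

    lexicon = make_lexicon(config.n_words, config.alphabet_size,
                           config.zipf_exponent, lex_ss)
    transcripts = make_transcripts(
        lexicon, config.n_segments, config.segment_duration, trans_ss,
        phoneme_dur_median=config.phoneme_dur_median,
        phoneme_dur_sigma=config.phoneme_dur_sigma,
    )
    env_rng = np.random.default_rng(env_ss)
    provider = contextual_provider(lexicon, np.random.default_rng(surp_ss),
                                   config.surprisal_context_sd)
    feature_sets = [
        assemble_features(tr, synthetic_envelope(config.n_samples, env_rng),
                          lexicon, surprisal=provider)
        for tr in transcripts
    ]
    participants = make_participants(config, meta_ss)
    pta = np.array([p.pta for p in participants])
    pta_z = (pta - pta.mean()) / pta.std()
    gains = np.array([
        1.0
        + config.group_effect * (p.moca_group == "low")
        + config.pta_effect * z
        for p, z in zip(participants, pta_z)
    ])

    truth = default_truth(config.n_electrodes)
    part_seeds = eeg_ss.spawn(config.n_participants)
    eeg = np.empty((config.n_participants, config.n_segments,
                    config.n_electrodes, config.n_samples))
    for i in range(config.n_participants):
        eeg[i] = simulate_eeg(
            feature_sets, truth.scaled("word_onsets", float(gains[i])),
            config, seed=part_seeds[i],
        )
    return SyntheticDataset(
        config=config,
        participants=participants,
        lexicon=lexicon,
        transcripts=transcripts,
        feature_sets=feature_sets,
        eeg=eeg,
        truth_base=truth,
        word_onset_gains=gains,
    )
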