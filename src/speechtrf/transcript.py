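"""Time-aligned transcripts and Praat TextGrid input/output.

A transcript is an ordered sequence of word tokens, each carrying the ordered
phoneme tokens produced by a forced aligner (word tier + phone tier of a Praat
TextGrid). Intervals whose label is empty or in the silence set are not words.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Labels conventionally used by forced aligners for non-speech intervals.
SILENCE_LABELS = frozenset({"", "sil", "sp", "spn"})

#: Nesting tolerance for phone-inside-word checks: half a sample at 128 Hz.
NESTING_TOLERANCE_S = 0.5 / 128.0


class TranscriptError(ValueError):
    """Raised when alignment intervals violate transcript invariants."""


@dataclass(frozen=True)
class PhonemeToken:
    """One aligned phoneme: symbol plus [onset, offset) in seconds."""

    label: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.label:
            raise TranscriptError("phoneme label must be non-empty")
        if not self.offset > self.onset:
            raise TranscriptError(
                f"phoneme {self.label!r}: offset {self.offset} <= onset {self.onset}"
            )


@dataclass(frozen=True)
class WordToken:
    """One aligned word with its ordered, non-overlapping phonemes."""

    orthography: str
    phonemes: tuple[PhonemeToken, ...]
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.phonemes:
            raise TranscriptError(f"word {self.orthography!r} has no phonemes")
        tol = NESTING_TOLERANCE_S
        prev_off = None
        for ph in self.phonemes:
            if ph.onset < self.onset - tol or ph.offset > self.offset + tol:
                raise TranscriptError(
                    f"phone {ph.label!r} [{ph.onset}, {ph.offset}] outside word "
                    f"{self.orthography!r} [{self.onset}, {self.offset}]"
                )
            if prev_off is not None and ph.onset < prev_off - tol:
                raise TranscriptError(
                    f"phones overlap within word {self.orthography!r}"
                )
            prev_off = ph.offset


@dataclass(frozen=True)
class TimeAlignedTranscript:
    """Ordered words of one audiobook segment, with duration in seconds."""

    segment_id: str
    duration: float
    words: tuple[WordToken, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        tol = NESTING_TOLERANCE_S
        prev_off = None
        for w in self.words:
            if prev_off is not None and w.onset < prev_off - tol:
                raise TranscriptError(f"words overlap at {w.orthography!r}")
            if w.offset > self.duration + tol:
                raise TranscriptError(
                    f"word {w.orthography!r} ends at {w.offset} s, beyond the "
                    f"segment duration {self.duration} s"
                )
            prev_off = w.offset

    @property
    def word_onsets(self) -> list[float]:
        return [w.onset for w in self.words]

    @property
    def phoneme_onsets(self) -> list[float]:
        return [p.onset for w in self.words for p in w.phonemes]


# ---------------------------------------------------------------------------
# Praat TextGrid parsing (long and short text formats)
# ---------------------------------------------------------------------------


def _read_text(path: str | Path) -> str:
    raw = Path(path).read_bytes()
    for enc in ("utf-8-sig", "utf-16"):
        try:
            return raw.decode(enc)
        except UnicodeDecodeError:
            continue
    return raw.decode("latin-1")


def _parse_textgrid_tiers(text: str) -> dict[str, list[tuple[float, float, str]]]:
    """Parse interval tiers out of a TextGrid in either text format.

    Both formats list, per interval tier, the tier name followed by
    (xmin, xmax, label) triples; the long format decorates them with
    ``key =`` prefixes which we simply strip.
    """
    # Tokenize line-wise into quoted strings and numbers; the long format's
    # `key =` decorations and `intervals [i]:` headers are stripped so both
    # formats reduce to the same token stream.
    tokens: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        # drop long-format decorations: "xmin = 0.5", "text = \"ab\"", headers
        if "=" in line:
            line = line.split("=", 1)[1].strip()
        if line.startswith(("File type", "Object class")):
            continue
        if re.fullmatch(r"(item|intervals|points)\s*\[\d*\]:?", line):
            continue
        for m in re.finditer(r'"(?:[^"]|"")*"|-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?', line):
            tok = m.group(0)
            if tok.startswith('"'):
                tokens.append(("s", tok[1:-1].replace('""', '"')))
            else:
                tokens.append(("n", tok))

    it = iter(tokens)

    def need(kind: str) -> str:
        for k, v in it:
            if k == kind:
                return v
        raise TranscriptError("truncated TextGrid file")

    tg_type = need("s")
    if tg_type != "ooTextFile":
        raise TranscriptError(f"not a TextGrid file (File type {tg_type!r})")
    obj = need("s")
    if obj != "TextGrid":
        raise TranscriptError(f"not a TextGrid file (Object class {obj!r})")
    float(need("n"))  # xmin
    float(need("n"))  # xmax
    # long format: a string "<exists>" flag may appear before the tier count
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    n_tiers = None
    for k, v in it:
        if k == "n":
            n_tiers = int(float(v))
            break
    if n_tiers is None:
        raise TranscriptError("TextGrid lists no tiers")
    for _ in range(n_tiers):
        tier_class = need("s")
        tier_name = need("s")
        float(need("n"))  # tier xmin
        float(need("n"))  # tier xmax
        n_items = int(float(need("n")))
        items = []
        if tier_class == "IntervalTier":
            for _ in range(n_items):
                x0 = float(need("n"))
                x1 = float(need("n"))
                lab = need("s")
                items.append((x0, x1, lab))
            tiers[tier_name] = items
        elif tier_class == "TextTier":
            for _ in range(n_items):
                float(need("n"))
                need("s")
        else:
            raise TranscriptError(f"unknown tier class {tier_class!r}")
    return tiers


def read_textgrid(
    path: str | Path,
    word_tier: str = "words",
    phone_tier: str = "phones",
    *,
    segment_id: str | None = None,
    silence_labels: Iterable[str] = SILENCE_LABELS,
) -> TimeAlignedTranscript:
    """Read a forced-alignment TextGrid into a :class:`TimeAlignedTranscript`.

    Empty-labelled intervals and labels in ``silence_labels`` are dropped.
    Phone intervals must nest inside their word interval within half a sample
    at 128 Hz; a phone crossing a word boundary beyond that raises.
    """
    path = Path(path)
    tiers = _parse_textgrid_tiers(_read_text(path))
    for name in (word_tier, phone_tier):
        if name not in tiers:
            raise TranscriptError(
                f"tier {name!r} not found in {path.name} (has {sorted(tiers)})"
            )
    silence = {s.lower() for s in silence_labels}
    tol = NESTING_TOLERANCE_S

    phones = [
        (x0, x1, lab)
        for x0, x1, lab in tiers[phone_tier]
        if lab.strip().lower() not in silence
    ]
    duration = max((x1 for _, x1, _ in tiers[word_tier]), default=0.0)
    words: list[WordToken] = []
    for x0, x1, lab in tiers[word_tier]:
        if lab.strip().lower() in silence:
            continue
        inside: list[PhonemeToken] = []
        for p0, p1, plab in phones:
            if p1 <= x0 + tol or p0 >= x1 - tol:
                continue  # outside this word
            if p0 < x0 - tol or p1 > x1 + tol:
                raise TranscriptError(
                    f"phone {plab!r} [{p0}, {p1}] crosses the boundary of word "
                    f"{lab!r} [{x0}, {x1}]"
                )
            inside.append(PhonemeToken(plab, p0, p1))
        words.append(WordToken(lab, tuple(inside), x0, x1))
    return TimeAlignedTranscript(
        segment_id=segment_id or path.stem, duration=duration, words=tuple(words)
    )


def write_textgrid(
    transcript: TimeAlignedTranscript,
    path: str | Path,
    word_tier: str = "words",
    phone_tier: str = "phones",
) -> None:
    """Write a transcript as a long-format TextGrid (round-trips with reader)."""

    def esc(s: str) -> str:
        return s.replace('"', '""')

    words = transcript.words
    phones = [p for w in words for p in w.phonemes]

    def tier_block(name: str, items: Sequence[tuple[float, float, str]]) -> list[str]:
        # fill gaps with empty (silence) intervals so the tier is contiguous
        full: list[tuple[float, float, str]] = []
        t = 0.0
        for x0, x1, lab in items:
            if x0 > t + 1e-9:
                full.append((t, x0, ""))
            full.append((x0, x1, lab))
            t = x1
        if t < transcript.duration - 1e-9:
            full.append((t, transcript.duration, ""))
        out = [
            '        class = "IntervalTier"',
            f'        name = "{esc(name)}"',
            "        xmin = 0",
            f"        xmax = {transcript.duration:.10g}",
            f"        intervals: size = {len(full)}",
        ]
        for i, (x0, x1, lab) in enumerate(full, 1):
            out += [
                f"        intervals [{i}]:",
                f"            xmin = {x0:.10g}",
                f"            xmax = {x1:.10g}",
                f'            text = "{esc(lab)}"',
            ]
        return out

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {transcript.duration:.10g}",
        "tiers? <exists>",
        "size = 2",
        "item []:",
        "    item [1]:",
        *tier_block(word_tier, [(w.onset, w.offset, w.orthography) for w in words]),
        "    item [2]:",
        *tier_block(phone_tier, [(p.onset, p.offset, p.label) for p in phones]),
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
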