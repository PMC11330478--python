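"""Phonetic lexicon: pronunciations merged with corpus unigram frequencies.

The lexicon is the substrate of the cohort model: each entry pairs a
case-folded orthographic word with one pronunciation (ordered phoneme symbols)
and a positive corpus frequency. Pronunciations come from an MFA-style
dictionary (one ``word phone phone ...`` entry per line); frequencies from a
two-column ``token<TAB>count`` table. Stimulus words missing from the
frequency table are assigned a frequency of one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class LexiconError(ValueError):
    """Raised on malformed lexicon inputs or inconsistent entries."""


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    pronunciation: tuple[str, ...]
    frequency: int

    def __post_init__(self) -> None:
        if not self.pronunciation:
            raise LexiconError(f"{self.word!r}: empty pronunciation")
        if self.frequency < 1:
            raise LexiconError(f"{self.word!r}: frequency {self.frequency} < 1")


@dataclass(frozen=True)
class PhoneticLexicon:
    """Immutable word -> (pronunciation, frequency) collection."""

    entries: Mapping[str, LexiconEntry]

    @property
    def phoneme_alphabet(self) -> frozenset[str]:
        return frozenset(p for e in self.entries.values() for p in e.pronunciation)

    @property
    def total_frequency(self) -> int:
        return sum(e.frequency for e in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __getitem__(self, word: str) -> LexiconEntry:
        return self.entries[word.lower()]

    def relative_frequency(self, word: str) -> float:
        return self[word].frequency / self.total_frequency


def read_pronunciation_dict(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Parse an MFA-style pronunciation dictionary.

    Each non-empty line is ``word<whitespace>phone phone ...``. Words are
    case-folded; if a word appears on several lines, the first pronunciation
    wins and a warning is logged.
    """
    path = Path(path)
    out: dict[str, tuple[str, ...]] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    n_entries = 0
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise LexiconError(
                f"{path.name}:{lineno}: entry {parts[0]!r} has no phones"
            )
        word = parts[0].lower()
        phones = tuple(parts[1:])
        if word in out:
            logger.warning(
                "%s:%d: duplicate pronunciation for %r, keeping the first",
                path.name, lineno, word,
            )
        else:
            out[word] = phones
        n_entries += 1
    if n_entries == 0:
        raise LexiconError(f"{path.name}: empty pronunciation dictionary")
    return out


def read_frequency_table(path: str | Path) -> dict[str, int]:
    """Parse a ``token<TAB>count`` unigram table; case-folds and sums duplicates."""
    path = Path(path)
    out: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"{path.name}:{lineno}: expected 'token<TAB>count'")
        token, count_s = parts[0].strip().lower(), parts[1].strip()
        try:
            count = int(count_s)
        except ValueError:
            raise LexiconError(
                f"{path.name}:{lineno}: count {count_s!r} is not an integer"
            ) from None
        if count <= 0:
            raise LexiconError(f"{path.name}:{lineno}: count {count} is not positive")
        out[token] = out.get(token, 0) + count
    return out


def build_lexicon(
    pronunciations: Mapping[str, Sequence[str]],
    frequencies: Mapping[str, int],
    stimulus_words: Iterable[str] = (),
) -> PhoneticLexicon:
    """Merge pronunciations and frequencies into a :class:`PhoneticLexicon`.

    The lexicon contains every word that has both a pronunciation and a
    frequency. Stimulus words absent from the frequency table are inserted at
    frequency 1; a stimulus word with no pronunciation is an error.
    """
    prons = {w.lower(): tuple(p) for w, p in pronunciations.items()}
    freqs = {w.lower(): int(c) for w, c in frequencies.items()}
    stim = {w.lower() for w in stimulus_words}

    missing = sorted(w for w in stim if w not in prons)
    if missing:
        raise LexiconError(
            "stimulus words missing from the pronunciation dictionary: "
            + ", ".join(missing)
        )
    entries: dict[str, LexiconEntry] = {}
    for word in sorted(prons):
        if word in freqs:
            freq = freqs[word]
        elif word in stim:
            freq = 1  # stimulus word unseen in the frequency corpus
        else:
            continue
        entries[word] = LexiconEntry(word, prons[word], freq)
    return PhoneticLexicon(entries=entries)
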