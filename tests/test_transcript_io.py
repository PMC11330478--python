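"""Pronunciation dictionaries, frequency tables, TextGrids and the lexicon."""

import pytest

from speechtrf.lexicon import (
    LexiconError,
    build_lexicon,
    read_frequency_table,
    read_pronunciation_dict,
)
from speechtrf.transcript import (
    TranscriptError,
    read_textgrid,
    write_textgrid,
)
from .conftest import make_word
from speechtrf.transcript import TimeAlignedTranscript


# ---------------------------------------------------------------------------
# pronunciation dictionary
# ---------------------------------------------------------------------------


def test_pronunciation_dict_parsing(tmp_path, caplog):
    p = tmp_path / "dict.txt"
    p.write_text("hund h U n t\nAb a p\nab a b\n", encoding="utf-8")
    with caplog.at_level("WARNING"):
        d = read_pronunciation_dict(p)
    assert d["hund"] == ("h", "U", "n", "t")
    # case folding + first-pronunciation-wins with a warning
    assert d["ab"] == ("a", "p")
    assert any("duplicate" in r.message for r in caplog.records)


@pytest.mark.parametrize("content,match", [
    ("wort\n", "no phones"),
    ("", "empty"),
])
def test_pronunciation_dict_errors(tmp_path, content, match):
    p = tmp_path / "dict.txt"
    p.write_text(content, encoding="utf-8")
    with pytest.raises(LexiconError, match=match):
        read_pronunciation_dict(p)


# ---------------------------------------------------------------------------
# frequency table
# ---------------------------------------------------------------------------


def test_frequency_table_case_folds_and_sums(tmp_path):
    p = tmp_path / "freq.tsv"
    p.write_text("der\t1000\nDer\t2\nder\t3\n", encoding="utf-8")
    assert read_frequency_table(p) == {"der": 1005}


@pytest.mark.parametrize("line", ["der\t-1", "der\t0", "der\tx", "der 1"])
def test_frequency_table_rejects_bad_counts(tmp_path, line):
    p = tmp_path / "freq.tsv"
    p.write_text(line + "\n", encoding="utf-8")
    with pytest.raises(LexiconError):
        read_frequency_table(p)


# ---------------------------------------------------------------------------
# lexicon construction
# ---------------------------------------------------------------------------


def test_build_lexicon_merges_and_backfills_stimulus_words():
    prons = {"hund": ["h", "U", "n", "t"], "xylo": ["k", "s"], "rare": ["r", "a"]}
    freqs = {"hund": 100, "unrelated": 5}
    lex = build_lexicon(prons, freqs, stimulus_words={"xylo", "hund"})
    # stimulus word missing from the corpus enters at frequency one
    assert lex["xylo"].frequency == 1
    assert lex["hund"].frequency == 100
    # a word with frequency but no pronunciation is absent
    assert "unrelated" not in lex
    # a non-stimulus word with no frequency is absent
    assert "rare" not in lex
    assert lex.total_frequency == 101
    assert lex.phoneme_alphabet == {"h", "U", "n", "t", "k", "s"}


def test_build_lexicon_empty_stimulus_is_intersection():
    lex = build_lexicon({"a": ["x"], "b": ["y"]}, {"b": 2, "c": 3})
    assert set(lex.entries) == {"b"}


def test_build_lexicon_order_independent():
    prons = {"a": ["x"], "b": ["y"], "c": ["z"]}
    freqs = {"a": 1, "b": 2, "c": 3}
    l1 = build_lexicon(prons, freqs)
    l2 = build_lexicon(dict(reversed(prons.items())), dict(reversed(freqs.items())))
    assert l1.entries == l2.entries


def test_build_lexicon_missing_pronunciation_names_word():
    with pytest.raises(LexiconError, match="xylo"):
        build_lexicon({"hund": ["h"]}, {"hund": 1}, stimulus_words={"xylo"})


# ---------------------------------------------------------------------------
# TextGrid
# ---------------------------------------------------------------------------


def _transcript():
    w1 = make_word("ab", ["a", "b"], 0.5, 0.2)
    w2 = make_word("cd", ["c", "d"], 1.1, 0.15)
    return TimeAlignedTranscript("seg", 2.0, (w1, w2))


def test_textgrid_round_trip(tmp_path):
    tr = _transcript()
    path = tmp_path / "seg.TextGrid"
    write_textgrid(tr, path)
    back = read_textgrid(path, segment_id="seg")
    assert back.duration == pytest.approx(tr.duration, abs=1e-6)
    assert [w.orthography for w in back.words] == ["ab", "cd"]
    for w0, w1 in zip(tr.words, back.words):
        assert w1.onset == pytest.approx(w0.onset, abs=1e-6)
        assert w1.offset == pytest.approx(w0.offset, abs=1e-6)
        assert [p.label for p in w1.phonemes] == [p.label for p in w0.phonemes]
        for p0, p1 in zip(w0.phonemes, w1.phonemes):
            assert p1.onset == pytest.approx(p0.onset, abs=1e-6)


def test_textgrid_short_format_and_utf16(tmp_path):
    short = "\n".join([
        '"ooTextFile"', '"TextGrid"', "",
        "0", "1.0", "<exists>", "1",
        '"IntervalTier"', '"words"', "0", "1.0", "3",
        "0", "0.4", '""',
        "0.4", "0.7", '"ab"',
        "0.7", "1.0", '"sil"',
    ])
    p8 = tmp_path / "short8.TextGrid"
    p8.write_text(short + "\n", encoding="utf-8")
    p16 = tmp_path / "short16.TextGrid"
    p16.write_bytes(short.encode("utf-16"))
    for p in (p8, p16):
        tr = read_textgrid(p, word_tier="words", phone_tier="words")
        # silence conventions: "" and "sil" are not words
        assert [w.orthography for w in tr.words] == ["ab"]


def test_textgrid_missing_tier_errors(tmp_path):
    path = tmp_path / "seg.TextGrid"
    write_textgrid(_transcript(), path)
    with pytest.raises(TranscriptError, match="phonemes"):
        read_textgrid(path, word_tier="words", phone_tier="phonemes")


def test_textgrid_phone_crossing_word_boundary_errors(tmp_path):
    lines = [
        'File type = "ooTextFile"', 'Object class = "TextGrid"', "",
        "xmin = 0", "xmax = 1.0", "tiers? <exists>", "size = 2", "item []:",
        "    item [1]:",
        '        class = "IntervalTier"', '        name = "words"',
        "        xmin = 0", "        xmax = 1.0",
        "        intervals: size = 2",
        "        intervals [1]:", "            xmin = 0", "            xmax = 0.9",
        '            text = "ab"',
        "        intervals [2]:", "            xmin = 0.9", "            xmax = 1.0",
        '            text = ""',
        "    item [2]:",
        '        class = "IntervalTier"', '        name = "phones"',
        "        xmin = 0", "        xmax = 1.0",
        "        intervals: size = 1",
        "        intervals [1]:", "            xmin = 0.65", "            xmax = 0.95",
        '            text = "a"',
    ]
    p = tmp_path / "bad.TextGrid"
    p.write_text("\n".join(lines) + "\n", encoding="utf-8")
    with pytest.raises(TranscriptError, match="crosses"):
        read_textgrid(p)


def test_transcript_invariants():
    w = make_word("ab", ["a", "b"], 0.5, 0.2)
    # word offset beyond the segment duration
    with pytest.raises(TranscriptError, match="beyond"):
        TimeAlignedTranscript("seg", 0.6, (w,))
    # overlapping words
    w2 = make_word("cd", ["c"], 0.6, 0.2)
    with pytest.raises(TranscriptError, match="overlap"):
        TimeAlignedTranscript("seg", 2.0, (w, w2))
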