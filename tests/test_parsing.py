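"""Graphemic parsing: standard parses, enumeration vs oracle, aligner."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from graphovar.errors import AlignmentError, NoParseError
from graphovar.parsing import (
    EditCosts,
    enumerate_parses,
    infer_parse,
    standard_parse,
    standard_pronunciation,
)
from graphovar.phonology import tokenize_phonemes
from graphovar.simulate import generate_nonwords

from conftest import TOY_PATTERNS


@pytest.mark.parametrize(
    "word, expected",
    [
        ("SHOIL", ("SH", "OI", "L")),
        ("GNEUTH", ("GN", "EU", "TH")),
        ("SCROME", ("S", "C", "R", "O.E", "M")),
        ("PSIRP", ("PS", "IR", "P")),
        ("CLALF", ("C", "L", "A", "L", "F")),
        ("DONGE", ("D", "O", "N", "GE")),
        ("GANC", ("G", "A", "N", "C")),
        ("SPRAUK", ("S", "P", "R", "AU", "K")),
        ("B", ("B",)),
    ],
)
def test_standard_parse_examples(inv, word, expected):
    assert standard_parse(word, inv).patterns == expected


@pytest.mark.parametrize(
    "word, split_grapheme",
    [
        ("PSOATH", None),  # OA is contiguous, not split
        ("GWENE", "E.E"),
        ("TWOLE", "O.E"),
        ("TRURE", "U.E"),
        ("THAQUE", "A.UE"),
        ("WAICE", "AI.E"),
        ("HAUVE", "AU.E"),
        ("STRIQUE", "I.UE"),
        ("HIECE", "IE.E"),
        ("WOUGE", "OU.E"),
        ("CRUSQUE", "U.UE"),
        ("FRUGUE", "U.UE"),
        ("PSEUCE", "EU.E"),
        ("SUILE", "UI.E"),
        ("STOARSE", "OA.E"),
    ],
)
def test_split_vowel_graphemes_bind(inv, word, split_grapheme):
    """Every multiletter/split vowel grapheme of the example nonwords is
    recovered by the standard parse."""
    patterns = standard_parse(word, inv).patterns
    if split_grapheme is not None:
        assert split_grapheme in patterns


def test_final_e_competition(inv):
    """A word-final GE/CE grapheme beats split binding across two consonants
    but loses to binding across one."""
    assert standard_parse("DONGE", inv).patterns == ("D", "O", "N", "GE")
    assert standard_parse("PONCE", inv).patterns == ("P", "O", "N", "CE")
    assert "OU.E" in standard_parse("WOUGE", inv).patterns
    assert "OA.E" in standard_parse("STOARSE", inv).patterns


def test_parse_requires_letters(inv):
    for bad in ("", "SHO1L", "SH OIL"):
        with pytest.raises(NoParseError):
            standard_parse(bad, inv)


def test_span_cover_conservation(inv):
    rng = np.random.default_rng(3)
    for word in generate_nonwords(50, inv, rng):
        parse = standard_parse(word, inv)
        assert sum(el.n_letters for el in parse.elements) == len(word)


# ---------------------------------------------------------------------------
# enumeration


def _brute_segmentations(word: str, patterns: set[str]) -> set[tuple[str, ...]]:
    """All contiguous segmentations via the 2^(n-1) split-point oracle."""
    n = len(word)
    out = set()
    for mask in range(2 ** max(n - 1, 0)):
        cuts = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        segs = tuple(word[a:b] for a, b in zip(cuts, cuts[1:]))
        if all(s in patterns for s in segs):
            out.add(segs)
    return out


def test_enumerate_matches_bruteforce_short(toy_inv):
    """Spot-check of enumeration vs the exhaustive oracle (full sweep in the
    acceptance suite)."""
    patterns = set(TOY_PATTERNS)
    for word in ("BREC", "RECCE", "BRECB", "EEC"):
        expected = _brute_segmentations(word, patterns)
        if not expected:
            with pytest.raises(NoParseError):
                enumerate_parses(word, toy_inv)
            continue
        got = {p.patterns for p in enumerate_parses(word, toy_inv)}
        assert got == expected


def test_enumerate_contains_standard_first(inv):
    rng = np.random.default_rng(9)
    for word in generate_nonwords(25, inv, rng):
        parses = enumerate_parses(word, inv, max_count=500)
        std = standard_parse(word, inv)
        assert parses[0].signature == std.signature
        assert all(
            sum(el.n_letters for el in p.elements) == len(word) for p in parses
        )


def test_enumerate_single_letter(inv):
    parses = enumerate_parses("A", inv)
    assert [p.patterns for p in parses] == [("A",)]


def test_enumerate_truncation_flag(inv):
    # OOSH has four parses; capping at two must set the flag
    parses = enumerate_parses("OOSH", inv, max_count=2)
    assert len(parses) == 2 and parses.truncated
    assert not enumerate_parses("OOSH", inv, max_count=10).truncated


def test_enumerate_oosh_contains_both_granularities(inv):
    got = {p.patterns for p in enumerate_parses("OOSH", inv)}
    assert ("OO", "SH") in got
    assert ("O", "O", "S", "H") in got


# ---------------------------------------------------------------------------
# response-to-parse alignment


def test_infer_standard_response_is_zero_cost(inv):
    result = infer_parse("SPRAUK", tokenize_phonemes("/sprɔːk/"), inv)
    assert result.cost == 0
    assert result.parsing.patterns == ("S", "P", "R", "AU", "K")
    assert all(op.kind == "match" for op in result.ops)


def test_infer_omission(inv):
    result = infer_parse("SPRAUK", tokenize_phonemes("/spɔːk/"), inv)
    omitted = [op.grapheme.pattern for op in result.ops if op.kind == "omission"]
    assert omitted == ["R"]
    assert result.parsing.patterns == ("S", "P", "R", "AU", "K")


def test_infer_split_with_glide_gluit(inv):
    """GLUIT read /gluwit/: UI treated as two graphemes with an inserted glide."""
    result = infer_parse("GLUIT", tokenize_phonemes("/gluwit/"), inv)
    assert result.parsing.patterns == ("G", "L", "U", "I", "T")
    inserted = [op.phoneme.ipa for op in result.ops if op.kind == "insertion"]
    assert inserted == ["w"]


def test_infer_split_with_glide_psoath(inv):
    """PSOATH read /səʊwəθ/: OA parsed as two vowel graphemes."""
    result = infer_parse("PSOATH", tokenize_phonemes("/səʊwəθ/"), inv)
    assert "OA" not in result.parsing.patterns
    assert "O" in result.parsing.patterns and "A" in result.parsing.patterns


def test_infer_cost_ceiling(inv):
    with pytest.raises(AlignmentError):
        infer_parse("SPRAUK", tokenize_phonemes("/spɔːk/"), inv, ceiling=1.0)


def test_infer_costs_configurable(inv):
    cheap = EditCosts(insertion=0.1)
    result = infer_parse("PSOATH", tokenize_phonemes("/səʊwəθ/"), inv, costs=cheap)
    # with near-free insertions the standard 3-grapheme parse wins
    assert result.parsing.patterns == ("PS", "OA", "TH")
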