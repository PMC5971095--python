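"""Response classification, alignment, tallies, eligibility."""

from __future__ import annotations

import pytest

from graphovar.analysis import (
    NONSTANDARD,
    STANDARD,
    UNANALYSABLE,
    AssignmentTally,
    ResponseRecord,
    align_standard,
    classify_assignment,
    classify_parsing,
    classify_responses,
    eligible_graphemes,
    status_counts,
    tally_assignments,
)
from graphovar.errors import GraphovarError


@pytest.mark.parametrize(
    "nonword, transcription, n_g, n_p, status",
    [
        ("SPRAUK", "/sprʌŋk/", 5, 6, NONSTANDARD),  # new grapheme parsed in
        ("SPRAUK", "/spɔːk/", 5, 4, NONSTANDARD),   # grapheme omitted
        ("SPRAUK", "/spraʊ/", 5, 4, NONSTANDARD),   # final grapheme omitted
        ("SHOIL", "/ʃɔɪl/", 3, 3, STANDARD),
        ("GNEUTH", "/nuθ/", 3, 3, STANDARD),
        ("GNEUTH", "/gwɛnθ/", 3, 5, NONSTANDARD),
    ],
)
def test_classify_parsing_count_rule(inv, nonword, transcription, n_g, n_p, status):
    cls = classify_parsing(ResponseRecord("s1", nonword, transcription), inv)
    assert (cls.n_graphemes, cls.n_phonemes, cls.status) == (n_g, n_p, status)


def test_classify_unanalysable_paths(inv):
    # missing transcription
    cls = classify_parsing(ResponseRecord("s1", "SHOIL", ""), inv)
    assert cls.status == UNANALYSABLE
    # transcription outside the phoneme inventory
    cls = classify_parsing(ResponseRecord("s1", "SHOIL", "/ʃɔɪl?/"), inv)
    assert cls.status == UNANALYSABLE


def test_classification_ignores_formatting(inv):
    plain = classify_parsing(ResponseRecord("s1", "SHOIL", "ʃɔɪl"), inv)
    fancy = classify_parsing(ResponseRecord("s1", "shoil", "/ˈʃɔɪl/"), inv)
    assert plain.status == fancy.status == STANDARD
    assert plain.n_phonemes == fancy.n_phonemes


def test_align_standard_examples(inv):
    pairs = align_standard(ResponseRecord("s1", "SHOIL", "/ʃɔɪl/"), inv)
    assert [(g.pattern, p.ipa) for g, p in pairs] == [
        ("SH", "ʃ"), ("OI", "ɔɪ"), ("L", "l")
    ]
    pairs = align_standard(ResponseRecord("s1", "GNEUTH", "/nuθ/"), inv)
    assert [(g.pattern, p.ipa) for g, p in pairs] == [
        ("GN", "n"), ("EU", "u"), ("TH", "θ")
    ]


def test_align_standard_rejects_nonstandard(inv):
    with pytest.raises(GraphovarError):
        align_standard(ResponseRecord("s1", "SPRAUK", "/sprʌŋk/"), inv)


# ---------------------------------------------------------------------------
# tallies


def _variable_reader_records():
    """Records reproducing a highly variable reader's CH and I.E distributions:
    CH as /ʧ/ x3, /k/ x11, /s/ x1, /ʃ/ x2, /θ/ x1; I.E as /aɪ/ x1, /ɛ/ x1,
    /i/ x2, /ɪ/ x3."""
    ch_words = [
        "CHAB", "CHAD", "CHAF", "CHAG", "CHAK", "CHAL", "CHAM", "CHAN",
        "CHAP", "CHAT", "CHEB", "CHED", "CHEF", "CHEG", "CHEK", "CHEL",
        "CHEM", "CHEN",
    ]
    ch_phonemes = ["ʧ"] * 3 + ["k"] * 11 + ["s"] + ["ʃ"] * 2 + ["θ"]
    vowel = {"A": "æ", "E": "ɛ"}
    coda = {"B": "b", "D": "d", "F": "f", "G": "g", "K": "k", "L": "l",
            "M": "m", "N": "n", "P": "p", "T": "t"}
    records = []
    for word, ch in zip(ch_words, ch_phonemes):
        ipa = ch + vowel[word[2]] + coda[word[3]]
        records.append(ResponseRecord("R1", word, f"/{ipa}/"))
    ie_words = ["BIDE", "DIDE", "FIDE", "KIDE", "LIDE", "MIDE", "NIDE"]
    ie_phonemes = ["aɪ", "ɛ", "i", "i", "ɪ", "ɪ", "ɪ"]
    onset = {"B": "b", "D": "d", "F": "f", "K": "k", "L": "l", "M": "m", "N": "n"}
    for word, v in zip(ie_words, ie_phonemes):
        records.append(ResponseRecord("R1", word, f"/{onset[word[0]]}{v}d/"))
    return records


def test_tally_reproduces_subject_level_distributions(inv):
    records = _variable_reader_records()
    tally = tally_assignments(records, inv)
    ch = inv.find("CH")
    counts = {p.ipa: n for p, n in tally.subject_grapheme_counts("R1", ch).items()}
    assert counts == {"ʧ": 3, "k": 11, "s": 1, "ʃ": 2, "θ": 1}
    ie = inv.find("I.E")
    counts = {p.ipa: n for p, n in tally.subject_grapheme_counts("R1", ie).items()}
    assert counts == {"aɪ": 1, "ɛ": 1, "i": 2, "ɪ": 3}


def test_tally_empty_and_nonstandard_excluded(inv):
    assert tally_assignments([], inv).total == 0
    # a nonstandard-parse record contributes nothing
    tally = tally_assignments(
        [ResponseRecord("s1", "SPRAUK", "/sprʌŋk/")], inv
    )
    assert tally.total == 0


def test_tally_conservation(inv, small_sim):
    _, records, _ = small_sim
    classifications = classify_responses(records, inv)
    tally = tally_assignments(records, inv)
    incidences = sum(
        c.n_graphemes for c in classifications if c.status == STANDARD
    )
    assert tally.total == incidences
    # summing a subject's phoneme counts gives parsed-out grapheme occurrences
    totals = tally.per_subject_totals()
    for (s, g), n in totals.items():
        assert n == sum(tally.subject_grapheme_counts(s, g).values())


def test_partition_invariant(inv, small_sim):
    _, records, _ = small_sim
    counts = status_counts(classify_responses(records, inv))
    assert sum(counts.values()) == len(records)
    assert set(counts) <= {STANDARD, NONSTANDARD, UNANALYSABLE}


# ---------------------------------------------------------------------------
# eligibility


def _toy_tally(inv, spec):
    """spec: {(subject, pattern, ipa): count}"""
    tally = AssignmentTally()
    for (s, pattern, ipa), n in spec.items():
        tally.add(s, inv.find(pattern), inv.phonemes[ipa], n)
    return tally


def test_eligible_graphemes_universal_quantifier(inv):
    tally = _toy_tally(inv, {
        ("a", "L", "l"): 10, ("b", "L", "l"): 4, ("c", "L", "l"): 114,
        ("a", "CH", "ʧ"): 100, ("b", "CH", "ʧ"): 3, ("c", "CH", "ʧ"): 100,
    })
    eligible = {g.pattern for g in eligible_graphemes(tally, 4)}
    assert eligible == {"L"}  # CH fails for one subject, so it is out


def test_eligible_graphemes_matches_bruteforce(inv, small_sim):
    _, records, _ = small_sim
    tally = tally_assignments(records, inv)
    got = eligible_graphemes(tally, 4)
    totals = tally.per_subject_totals()
    subjects = tally.subjects
    brute = {
        g for g in tally.graphemes
        if all(totals.get((s, g), 0) >= 4 for s in subjects)
    }
    assert got == brute
    assert eligible_graphemes(tally, 1) >= got  # weaker threshold is larger


def test_classify_assignment(inv):
    au, ch = inv.find("AU"), inv.find("CH")
    assert classify_assignment(au, inv.phonemes["ɔː"], inv) == STANDARD
    assert classify_assignment(au, inv.phonemes["aʊ"], inv) == NONSTANDARD
    assert classify_assignment(ch, inv.phonemes["ʧ"], inv) == STANDARD
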