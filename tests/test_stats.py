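"""Entropy and rate statistics: worked values, invariants, oracles."""

from __future__ import annotations

import math
from itertools import combinations_with_replacement

import numpy as np
import pytest
from hypothesis import given, strategies as st

from graphovar.analysis import (
    ResponseRecord,
    classify_responses,
    eligible_graphemes,
    tally_assignments,
)
from graphovar.errors import AnalysisError
from graphovar.stats import (
    Rate,
    distinct_response_counts,
    entropy,
    grapheme_entropy_across_subjects,
    nonstandard_rates,
    subject_grapheme_entropy,
)


def _entropy_direct(counts):
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c)


@pytest.mark.parametrize(
    "counts, expected_2dp",
    [
        ({"ʧ": 3, "k": 11, "s": 1, "ʃ": 2, "θ": 1}, 1.68),
        ({"aɪ": 1, "ɛ": 1, "i": 2, "ɪ": 3}, 1.84),
        ({"x": 7}, 0.0),
        ({"a": 5, "b": 5}, 1.0),
    ],
)
def test_entropy_worked_examples(counts, expected_2dp):
    assert round(entropy(counts), 2) == expected_2dp


def test_entropy_rejects_degenerate_input():
    with pytest.raises(AnalysisError):
        entropy({})
    with pytest.raises(AnalysisError):
        entropy({"a": 0})
    with pytest.raises(AnalysisError):
        entropy({"a": -1, "b": 2})


@given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=6)
       .filter(lambda xs: sum(xs) > 0))
def test_entropy_matches_direct_formula_and_invariances(xs):
    counts = {i: x for i, x in enumerate(xs)}
    h = entropy(counts)
    assert h == pytest.approx(_entropy_direct(xs), abs=1e-12)
    # permutation invariance
    perm = {i: x for i, x in enumerate(reversed(xs))}
    assert entropy(perm) == pytest.approx(h, abs=1e-12)
    # scale invariance H(c) = H(3c)
    scaled = {i: 3 * x for i, x in enumerate(xs)}
    assert entropy(scaled) == pytest.approx(h, abs=1e-12)
    # bounds
    k = sum(1 for x in xs if x)
    assert -1e-12 <= h <= math.log2(k) + 1e-12
    assert (h < 1e-12) == (k == 1)


def test_uniform_maximizes_entropy_bruteforce():
    """Over all integer compositions at fixed k and total, uniform counts
    achieve the maximum H (k <= 4)."""
    for k in (2, 3, 4):
        total = 12
        best = max(
            entropy(dict(enumerate(c)))
            for c in combinations_with_replacement(range(1, total), k)
            if sum(c) == total
        )
        uniform = entropy(dict(enumerate([total // k] * k)))
        assert best == pytest.approx(uniform, abs=1e-12)
        assert uniform == pytest.approx(math.log2(k), abs=1e-12)


# ---------------------------------------------------------------------------
# entropy reports


def test_subject_grapheme_entropy_matches_cellwise_oracle(inv, small_sim):
    _, records, _ = small_sim
    tally = tally_assignments(records, inv)
    eligible = eligible_graphemes(tally, 4)
    report = subject_grapheme_entropy(tally, eligible)
    assert report.per_subject_grapheme  # non-degenerate
    by_label = {g.label: g for g in eligible}
    for (s, label), h in report.per_subject_grapheme.items():
        cell = tally.subject_grapheme_counts(s, by_label[label])
        assert h == pytest.approx(entropy(cell), abs=1e-12)
    for s, mean in report.subject_means.items():
        cells = [h for (ss, _), h in report.per_subject_grapheme.items() if ss == s]
        assert mean == pytest.approx(np.mean(cells), abs=1e-12)


def test_unanimous_subject_has_zero_entropy(inv):
    records = [
        ResponseRecord("s1", w, "/" + ipa + "/")
        for w, ipa in [("NOF", "nɒf"), ("NIF", "nɪf"), ("NAF", "næf"),
                       ("NUF", "nʌf"), ("FON", "fɒn")]
    ]
    tally = tally_assignments(records, inv)
    report = subject_grapheme_entropy(tally, eligible_graphemes(tally, 4))
    assert report.per_subject_grapheme
    assert all(h == 0 for h in report.per_subject_grapheme.values())
    assert report.subject_means["s1"] == 0


def test_grapheme_entropy_across_subjects_pooling(inv):
    """Two subjects with disjoint single phonemes at equal counts pool to
    H = 1 bit, while each subject's own H (and hence the mean) is 0."""
    from graphovar.analysis import AssignmentTally

    tally = AssignmentTally()
    n = inv.find("N")
    tally.add("a", n, inv.phonemes["n"], 6)
    tally.add("b", n, inv.phonemes["m"], 6)
    report = grapheme_entropy_across_subjects(tally, {n})
    assert report.per_grapheme_pooled["N"] == pytest.approx(1.0)
    # each subject is internally unanimous, so the mean-over-subjects H is 0
    assert report.per_grapheme_mean["N"] == 0
    # unanimity across everyone -> pooled H = 0
    tally2 = AssignmentTally()
    tally2.add("a", n, inv.phonemes["n"], 6)
    tally2.add("b", n, inv.phonemes["n"], 6)
    report2 = grapheme_entropy_across_subjects(tally2, {n})
    assert report2.per_grapheme_pooled["N"] == 0


# ---------------------------------------------------------------------------
# rates


def test_rate_percentages_match_printed_arithmetic():
    assert round(Rate(2199, 18118).pct, 1) == 12.1
    assert round(Rate(4230, 48269).pct, 1) == 8.8


def test_rates_all_standard_toy(inv):
    records = [ResponseRecord("s1", "SHOIL", "/ʃɔɪl/"),
               ResponseRecord("s2", "SHOIL", "/ʃɔɪl/")]
    cls = classify_responses(records, inv)
    tally = tally_assignments(records, inv)
    report = nonstandard_rates(cls, tally, inv)
    assert report.overall["parsing"].pct == 0
    assert report.overall["assignment"].pct == 0
    assert all(r.pct == 0 for r in report.subject_parsing_rates.values())


def test_rates_conservation_and_denominators(inv, small_sim):
    _, records, _ = small_sim
    cls = classify_responses(records, inv)
    tally = tally_assignments(records, inv)
    report = nonstandard_rates(cls, tally, inv)
    overall = report.overall["parsing"]
    assert overall.numerator == sum(
        r.numerator for r in report.subject_parsing_rates.values()
    )
    assert overall.numerator == sum(
        r.numerator for r in report.item_parsing_rates.values()
    )
    assert overall.denominator == sum(
        r.denominator for r in report.subject_parsing_rates.values()
    )
    assert all(0 <= r.pct <= 100 for r in report.subject_parsing_rates.values())
    assign = report.overall["assignment"]
    assert assign.denominator == tally.total


def test_zero_denominator_cells_are_missing_not_zero(inv):
    records = [ResponseRecord("s1", "SHOIL", ""),  # unanalysable
               ResponseRecord("s2", "SHOIL", "/ʃɔɪl/")]
    report = nonstandard_rates(classify_responses(records, inv))
    assert "s1" not in report.subject_parsing_rates
    assert "s2" in report.subject_parsing_rates


# ---------------------------------------------------------------------------
# distinct responses


def test_distinct_response_counts(inv):
    records = [
        ResponseRecord("a", "SHOIL", "/ʃɔɪl/"),
        ResponseRecord("b", "SHOIL", "ʃɔɪl"),      # same after normalization
        ResponseRecord("c", "SHOIL", "/ʃaʊl/"),
        ResponseRecord("d", "SHOIL", "/sɔɪl/"),
        ResponseRecord("e", "SHOIL", ""),           # unanalysable, skipped
        ResponseRecord("a", "NOF", "/nɒf/"),
        ResponseRecord("b", "NOF", "/nɒf/"),
    ]
    counts = distinct_response_counts(records, inv)
    assert counts == {"SHOIL": 3, "NOF": 1}
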