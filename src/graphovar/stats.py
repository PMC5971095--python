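"""Variability statistics: Shannon entropy, nonstandard rates, response counts.

Variability of phoneme assignment is quantified with Shannon entropy in
bits, H = -sum_i p_i log2 p_i, where p_i is the proportion of assignments
of phoneme i to the grapheme in question. H = 0 means unanimity; higher
values mean the grapheme received many different phonemes. Parsing
variability is quantified as the percentage of nonstandard parsings per
subject and per nonword, always stored with explicit numerators and
denominators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
from scipy import stats as sps

from .analysis import (
    NONSTANDARD,
    STANDARD,
    AssignmentTally,
    ParseClassification,
    ResponseRecord,
    classify_assignment,
)
from .errors import AnalysisError
from .inventory import Grapheme, GraphemeInventory
from .phonology import Phoneme


def entropy(counts: Mapping) -> float:
    """Shannon entropy in bits of a categorical count distribution.

    Zero-count categories contribute nothing (0 * log 0 = 0 convention);
    the total must be positive.
    """
    values = np.asarray([c for c in counts.values()], dtype=float)
    if values.size == 0 or values.sum() <= 0:
        raise AnalysisError("entropy requires a positive total count")
    if (values < 0).any():
        raise AnalysisError("entropy counts must be non-negative")
    return float(sps.entropy(values[values > 0], base=2))


class Rate(NamedTuple):
    """A percentage with its numerator and denominator kept alongside."""

    numerator: int
    denominator: int

    @property
    def pct(self) -> float:
        return 100.0 * self.numerator / self.denominator


@dataclass
class EntropyReport:
    """Subject-level and grapheme-level entropy summaries (bits).

    ``per_grapheme_pooled`` uses the distribution of assignments pooled
    across subjects (the headline measure); ``per_grapheme_mean`` averages
    each subject's own H for the grapheme, which weights subjects equally
    regardless of how often they parsed the grapheme out.
    """

    per_subject_grapheme: dict[tuple[str, str], float] = field(default_factory=dict)
    subject_means: dict[str, float] = field(default_factory=dict)
    per_grapheme_pooled: dict[str, float] = field(default_factory=dict)
    per_grapheme_mean: dict[str, float] = field(default_factory=dict)


@dataclass
class RateReport:
    """Nonstandard-parsing and nonstandard-assignment rates with totals."""

    subject_parsing_rates: dict[str, Rate] = field(default_factory=dict)
    item_parsing_rates: dict[str, Rate] = field(default_factory=dict)
    subject_assignment_rates: dict[str, Rate] = field(default_factory=dict)
    overall: dict[str, Rate] = field(default_factory=dict)


def subject_grapheme_entropy(
    tally: AssignmentTally,
    eligible: Iterable[Grapheme],
    min_cell: int = 1,
) -> EntropyReport:
    """Entropy of each subject's phoneme distribution per eligible grapheme.

    Cells with fewer than ``min_cell`` parsed-out occurrences are omitted
    (default: global eligibility only — every observed cell is reported).
    ``subject_means`` averages over the subject's reported cells.
    """
    eligible = set(eligible)
    report = EntropyReport()
    per_subject: dict[str, list[float]] = {}
    cells: dict[tuple[str, Grapheme], dict[Phoneme, int]] = {}
    for (s, g, p), n in tally.counts.items():
        if g in eligible:
            cells.setdefault((s, g), {})[p] = n
    for (s, g), dist in sorted(cells.items(), key=lambda kv: (kv[0][0], kv[0][1].label)):
        if sum(dist.values()) < min_cell:
            continue
        h = entropy(dist)
        report.per_subject_grapheme[(s, g.label)] = h
        per_subject.setdefault(s, []).append(h)
    report.subject_means = {
        s: float(np.mean(hs)) for s, hs in per_subject.items()
    }
    return report


def grapheme_entropy_across_subjects(
    tally: AssignmentTally,
    eligible: Iterable[Grapheme],
) -> EntropyReport:
    """Across-subject entropy per eligible grapheme.

    The pooled variant computes H over all subjects' assignments lumped
    together; the mean variant averages each subject's own H for the
    grapheme. Both are reported.
    """
    eligible_set = set(eligible)
    report = EntropyReport()
    per_subject = subject_grapheme_entropy(tally, eligible_set)
    by_grapheme: dict[str, list[float]] = {}
    for (_, label), h in per_subject.per_subject_grapheme.items():
        by_grapheme.setdefault(label, []).append(h)
    for g in sorted(eligible_set, key=lambda g: g.label):
        pooled = tally.pooled_counts(g)
        if not pooled:
            continue
        report.per_grapheme_pooled[g.label] = entropy(pooled)
        report.per_grapheme_mean[g.label] = float(np.mean(by_grapheme.get(g.label, [0.0])))
    return report


def nonstandard_rates(
    classifications: Iterable[ParseClassification],
    tally: AssignmentTally | None = None,
    inv: GraphemeInventory | None = None,
    eligible: Iterable[Grapheme] | None = None,
) -> RateReport:
    """Per-subject / per-item parsing rates and per-subject assignment rates.

    Zero-denominator cells are omitted (missing, not 0%). If a tally and
    inventory are supplied, assignment rates are computed over it,
    optionally restricted to an eligible grapheme set.
    """
    report = RateReport()
    subj_counts: dict[str, Counter] = {}
    item_counts: dict[str, Counter] = {}
    for c in classifications:
        subj_counts.setdefault(c.subject_id, Counter())[c.status] += 1
        item_counts.setdefault(c.nonword, Counter())[c.status] += 1

    def rates(groups: dict[str, Counter]) -> dict[str, Rate]:
        out = {}
        for key in sorted(groups):
            counts = groups[key]
            den = counts[STANDARD] + counts[NONSTANDARD]
            if den > 0:
                out[key] = Rate(counts[NONSTANDARD], den)
        return out

    report.subject_parsing_rates = rates(subj_counts)
    report.item_parsing_rates = rates(item_counts)
    num = sum(r.numerator for r in report.subject_parsing_rates.values())
    den = sum(r.denominator for r in report.subject_parsing_rates.values())
    if den:
        report.overall["parsing"] = Rate(num, den)

    if tally is not None:
        if inv is None:
            raise AnalysisError("assignment rates require the inventory")
        if eligible is not None:
            tally = tally.restrict(eligible)
        subj_assign: dict[str, list[int]] = {}
        for (s, g, p), n in tally.counts.items():
            bad = classify_assignment(g, p, inv) == NONSTANDARD
            nn, dd = subj_assign.setdefault(s, [0, 0])
            subj_assign[s] = [nn + (n if bad else 0), dd + n]
        report.subject_assignment_rates = {
            s: Rate(nn, dd) for s, (nn, dd) in sorted(subj_assign.items()) if dd > 0
        }
        num = sum(r.numerator for r in report.subject_assignment_rates.values())
        den = sum(r.denominator for r in report.subject_assignment_rates.values())
        if den:
            report.overall["assignment"] = Rate(num, den)
    return report


def distinct_response_counts(
    records: Iterable[ResponseRecord],
    inv: GraphemeInventory | None = None,
) -> dict[str, int]:
    """Number of distinct normalized transcriptions per nonword.

    Transcriptions are normalized through phoneme tokenization when an
    inventory is given (so /nuθ/ and nuθ coincide); unanalysable and
    untokenizable records are skipped.
    """
    responses: dict[str, set[str]] = {}
    for r in records:
        if not r.analysable:
            continue
        key = r.transcription.strip()
        if inv is not None:
            try:
                key = inv.phonemes.tokenize(r.transcription).ipa
            except Exception:
                continue
        responses.setdefault(r.nonword, set()).add(key)
    return {w: len(s) for w, s in sorted(responses.items())}
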