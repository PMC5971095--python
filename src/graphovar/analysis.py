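"""Response classification, grapheme-phoneme alignment, assignment tallies.

A response exhibits a *standard parsing* exactly when the number of
phonemes in the response equals the number of graphemes in the stimulus's
standard parse; otherwise the parsing is nonstandard (an extra grapheme was
parsed out, or one was omitted, or a multi-letter grapheme was read as its
constituent letters). For standard-parse responses each grapheme is
unambiguously associated with one response phoneme positionally, which is
what makes subject-level grapheme-phoneme assignment tallies well defined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import GraphovarError, NoParseError, TokenizationError
from .inventory import Grapheme, GraphemeInventory
from .parsing import standard_parse
from .phonology import Phoneme, PhonemeString

STANDARD = "standard"
NONSTANDARD = "nonstandard"
UNANALYSABLE = "unanalysable"


@dataclass(frozen=True)
class ResponseRecord:
    """One subject's transcribed pronunciation of one nonword."""

    subject_id: str
    nonword: str
    transcription: str
    analysable: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "nonword", self.nonword.strip().upper())
        if not self.transcription or not self.transcription.strip():
            object.__setattr__(self, "analysable", False)


@dataclass(frozen=True)
class ParseClassification:
    """Grapheme/phoneme counts and the standard/nonstandard verdict."""

    record: ResponseRecord
    n_graphemes: int | None
    n_phonemes: int | None
    status: str  # standard | nonstandard | unanalysable

    @property
    def subject_id(self) -> str:
        return self.record.subject_id

    @property
    def nonword(self) -> str:
        return self.record.nonword


def classify_parsing(
    record: ResponseRecord, inv: GraphemeInventory
) -> ParseClassification:
    """Classify one response by the phoneme-count = grapheme-count rule.

    Records whose transcription fails tokenization, or whose stimulus does
    not parse, are marked unanalysable (they join the unavailable records
    and are excluded from all denominators), never nonstandard.
    """
    if not record.analysable:
        return ParseClassification(record, None, None, UNANALYSABLE)
    try:
        n_g = len(standard_parse(record.nonword, inv))
        n_p = len(inv.phonemes.tokenize(record.transcription))
    except (TokenizationError, NoParseError):
        return ParseClassification(record, None, None, UNANALYSABLE)
    status = STANDARD if n_p == n_g else NONSTANDARD
    return ParseClassification(record, n_g, n_p, status)


def classify_responses(
    records: Iterable[ResponseRecord], inv: GraphemeInventory
) -> list[ParseClassification]:
    return [classify_parsing(r, inv) for r in records]


def align_standard(
    record: ResponseRecord, inv: GraphemeInventory
) -> list[tuple[Grapheme, Phoneme]]:
    """Positional one-to-one pairing of standard-parse graphemes and phonemes.

    Only defined for standard-parse responses; raises on any other record.
    """
    cls = classify_parsing(record, inv)
    if cls.status != STANDARD:
        raise GraphovarError(
            f"align_standard requires a standard parsing; "
            f"{record.nonword}/{record.transcription!r} is {cls.status}"
        )
    parse = standard_parse(record.nonword, inv)
    phonemes = inv.phonemes.tokenize(record.transcription)
    return list(zip(parse.graphemes, phonemes.phonemes))


@dataclass
class AssignmentTally:
    """Counts of phoneme assignments per (subject, grapheme).

    ``counts[(subject_id, grapheme, phoneme)]`` is the number of
    standard-parse responses in which that subject parsed out that grapheme
    and assigned it that phoneme. Summing over phonemes gives the subject's
    parsed-out occurrences of the grapheme.
    """

    counts: dict[tuple[str, Grapheme, Phoneme], int] = field(default_factory=dict)

    def add(self, subject_id: str, g: Grapheme, p: Phoneme, n: int = 1) -> None:
        key = (subject_id, g, p)
        self.counts[key] = self.counts.get(key, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _, _ in self.counts})

    @property
    def graphemes(self) -> list[Grapheme]:
        return sorted({g for _, g, _ in self.counts}, key=lambda g: g.label)

    def subject_grapheme_counts(
        self, subject_id: str, g: Grapheme
    ) -> dict[Phoneme, int]:
        """Phoneme distribution (as counts) for one (subject, grapheme) cell."""
        return {
            p: n for (s, gg, p), n in self.counts.items()
            if s == subject_id and gg == g
        }

    def per_subject_totals(self) -> dict[tuple[str, Grapheme], int]:
        """Occurrences of each grapheme in each subject's standard parses."""
        out: dict[tuple[str, Grapheme], int] = {}
        for (s, g, _), n in self.counts.items():
            out[(s, g)] = out.get((s, g), 0) + n
        return out

    def pooled_counts(self, g: Grapheme) -> dict[Phoneme, int]:
        """Phoneme distribution for a grapheme pooled across subjects."""
        out: dict[Phoneme, int] = {}
        for (_, gg, p), n in self.counts.items():
            if gg == g:
                out[p] = out.get(p, 0) + n
        return out

    def restrict(self, graphemes: Iterable[Grapheme]) -> "AssignmentTally":
        keep = set(graphemes)
        return AssignmentTally(
            {k: n for k, n in self.counts.items() if k[1] in keep}
        )


def tally_assignments(
    records: Iterable[ResponseRecord], inv: GraphemeInventory
) -> AssignmentTally:
    """Aggregate grapheme-phoneme pairs over all standard-parse responses.

    Nonstandard-parse and unanalysable records contribute nothing; an empty
    tally is allowed.
    """
    tally = AssignmentTally()
    for record in records:
        if classify_parsing(record, inv).status != STANDARD:
            continue
        for g, p in align_standard(record, inv):
            tally.add(record.subject_id, g, p)
    return tally


def eligible_graphemes(
    tally: AssignmentTally,
    min_per_subject: int = 4,
    subjects: Sequence[str] | None = None,
) -> set[Grapheme]:
    """Graphemes occurring at least ``min_per_subject`` times for EVERY subject.

    The threshold gives each grapheme a reasonable chance of being read in
    different ways by each subject; the quantifier is universal, so a single
    subject below threshold excludes the grapheme.
    """
    subject_list = list(subjects) if subjects is not None else tally.subjects
    if not subject_list:
        return set()
    totals = tally.per_subject_totals()
    out: set[Grapheme] = set()
    for g in tally.graphemes:
        if all(totals.get((s, g), 0) >= min_per_subject for s in subject_list):
            out.add(g)
    return out


def classify_assignment(
    g: Grapheme, p: Phoneme, inv: GraphemeInventory
) -> str:
    """standard iff ``p`` is the inventory's standard phoneme for ``g``."""
    return STANDARD if inv.standard_phoneme(g) == p else NONSTANDARD


def status_counts(classifications: Iterable[ParseClassification]) -> Counter:
    """Counter over standard/nonstandard/unanalysable (conservation helper)."""
    return Counter(c.status for c in classifications)
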