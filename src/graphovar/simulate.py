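"""Synthetic reader-response generator with ground-truth ledger.

Emulates the study conditions the analysis assumes: a panel of skilled
readers (default 45) reading a set of monosyllabic nonwords (default 412)
aloud, with a small fraction of missing/unanalysable responses (default
2.3%). Each simulated reader owns
  * a parse-perturbation propensity — the probability of producing a
    nonstandard graphemic parsing (splitting a multi-letter grapheme into
    its constituent letters, omitting a grapheme, or inserting an extra
    phoneme), drawn per subject from the 3.16-36.65% range, and
  * a per-grapheme categorical phoneme distribution concentrated on the
    standard phoneme, with nonstandard mass drawn per subject from the
    9-31% range and spread over a few plausible alternatives.
Perturbations operate on the parse, not on the phoneme string, so the
ground-truth ledger is interpretable grapheme by grapheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .analysis import (
    NONSTANDARD,
    STANDARD,
    AssignmentTally,
    ResponseRecord,
    classify_responses,
    eligible_graphemes,
    tally_assignments,
)
from .errors import InvalidParamsError
from .inventory import Grapheme, GraphemeInventory, default_inventory
from .parsing import standard_parse
from .phonology import Phoneme
from .stats import entropy, nonstandard_rates

# ---------------------------------------------------------------------------
# parameters

_ONSETS = (
    "B BL BR C CL CR D DR F FL FR G GL GN GR H J K KN L M N P PL PR PS R "
    "S SC SCR SH SHR SK SL SM SN SP SPR ST STR SW T TH THR TR TW V W WR Z "
    "CH PH WH"
).split()
_NUCLEI = (
    "A E I O U AI AU AW EA EE EU OA OI OO OU OW OY AR ER IR OR UR"
).split()
_CODAS = (
    "B CK D F FF G K L LL M N ND NK NT NG NGE NCE P RP RK SK SP ST T TCH "
    "TH SH SS X Z LF LK LT MP"
).split()
_SPLIT_NUCLEI = (
    ("A", "E"), ("E", "E"), ("I", "E"), ("O", "E"), ("U", "E"),
    ("A", "UE"), ("I", "UE"), ("U", "UE"), ("EU", "E"), ("AI", "E"),
    ("AU", "E"), ("IE", "E"), ("OA", "E"), ("OU", "E"), ("UI", "E"),
)
_SPLIT_CODAS = "C D K L M N P R S T V Z CK SK ST RS NC SQ".split()

#: phonemes a reader may substitute for the standard one, by class
_ALT_VOWELS = "ɪ ɛ æ ʌ ɒ ʊ ə iː uː ɔː ɑː ɜː eɪ aɪ əʊ aʊ ɔɪ".split()
_ALT_CONSONANTS = "p b t d k g m n ŋ f v s z ʃ θ ʧ ʤ l r w j h".split()
#: extra phonemes available for the insertion perturbation
_INSERTIONS = "ə w j".split()


@dataclass
class SimulationParams:
    """Generator settings; the defaults are the emulated study conditions."""

    n_subjects: int = 45
    n_nonwords: int = 412
    nonwords: Sequence[str] | None = None
    p_missing: float = 0.023
    #: per-subject parse-perturbation propensity range (nonstandard parsings)
    parse_rate_range: tuple[float, float] = (0.0316, 0.3665)
    #: relative weights of split / omission / insertion among perturbations
    split_weight: float = 0.6
    omission_weight: float = 0.25
    insertion_weight: float = 0.15
    #: chance a split targets a multi-letter *vowel* grapheme when both
    #: vowel and consonant candidates exist (vowel splits dominate)
    p_vowel_split: float = 0.85
    #: per-subject nonstandard phoneme-assignment mass range
    assign_rate_range: tuple[float, float] = (0.09, 0.31)
    #: number of alternative phonemes sharing the nonstandard mass
    n_alternatives: int = 3
    #: fraction of generated nonwords built around a split vowel grapheme
    split_nucleus_fraction: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise InvalidParamsError("n_subjects must be >= 2")
        if self.n_nonwords < 1 and self.nonwords is None:
            raise InvalidParamsError("n_nonwords must be >= 1")
        for name in ("p_missing", "p_vowel_split", "split_nucleus_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParamsError(f"{name}={v} outside [0, 1]")
        for name in ("parse_rate_range", "assign_rate_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise InvalidParamsError(f"{name}=({lo}, {hi}) invalid")
        if self.split_weight + self.omission_weight + self.insertion_weight <= 0:
            raise InvalidParamsError("perturbation weights sum to zero")
        if self.n_alternatives < 1:
            raise InvalidParamsError("n_alternatives must be >= 1")


# ---------------------------------------------------------------------------
# ground truth ledger


@dataclass(frozen=True)
class LedgerEntry:
    """Latent choices behind one simulated response."""

    subject_id: str
    nonword: str
    missing: bool
    perturbation: str  # none | split | omission | insertion
    target: str  # label of the perturbed grapheme ("" if none)
    repaired: bool  # perturbation abandoned to keep phoneme counts exact
    assignments: tuple[tuple[str, str, bool], ...]  # (grapheme, ipa, standard)


@dataclass
class GroundTruth:
    """Everything the generator decided, for parameter-recovery checks."""

    params: SimulationParams
    entries: list[LedgerEntry] = field(default_factory=list)
    subject_parse_rates: dict[str, float] = field(default_factory=dict)
    subject_assign_rates: dict[str, float] = field(default_factory=dict)
    #: (subject, grapheme label) -> tuple of (ipa, probability)
    distributions: dict[tuple[str, str], tuple[tuple[str, float], ...]] = field(
        default_factory=dict
    )

    def true_entropy(self, subject_id: str, label: str) -> float:
        dist = dict(self.distributions[(subject_id, label)])
        return entropy(dist)


# ---------------------------------------------------------------------------
# nonword generation


def generate_nonwords(
    n: int,
    inv: GraphemeInventory,
    rng: np.random.Generator,
    split_fraction: float = 0.35,
) -> list[str]:
    """Build ``n`` unique parseable monosyllabic nonword spellings.

    Words are composed onset + nucleus + coda (or onset + split-vowel head +
    coda + silent tail) from the inventory's patterns, then filtered so the
    standard pronunciation tokenizes back to exactly one phoneme per
    grapheme — the bijection the analysis rests on.
    """
    from .parsing import standard_pronunciation  # local to avoid cycle at import

    out: list[str] = []
    seen: set[str] = set()
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 200 * n:
            raise InvalidParamsError(f"could not generate {n} distinct nonwords")
        onset = _ONSETS[rng.integers(len(_ONSETS))]
        if rng.random() < split_fraction:
            head, tail = _SPLIT_NUCLEI[rng.integers(len(_SPLIT_NUCLEI))]
            coda = _SPLIT_CODAS[rng.integers(len(_SPLIT_CODAS))]
            word = onset + head + coda + tail
        else:
            nucleus = _NUCLEI[rng.integers(len(_NUCLEI))]
            coda = _CODAS[rng.integers(len(_CODAS))]
            if len(nucleus) == 1 and not coda:
                continue
            word = onset + nucleus + coda
        if word in seen or len(word) > 8:
            continue
        seen.add(word)
        try:
            parse = standard_parse(word, inv)
            pron = standard_pronunciation(word, inv)
            if len(inv.phonemes.tokenize(pron.ipa)) != len(parse):
                continue
        except Exception:
            continue
        out.append(word)
    return out


# ---------------------------------------------------------------------------
# response simulation


class _SubjectProfile:
    def __init__(
        self,
        subject_id: str,
        parse_rate: float,
        assign_rate: float,
        params: SimulationParams,
        inv: GraphemeInventory,
        rng: np.random.Generator,
    ):
        self.subject_id = subject_id
        self.parse_rate = parse_rate
        self.assign_rate = assign_rate
        self.params = params
        self.inv = inv
        self.rng = rng
        # (grapheme label) -> (phoneme list, cumulative probabilities)
        self._dists: dict[str, tuple[list[Phoneme], np.ndarray]] = {}
        #: (grapheme label) -> ((ipa, probability), ...) for the ledger
        self.probs: dict[str, tuple[tuple[str, float], ...]] = {}

    def distribution(self, g: Grapheme) -> tuple[list[Phoneme], np.ndarray]:
        cached = self._dists.get(g.label)
        if cached is not None:
            return cached
        std = self.inv.standard_phoneme(g)
        pool = _ALT_VOWELS if std.is_vowel else _ALT_CONSONANTS
        alts = [ipa for ipa in pool if ipa != std.ipa]
        k = min(self.params.n_alternatives, len(alts))
        idx = self.rng.choice(len(alts), size=k, replace=False)
        phonemes = [std] + [self.inv.phonemes[alts[i]] for i in sorted(idx)]
        q = self.assign_rate
        weights = self.rng.dirichlet(np.ones(k)) * q
        probs = np.concatenate([[1.0 - q], weights])
        cum = np.cumsum(probs)
        cum[-1] = 1.0
        self._dists[g.label] = (phonemes, cum)
        self.probs[g.label] = tuple(
            (p.ipa, float(pr)) for p, pr in zip(phonemes, probs)
        )
        return phonemes, cum

    def draw_phoneme(self, g: Grapheme) -> tuple[Phoneme, bool]:
        phonemes, cum = self.distribution(g)
        i = int(np.searchsorted(cum, self.rng.random(), side="right"))
        i = min(i, len(phonemes) - 1)
        return phonemes[i], i == 0


def _choose_perturbation(
    profile: _SubjectProfile, parse, params: SimulationParams
) -> str:
    """Pick an applicable perturbation kind by the configured weights."""
    rng = profile.rng
    kinds: list[str] = []
    weights: list[float] = []
    if any(len(g.letters) >= 2 for g in parse.graphemes):
        kinds.append("split")
        weights.append(params.split_weight)
    if len(parse) >= 2:
        kinds.append("omission")
        weights.append(params.omission_weight)
    kinds.append("insertion")
    weights.append(params.insertion_weight)
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    return kinds[int(np.searchsorted(np.cumsum(w), rng.random(), side="right").clip(max=len(kinds) - 1))]


def _compose(
    profile: _SubjectProfile,
    graphemes: Sequence[Grapheme],
    insertion: tuple[int, Phoneme] | None,
) -> tuple[list[Phoneme], list[tuple[str, str, bool]]]:
    phonemes: list[Phoneme] = []
    assignments: list[tuple[str, str, bool]] = []
    for g in graphemes:
        p, is_std = profile.draw_phoneme(g)
        phonemes.append(p)
        assignments.append((g.label, p.ipa, is_std))
    if insertion is not None:
        pos, ph = insertion
        phonemes.insert(pos, ph)
    return phonemes, assignments


def simulate_responses(
    params: SimulationParams,
    inv: GraphemeInventory | None = None,
) -> tuple[list[ResponseRecord], GroundTruth]:
    """Generate a full subject x nonword response table plus its ledger.

    Deterministic for a fixed seed (byte-identical tables). Every record the
    ledger marks as perturbed is nonstandard under the count rule by
    construction, and every unperturbed non-missing record is standard; in
    the rare case where drawn phonemes would coalesce under tokenization
    (e.g. an inserted /ə/ fusing with a following /ʊ/ into a diphthong) the
    draw is retried and, failing that, the response reverts to the fully
    standard pronunciation with the ledger marked ``repaired``.
    """
    params.validate()
    inv = inv if inv is not None else default_inventory()
    rng = np.random.default_rng(params.seed)
    truth = GroundTruth(params=params)

    if params.nonwords is not None:
        nonwords = [w.strip().upper() for w in params.nonwords]
    else:
        nonwords = generate_nonwords(
            params.n_nonwords, inv, rng, params.split_nucleus_fraction
        )

    width = max(2, len(str(params.n_subjects)))
    profiles: list[_SubjectProfile] = []
    for s in range(1, params.n_subjects + 1):
        sid = f"S{s:0{width}d}"
        p = float(rng.uniform(*params.parse_rate_range))
        q = float(rng.uniform(*params.assign_rate_range))
        profiles.append(_SubjectProfile(sid, p, q, params, inv, rng))
        truth.subject_parse_rates[sid] = p
        truth.subject_assign_rates[sid] = q

    records: list[ResponseRecord] = []
    for profile in profiles:
        sid = profile.subject_id
        for word in nonwords:
            if rng.random() < params.p_missing:
                records.append(ResponseRecord(sid, word, "", analysable=False))
                truth.entries.append(
                    LedgerEntry(sid, word, True, "none", "", False, ())
                )
                continue
            parse = standard_parse(word, inv)
            graphemes: list[Grapheme] = list(parse.graphemes)
            perturbation = "none"
            target = ""
            insertion: tuple[int, Phoneme] | None = None
            if rng.random() < profile.parse_rate:
                perturbation = _choose_perturbation(profile, parse, params)
                if perturbation == "split":
                    multi = [i for i, g in enumerate(graphemes) if len(g.letters) >= 2]
                    vowels = [i for i in multi if graphemes[i].klass == "vowel"]
                    cons = [i for i in multi if graphemes[i].klass == "consonant"]
                    if vowels and (not cons or rng.random() < params.p_vowel_split):
                        pick = vowels
                    else:
                        pick = cons
                    i = pick[rng.integers(len(pick))]
                    target = graphemes[i].label
                    letters = [
                        inv.single_letter_grapheme(ch)
                        for ch in graphemes[i].letters
                    ]
                    graphemes[i : i + 1] = letters
                elif perturbation == "omission":
                    i = int(rng.integers(len(graphemes)))
                    target = graphemes[i].label
                    del graphemes[i]
                else:  # insertion (strictly between two graphemes)
                    pos = int(rng.integers(1, len(graphemes)))
                    ph = inv.phonemes[_INSERTIONS[rng.integers(len(_INSERTIONS))]]
                    insertion = (pos, ph)
                    target = f"+{ph.ipa}@{pos}"

            repaired = False
            expected = len(graphemes) + (1 if insertion else 0)
            for _attempt in range(8):
                phonemes, assignments = _compose(profile, graphemes, insertion)
                ipa = "".join(p.ipa for p in phonemes)
                if len(inv.phonemes.tokenize(ipa)) == expected:
                    break
            else:
                # revert to the fully standard response; the generated
                # nonwords guarantee it round-trips
                repaired = True
                perturbation, target, insertion = "none", "", None
                phonemes = [inv.standard_phoneme(g) for g in parse.graphemes]
                assignments = [
                    (g.label, p.ipa, True)
                    for g, p in zip(parse.graphemes, phonemes)
                ]
                ipa = "".join(p.ipa for p in phonemes)

            records.append(ResponseRecord(sid, word, f"/{ipa}/"))
            truth.entries.append(
                LedgerEntry(
                    sid, word, False, perturbation, target, repaired,
                    tuple(assignments) if perturbation == "none" else (),
                )
            )
    for profile in profiles:
        for label, dist in profile.probs.items():
            truth.distributions[(profile.subject_id, label)] = dist
    return records, truth


# ---------------------------------------------------------------------------
# parameter recovery


class SubjectRecovery(NamedTuple):
    subject_id: str
    true: float
    estimate: float
    n: int
    se: float
    within_3se: bool


@dataclass
class RecoveryReport:
    """Pipeline estimates vs generator truth, per subject."""

    parse: list[SubjectRecovery] = field(default_factory=list)
    assignment: list[SubjectRecovery] = field(default_factory=list)
    entropy_bias: float = float("nan")
    n_entropy_cells: int = 0

    @staticmethod
    def _coverage(rows: list[SubjectRecovery]) -> float:
        return sum(r.within_3se for r in rows) / len(rows) if rows else float("nan")

    @property
    def parse_coverage(self) -> float:
        return self._coverage(self.parse)

    @property
    def assignment_coverage(self) -> float:
        return self._coverage(self.assignment)

    @property
    def parse_bias(self) -> float:
        return float(np.mean([r.estimate - r.true for r in self.parse]))

    @property
    def assignment_bias(self) -> float:
        return float(np.mean([r.estimate - r.true for r in self.assignment]))


def _recover_rows(
    rates: dict[str, "object"], truths: dict[str, float]
) -> list[SubjectRecovery]:
    rows = []
    for sid, rate in rates.items():
        p = truths[sid]
        n = rate.denominator
        se = float(np.sqrt(p * (1 - p) / n)) if n else float("inf")
        est = rate.pct / 100.0
        rows.append(
            SubjectRecovery(sid, p, est, n, se, abs(est - p) <= 3 * se)
        )
    return rows


def recover_parameters(
    records: Iterable[ResponseRecord],
    truth: GroundTruth,
    inv: GraphemeInventory | None = None,
    min_per_subject: int = 4,
    min_entropy_cell: int = 4,
) -> RecoveryReport:
    """Run the full pipeline and compare estimates with the ledger truth.

    Per-subject nonstandard-parsing and nonstandard-assignment rates are
    compared with the generative propensities (within three binomial
    standard errors at the subject's own denominator); plug-in entropies of
    tally cells with at least ``min_entropy_cell`` occurrences are compared
    with the entropy of the subject's true assignment distribution.
    """
    inv = inv if inv is not None else default_inventory()
    records = list(records)
    classifications = classify_responses(records, inv)
    tally = tally_assignments(records, inv)
    rates = nonstandard_rates(classifications, tally, inv)

    report = RecoveryReport()
    report.parse = _recover_rows(
        rates.subject_parsing_rates, truth.subject_parse_rates
    )
    report.assignment = _recover_rows(
        rates.subject_assignment_rates, truth.subject_assign_rates
    )

    biases: list[float] = []
    totals = tally.per_subject_totals()
    for (sid, g), n in totals.items():
        if n < min_entropy_cell or (sid, g.label) not in truth.distributions:
            continue
        est_h = entropy(tally.subject_grapheme_counts(sid, g))
        true_h = truth.true_entropy(sid, g.label)
        biases.append(est_h - true_h)
    if biases:
        report.entropy_bias = float(np.mean(biases))
        report.n_entropy_cells = len(biases)
    return report
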