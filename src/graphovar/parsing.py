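"""Graphemic parsing: standard parse, exhaustive enumeration, response aligner.

The standard parse of a letter string is deterministic: any applicable
split-vowel pattern (vowel head ... 1-2 coda consonant letters ... final
E/UE tail) is bound first, then the remaining letters are segmented left to
right by maximal munch — longest pattern first, then context-specific over
generic rules, then the rule file's precedence rank. This reproduces parses
such as GNEUTH -> GN,EU,TH and SCROME -> S,C,R,O.E,M.

One refinement governs the competition for a word-final silent E: when the
split head is separated from the E by two consonants and the last of those
consonants forms a word-final grapheme with the E (GE, CE), the final
grapheme wins and the split vowel is not bound. Hence DONGE -> D,O,N,GE
(not D,O.E,N,G) while STOARSE -> S,T,OA.E,R,S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import AlignmentError, NoParseError
from .inventory import VOWEL_LETTERS, GPCRule, Grapheme, GraphemeInventory
from .phonology import Phoneme, PhonemeString

Span = tuple[int, int]


@dataclass(frozen=True)
class ParsedGrapheme:
    """One grapheme occurrence with its letter span(s) in the stimulus.

    A split grapheme owns two spans: the head and the word-final tail.
    """

    grapheme: Grapheme
    spans: tuple[Span, ...]

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def n_letters(self) -> int:
        return sum(e - s for s, e in self.spans)


@dataclass(frozen=True)
class Parsing:
    """An ordered segmentation of a letter string into graphemes.

    Invariant: the spans cover every letter of the stimulus exactly once.
    """

    stimulus: str
    elements: tuple[ParsedGrapheme, ...]

    def __post_init__(self) -> None:
        covered: list[int] = []
        for el in self.elements:
            for s, e in el.spans:
                covered.extend(range(s, e))
        if sorted(covered) != list(range(len(self.stimulus))):
            raise ValueError(
                f"spans do not cover {self.stimulus!r} exactly once: {self.elements}"
            )

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def graphemes(self) -> tuple[Grapheme, ...]:
        return tuple(el.grapheme for el in self.elements)

    @property
    def patterns(self) -> tuple[str, ...]:
        return tuple(g.pattern for g in self.graphemes)

    @property
    def signature(self) -> tuple:
        """Hashable identity used for deduplication and ordering."""
        return tuple((el.grapheme.pattern, el.spans) for el in self.elements)

    def __str__(self) -> str:
        return "+".join(self.patterns)


class ParseList(list):
    """A list of parses with a flag marking truncation at max_count."""

    truncated: bool = False


# ---------------------------------------------------------------------------
# split-vowel binding


@dataclass(frozen=True)
class _SplitBinding:
    rule: GPCRule
    head_span: Span
    tail_span: Span
    blocked: bool  # loses the final-E competition to GE/CE

    @property
    def reserved(self) -> frozenset[int]:
        return frozenset(
            list(range(*self.head_span)) + list(range(*self.tail_span))
        )

    def element(self) -> ParsedGrapheme:
        return ParsedGrapheme(self.rule.grapheme, (self.head_span, self.tail_span))


def _split_candidates(word: str, inv: GraphemeInventory) -> list[_SplitBinding]:
    """All structurally valid split-vowel bindings, preferred order first.

    A binding requires the tail at word end, the head strictly before it,
    and 1-2 intervening consonant letters. Preference: longer head, then
    leftmost head.
    """
    out: list[_SplitBinding] = []
    n = len(word)
    for rule in inv.split_rules:
        g = rule.grapheme
        head, tail = g.head, g.tail
        if not word.endswith(tail):
            continue
        tail_span = (n - len(tail), n)
        limit = tail_span[0] - len(head)  # head must leave >=1 intervening letter
        for i in range(0, limit):
            if word[i : i + len(head)] != head:
                continue
            between = word[i + len(head) : tail_span[0]]
            if not (1 <= len(between) <= 2):
                continue
            if any(c in VOWEL_LETTERS for c in between):
                continue
            if not g.position_ok(word, i, i + len(head)):
                continue
            blocked = (
                tail == "E"
                and len(between) == 2
                and between[-1] + "E" in inv.final_e_claimers
            )
            out.append(
                _SplitBinding(rule, (i, i + len(head)), tail_span, blocked)
            )
    out.sort(key=lambda b: (-(b.head_span[1] - b.head_span[0]), b.head_span[0],
                            b.rule.grapheme.pattern))
    return out


# ---------------------------------------------------------------------------
# maximal munch


def _candidates_at(
    word: str, i: int, reserved: frozenset[int], inv: GraphemeInventory
) -> list[tuple[int, GPCRule]]:
    """Applicable contiguous rules matching at position i, best first.

    Order: longer pattern, then context-specific over generic, then
    precedence rank (ties broken by pattern for determinism).
    """
    found: list[tuple[int, GPCRule]] = []
    for rule in inv.contiguous_rules:
        g = rule.grapheme
        L = len(g.pattern)
        j = i + L
        if j > len(word) or word[i:j] != g.pattern:
            continue
        if any(k in reserved for k in range(i, j)):
            continue
        if not (g.position_ok(word, i, j) and g.context_ok(word, i, j)):
            continue
        found.append((L, rule))
    found.sort(
        key=lambda t: (-t[0], t[1].grapheme.context == "", t[1].precedence,
                       t[1].grapheme.pattern)
    )
    return found


def _munch(
    word: str, reserved: frozenset[int], inv: GraphemeInventory
) -> list[ParsedGrapheme]:
    out: list[ParsedGrapheme] = []
    i = 0
    n = len(word)
    while i < n:
        if i in reserved:
            i += 1
            continue
        cands = _candidates_at(word, i, reserved, inv)
        if not cands:
            raise NoParseError(
                f"no grapheme of {inv.name!r} covers {word!r} at position {i}"
            )
        L, rule = cands[0]
        out.append(ParsedGrapheme(rule.grapheme, ((i, i + L),)))
        i += L
    return out


def _std_cache(inv: GraphemeInventory) -> dict:
    cache = getattr(inv, "_standard_parse_cache", None)
    if cache is None:
        cache = {}
        setattr(inv, "_standard_parse_cache", cache)
    return cache


def standard_parse(stimulus: str, inv: GraphemeInventory) -> Parsing:
    """The deterministic standard graphemic parse of ``stimulus``."""
    word = stimulus.strip().upper()
    if not word or not word.isalpha():
        raise NoParseError(f"stimulus must be non-empty A-Z letters: {stimulus!r}")
    cache = _std_cache(inv)
    hit = cache.get(word)
    if hit is not None:
        return hit
    binding = next(
        (b for b in _split_candidates(word, inv) if not b.blocked), None
    )
    if binding is None:
        elements = _munch(word, frozenset(), inv)
    else:
        elements = _munch(word, binding.reserved, inv) + [binding.element()]
        elements.sort(key=lambda el: el.start)
    parse = Parsing(word, tuple(elements))
    cache[word] = parse
    return parse


def standard_pronunciation(stimulus: str, inv: GraphemeInventory) -> PhonemeString:
    """Standard phoneme of each grapheme of the standard parse, in order."""
    parse = standard_parse(stimulus, inv)
    phonemes = tuple(inv.standard_phoneme(g) for g in parse.graphemes)
    return PhonemeString(phonemes, "".join(p.ipa for p in phonemes))


# ---------------------------------------------------------------------------
# exhaustive enumeration


def _enumerate_contiguous(
    word: str, reserved: frozenset[int], inv: GraphemeInventory, limit: int
) -> list[list[ParsedGrapheme]]:
    """All segmentations of the unreserved letters into contiguous graphemes.

    At a given (position, length) at most one pattern can match, so the
    branching is over match lengths; among rules for the same span the best
    one (munch order) represents the segment.
    """
    n = len(word)
    results: list[list[ParsedGrapheme]] = []

    def rec(i: int, acc: list[ParsedGrapheme]) -> None:
        if len(results) >= limit:
            return
        while i < n and i in reserved:
            i += 1
        if i == n:
            results.append(list(acc))
            return
        seen_lengths = set()
        for L, rule in _candidates_at(word, i, reserved, inv):
            if L in seen_lengths:
                continue  # same span: best rule already taken
            seen_lengths.add(L)
            acc.append(ParsedGrapheme(rule.grapheme, ((i, i + L),)))
            rec(i + L, acc)
            acc.pop()

    rec(0, [])
    return results


def enumerate_parses(
    stimulus: str, inv: GraphemeInventory, max_count: int = 1000
) -> ParseList:
    """All distinct graphemic segmentations, standard parse first.

    Split-vowel patterns are optional: every binding (including those the
    standard parse rejects in the final-E competition) is explored as well
    as the unbound segmentation. Truncated at ``max_count`` with the
    returned list's ``truncated`` flag set.
    """
    word = stimulus.strip().upper()
    if not word or not word.isalpha():
        raise NoParseError(f"stimulus must be non-empty A-Z letters: {stimulus!r}")
    try:
        std = standard_parse(word, inv)
    except NoParseError:
        std = None
    seen: set[tuple] = set()
    parses: list[Parsing] = []
    truncated = False

    bindings: list[_SplitBinding | None] = [None]
    bindings.extend(_split_candidates(word, inv))
    for binding in bindings:
        reserved = binding.reserved if binding else frozenset()
        extra = [binding.element()] if binding else []
        budget = max_count + 1 - len(parses)
        if budget <= 0:
            truncated = True
            break
        for seg in _enumerate_contiguous(word, reserved, inv, budget):
            elements = sorted(seg + extra, key=lambda el: el.start)
            parse = Parsing(word, tuple(elements))
            if parse.signature in seen:
                continue
            seen.add(parse.signature)
            parses.append(parse)

    if not parses:
        raise NoParseError(f"{word!r} has no parse under {inv.name!r}")
    if std is not None and std.signature in seen:
        parses = [p for p in parses if p.signature != std.signature]
        parses.sort(key=lambda p: (len(p), p.signature))
        parses = [std] + parses
    else:
        parses.sort(key=lambda p: (len(p), p.signature))
    if len(parses) > max_count:
        parses = parses[:max_count]
        truncated = True
    out = ParseList(parses)
    out.truncated = truncated
    return out


# ---------------------------------------------------------------------------
# response-to-parse alignment (diagnostic)


@dataclass(frozen=True)
class EditCosts:
    """Edit costs for the stimulus-response aligner.

    A standard grapheme-phoneme match is free; assigning a nonstandard
    phoneme is a substitution (dearer when the phoneme's vowel/consonant
    class disagrees with the grapheme's, a rarer reading); a grapheme with
    no response phoneme is an omission; a response phoneme with no grapheme
    support is an insertion. Insertions cost more than omissions so that an
    unsupported phoneme is dispreferred to reading a multi-letter vowel
    grapheme as its constituent letters.
    """

    match: float = 0.0
    substitution: float = 1.0
    substitution_mismatch: float = 1.25
    omission: float = 2.0
    insertion: float = 2.5

    def sub_cost(self, grapheme: Grapheme, phoneme: Phoneme) -> float:
        same_class = (grapheme.klass == "vowel") == phoneme.is_vowel
        return self.substitution if same_class else self.substitution_mismatch


@dataclass(frozen=True)
class EditOp:
    kind: str  # match | substitution | omission | insertion
    grapheme: Grapheme | None = None
    phoneme: Phoneme | None = None


@dataclass(frozen=True)
class InferredParse:
    """Best-scoring parse + grapheme-phoneme mapping for a response."""

    parsing: Parsing
    ops: tuple[EditOp, ...]
    cost: float

    @property
    def n_substitutions(self) -> int:
        return sum(op.kind == "substitution" for op in self.ops)

    @property
    def n_omissions(self) -> int:
        return sum(op.kind == "omission" for op in self.ops)

    @property
    def n_insertions(self) -> int:
        return sum(op.kind == "insertion" for op in self.ops)


def _align(
    parse: Parsing,
    response: PhonemeString,
    inv: GraphemeInventory,
    costs: EditCosts,
) -> tuple[float, tuple[EditOp, ...]]:
    gs = parse.graphemes
    ps = response.phonemes
    n, m = len(gs), len(ps)
    INF = float("inf")
    dp = [[INF] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            cur = dp[i][j]
            if cur == INF:
                continue
            if i < n and j < m:
                std = inv.standard_phoneme(gs[i])
                step = costs.match if ps[j] == std else costs.sub_cost(gs[i], ps[j])
                if cur + step < dp[i + 1][j + 1]:
                    dp[i + 1][j + 1] = cur + step
            if i < n and cur + costs.omission < dp[i + 1][j]:
                dp[i + 1][j] = cur + costs.omission
            if j < m and cur + costs.insertion < dp[i][j + 1]:
                dp[i][j + 1] = cur + costs.insertion
    # traceback (prefer diagonal, then omission, then insertion)
    ops: list[EditOp] = []
    i, j = n, m
    while i > 0 or j > 0:
        cur = dp[i][j]
        if i > 0 and j > 0:
            std = inv.standard_phoneme(gs[i - 1])
            step = (costs.match if ps[j - 1] == std
                    else costs.sub_cost(gs[i - 1], ps[j - 1]))
            if abs(dp[i - 1][j - 1] + step - cur) < 1e-9:
                kind = "match" if ps[j - 1] == std else "substitution"
                ops.append(EditOp(kind, gs[i - 1], ps[j - 1]))
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(dp[i - 1][j] + costs.omission - cur) < 1e-9:
            ops.append(EditOp("omission", gs[i - 1], None))
            i -= 1
            continue
        ops.append(EditOp("insertion", None, ps[j - 1]))
        j -= 1
    ops.reverse()
    return dp[n][m], tuple(ops)


def infer_parse(
    stimulus: str,
    response: PhonemeString,
    inv: GraphemeInventory,
    costs: EditCosts | None = None,
    max_parses: int = 200,
    ceiling: float | None = None,
) -> InferredParse:
    """Infer the graphemic parsing a response implies (diagnostic).

    Dynamic-programming alignment of every candidate segmentation against
    the response phonemes, minimizing total edit cost; ties break toward the
    parse closest to the standard parse. Raises :class:`AlignmentError` if
    the best cost exceeds ``ceiling``.
    """
    costs = costs or EditCosts()
    std = standard_parse(stimulus, inv)
    std_sig = set(std.signature)
    best: tuple | None = None
    for parse in enumerate_parses(stimulus, inv, max_count=max_parses):
        cost, ops = _align(parse, response, inv, costs)
        shared = len(std_sig & set(parse.signature))
        key = (cost, parse.signature != std.signature, -shared, parse.signature)
        if best is None or key < best[0]:
            best = (key, parse, ops, cost)
    assert best is not None
    _, parse, ops, cost = best
    if ceiling is not None and cost > ceiling:
        raise AlignmentError(
            f"best alignment for {stimulus!r} ~ /{response.ipa}/ costs "
            f"{cost:.2f} > ceiling {ceiling:.2f}"
        )
    return InferredParse(parse, ops, cost)
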