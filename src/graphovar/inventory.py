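"""Grapheme inventory: GPC rules, standard phonemes, lexicon-based derivation.

A grapheme is the written representation of a single phoneme. It may span
several letters (SH, GN, AU) and may be discontinuous: a split vowel
grapheme such as O.E in STOLE owns a head (O) and a word-final silent tail
(E) separated by coda consonants. Each rule pairs a grapheme — a spelling
pattern plus positional and letter-context conditions — with its *standard*
phoneme, the phoneme that corresponds to that grapheme most often in the
monosyllabic words of English.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    DuplicateRuleError,
    EmptyLexiconError,
    InventoryFormatError,
    MissingGraphemeError,
)
from .phonology import (
    Phoneme,
    PhonemeInventory,
    PhonemeString,
    default_phoneme_inventory,
)

logger = logging.getLogger(__name__)

VOWEL_LETTERS = frozenset("AEIOU")

POSITIONS = ("any", "onset", "coda", "initial", "final")


@dataclass(frozen=True)
class Grapheme:
    """A spelling pattern with position/context conditions.

    ``pattern`` contains only A-Z and at most one ``.`` separating the head
    letters of a split vowel grapheme from its word-final silent tail (E or
    UE). Context conditions are limited to membership tests on the adjacent
    raw letters: ``next=E,I,Y`` / ``prev=...``; ``#`` denotes a word edge.
    """

    pattern: str
    position: str = "any"
    context: str = ""
    klass: str = "consonant"

    def __post_init__(self) -> None:
        body = self.pattern.replace(".", "")
        if not body or not body.isalpha() or not body.isupper():
            raise ValueError(f"bad grapheme pattern {self.pattern!r}")
        if self.pattern.count(".") > 1:
            raise ValueError(f"more than one gap in {self.pattern!r}")
        if self.is_split and self.tail not in ("E", "UE"):
            raise ValueError(f"split tail must be E or UE: {self.pattern!r}")
        if self.position not in POSITIONS:
            raise ValueError(f"bad position {self.position!r}")

    @property
    def is_split(self) -> bool:
        return "." in self.pattern

    @property
    def head(self) -> str:
        return self.pattern.split(".")[0]

    @property
    def tail(self) -> str:
        return self.pattern.split(".")[1] if self.is_split else ""

    @property
    def letters(self) -> str:
        """The letters the grapheme owns, gap removed."""
        return self.pattern.replace(".", "")

    @property
    def label(self) -> str:
        """Display/tally key: pattern, with any context condition appended."""
        return self.pattern if not self.context else f"{self.pattern}({self.context})"

    def __str__(self) -> str:  # pragma: no cover
        return self.label

    # -- condition checks on a concrete occurrence ------------------------

    def position_ok(self, word: str, start: int, end: int) -> bool:
        """Does the position constraint hold for a match at word[start:end]?"""
        if self.position == "any":
            return True
        if self.position == "initial":
            return start == 0
        if self.position == "final":
            return end == len(word)
        before = word[:start]
        has_vowel_before = any(c in VOWEL_LETTERS for c in before)
        if self.position == "onset":
            return not has_vowel_before
        if self.position == "coda":
            return has_vowel_before
        return False  # pragma: no cover

    def context_ok(self, word: str, start: int, end: int) -> bool:
        if not self.context:
            return True
        kind, _, letters = self.context.partition("=")
        allowed = {x.strip() for x in letters.split(",")}
        if kind == "next":
            nxt = word[end] if end < len(word) else "#"
            return nxt in allowed
        if kind == "prev":
            prv = word[start - 1] if start > 0 else "#"
            return prv in allowed
        raise ValueError(f"bad context {self.context!r}")


@dataclass(frozen=True)
class GPCRule:
    """One grapheme-phoneme correspondence with its precedence rank."""

    grapheme: Grapheme
    standard_phoneme: Phoneme
    precedence: int = 50

    def __post_init__(self) -> None:
        want = "vowel" if self.standard_phoneme.is_vowel else "consonant"
        if self.grapheme.klass != want:
            raise ValueError(
                f"grapheme {self.grapheme.label} class {self.grapheme.klass} "
                f"does not match phoneme /{self.standard_phoneme.ipa}/"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        g = self.grapheme
        return (g.pattern, g.position, g.context)


class GraphemeInventory:
    """A validated set of GPC rules.

    Invariant: exactly one rule per (pattern, position, context) triple, and
    every single letter A-Z is covered by at least one rule, so every legal
    letter string has at least one parse.
    """

    def __init__(
        self,
        rules: Iterable[GPCRule],
        name: str = "inventory",
        phoneme_inventory: PhonemeInventory | None = None,
        require_full_alphabet: bool = True,
    ):
        self.name = name
        self.phonemes = (
            phoneme_inventory
            if phoneme_inventory is not None
            else default_phoneme_inventory()
        )
        self.rules: list[GPCRule] = []
        self._by_key: dict[tuple[str, str, str], GPCRule] = {}
        self._by_grapheme: dict[Grapheme, GPCRule] = {}
        for rule in rules:
            if rule.key in self._by_key:
                raise DuplicateRuleError(
                    f"duplicate rule for {rule.key}", line=None
                )
            self.rules.append(rule)
            self._by_key[rule.key] = rule
            self._by_grapheme[rule.grapheme] = rule
        missing = sorted(
            {chr(c) for c in range(65, 91)}
            - {r.grapheme.pattern for r in self.rules if len(r.grapheme.pattern) == 1 and not r.grapheme.context}
        )
        if missing and require_full_alphabet:
            raise InventoryFormatError(
                f"letters not covered by any context-free single-letter rule: {missing}"
            )
        self.split_rules = [r for r in self.rules if r.grapheme.is_split]
        self.contiguous_rules = [r for r in self.rules if not r.grapheme.is_split]
        #: word-final consonant graphemes whose pattern ends in E (GE, CE):
        #: they compete with split-vowel binding for the final silent E.
        self.final_e_claimers = {
            r.grapheme.pattern
            for r in self.contiguous_rules
            if r.grapheme.position == "final"
            and r.grapheme.klass == "consonant"
            and r.grapheme.pattern.endswith("E")
        }
        self._single_plain = {
            r.grapheme.pattern: r.grapheme
            for r in self.contiguous_rules
            if len(r.grapheme.pattern) == 1 and not r.grapheme.context
        }

    def __len__(self) -> int:
        return len(self.rules)

    def __contains__(self, g: Grapheme) -> bool:
        return g in self._by_grapheme

    def __iter__(self):
        return iter(self.rules)

    def rule_for(self, g: Grapheme) -> GPCRule:
        try:
            return self._by_grapheme[g]
        except KeyError:
            raise MissingGraphemeError(f"no rule for grapheme {g.label}") from None

    def standard_phoneme(self, g: Grapheme) -> Phoneme:
        """The standard phoneme for ``g`` (pure lookup)."""
        return self.rule_for(g).standard_phoneme

    def find(self, pattern: str) -> Grapheme:
        """First grapheme with this pattern (context-free preferred)."""
        candidates = [r.grapheme for r in self.rules if r.grapheme.pattern == pattern]
        if not candidates:
            raise MissingGraphemeError(f"no grapheme with pattern {pattern!r}")
        candidates.sort(key=lambda g: (g.context != "", g.position != "any"))
        return candidates[0]

    def single_letter_grapheme(self, letter: str) -> Grapheme:
        """The context-free single-letter grapheme for ``letter``."""
        try:
            return self._single_plain[letter]
        except KeyError:
            raise MissingGraphemeError(f"no single-letter rule for {letter!r}") from None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        phoneme_inventory: PhonemeInventory | None = None,
        name: str | None = None,
    ) -> "GraphemeInventory":
        phinv = (
            phoneme_inventory
            if phoneme_inventory is not None
            else default_phoneme_inventory()
        )
        rules: list[GPCRule] = []
        seen: dict[tuple[str, str, str], int] = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1
        ):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise InventoryFormatError(
                    f"expected 6 tab-separated fields, got {len(fields)}", line=lineno
                )
            pattern, klass, position, context, ipa, prec = fields
            context = "" if context == "-" else context
            ph = phinv.get(ipa)
            if ph is None:
                raise InventoryFormatError(
                    f"unknown phoneme {ipa!r}", line=lineno
                )
            try:
                g = Grapheme(pattern, position, context, klass)
                rule = GPCRule(g, ph, int(prec))
            except ValueError as exc:
                raise InventoryFormatError(str(exc), line=lineno) from exc
            if rule.key in seen:
                raise DuplicateRuleError(
                    f"duplicate rule for {rule.key} (first at line {seen[rule.key]})",
                    line=lineno,
                )
            seen[rule.key] = lineno
            rules.append(rule)
        return cls(rules, name=name or Path(path).stem, phoneme_inventory=phinv)


def load_inventory(
    path: str | Path, phoneme_inventory: PhonemeInventory | None = None
) -> GraphemeInventory:
    """Load and validate a GPC rule file."""
    return GraphemeInventory.from_file(path, phoneme_inventory)


_default: GraphemeInventory | None = None


def default_inventory() -> GraphemeInventory:
    """The shipped DRC-style English rule table (cached)."""
    global _default
    if _default is None:
        with resources.as_file(
            resources.files("graphovar.data") / "gpc_rules.tsv"
        ) as path:
            _default = GraphemeInventory.from_file(path, name="default-english")
    return _default


def standard_phoneme(inv: GraphemeInventory, g: Grapheme) -> Phoneme:
    """Module-level convenience wrapper for :meth:`GraphemeInventory.standard_phoneme`."""
    return inv.standard_phoneme(g)


def derive_standard_assignments(
    lexicon: Sequence[tuple[str, PhonemeString | str]],
    inv: GraphemeInventory,
) -> GraphemeInventory:
    """Re-derive standard phonemes by majority over an aligned word lexicon.

    Each lexicon word is parsed with the inventory's standard parse; words
    whose grapheme count differs from their phoneme count cannot be aligned
    one-to-one and are skipped (and logged). For every grapheme, the phoneme
    observed most often across word *types* (not token frequency) replaces
    the rule's standard phoneme, with candidates restricted to the
    grapheme's class so vowel graphemes keep vowel phonemes. Ties break by
    the phoneme's summed count across all graphemes, then lexicographic IPA
    (deterministic and auditable). The input inventory is unchanged.
    """
    from .parsing import standard_parse  # deferred: parsing depends on inventory

    if not lexicon:
        raise EmptyLexiconError("empty lexicon")

    counts: dict[Grapheme, dict[Phoneme, int]] = {}
    global_counts: dict[Phoneme, int] = {}
    usable = 0
    for spelling, pron in lexicon:
        word = spelling.strip().upper()
        ps = pron if isinstance(pron, PhonemeString) else inv.phonemes.tokenize(pron)
        try:
            parse = standard_parse(word, inv)
        except Exception:
            logger.warning("lexicon word %s does not parse; skipped", word)
            continue
        if len(parse.graphemes) != len(ps):
            logger.warning(
                "lexicon word %s: %d graphemes vs %d phonemes; skipped",
                word, len(parse.graphemes), len(ps),
            )
            continue
        usable += 1
        for g, p in zip(parse.graphemes, ps):
            counts.setdefault(g, {})[p] = counts.setdefault(g, {}).get(p, 0) + 1
            global_counts[p] = global_counts.get(p, 0) + 1
    if usable == 0:
        raise EmptyLexiconError("no lexicon word could be aligned")

    new_rules: list[GPCRule] = []
    for rule in inv.rules:
        g = rule.grapheme
        cell = counts.get(g)
        if not cell:
            new_rules.append(rule)
            continue
        candidates = [
            (p, c) for p, c in cell.items()
            if ("vowel" if p.is_vowel else "consonant") == g.klass
        ]
        if not candidates:
            new_rules.append(rule)
            continue
        best_count = max(c for _, c in candidates)
        top = [p for p, c in candidates if c == best_count]
        if len(top) > 1:
            logger.warning(
                "majority tie for grapheme %s among %s; breaking by global count",
                g.label, sorted(p.ipa for p in top),
            )
            top.sort(key=lambda p: (-global_counts.get(p, 0), p.ipa))
        new_rules.append(replace(rule, standard_phoneme=top[0]))
    return GraphemeInventory(
        new_rules, name=f"{inv.name}+lexicon", phoneme_inventory=inv.phonemes
    )
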