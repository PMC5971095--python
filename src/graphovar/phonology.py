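"""Phoneme inventory and IPA tokenization.

The unit of analysis throughout the package is the phoneme: a diphthong
(/aɪ/) or an affricate (/ʧ/) counts as one phoneme, exactly as it does in
the grapheme definition ("the written representation of a phoneme").
Transcriptions are tokenized by greedy longest match over a fixed
General-English monosyllable inventory; the inventory is prefix-ambiguous
only between a multi-character phoneme and its first character, so greedy
matching is sufficient and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import InventoryFormatError, TokenizationError, UnknownSymbolError

VOWEL = "vowel"
CONSONANT = "consonant"

#: Characters removed before tokenization: transcription delimiters, stress
#: marks (monosyllables carry no contrastive stress), whitespace, brackets.
_STRIP_CHARS = set("/[]()ˈˌ'‿ \t\r\n")


@dataclass(frozen=True)
class Phoneme:
    """A single phoneme: canonical IPA string plus vowel/consonant class."""

    ipa: str
    klass: str  # "vowel" | "consonant"

    def __post_init__(self) -> None:
        if self.klass not in (VOWEL, CONSONANT):
            raise ValueError(f"bad phoneme class {self.klass!r}")

    @property
    def is_vowel(self) -> bool:
        return self.klass == VOWEL

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.ipa


@dataclass(frozen=True)
class PhonemeString:
    """An ordered phoneme sequence together with its source transcription."""

    phonemes: tuple[Phoneme, ...]
    source: str

    def __len__(self) -> int:
        return len(self.phonemes)

    def __iter__(self) -> Iterator[Phoneme]:
        return iter(self.phonemes)

    def __getitem__(self, i):
        return self.phonemes[i]

    @property
    def ipa(self) -> str:
        """Canonical slash-free concatenation of the tokens."""
        return "".join(p.ipa for p in self.phonemes)


class PhonemeInventory:
    """The fixed phoneme alphabet plus alias spellings.

    Aliases (e.g. ``tʃ`` for ``ʧ``, ``ɡ`` for ``g``) are accepted on input
    and normalized to the canonical form; they are the extension point if a
    data file uses a different IPA coding.
    """

    def __init__(self, entries: Iterable[tuple[Phoneme, tuple[str, ...]]]):
        self.phonemes: list[Phoneme] = []
        self.by_ipa: dict[str, Phoneme] = {}
        # surface string (canonical or alias) -> canonical phoneme
        self._match: dict[str, Phoneme] = {}
        for ph, aliases in entries:
            if ph.ipa in self.by_ipa:
                raise InventoryFormatError(f"duplicate phoneme {ph.ipa!r}")
            self.phonemes.append(ph)
            self.by_ipa[ph.ipa] = ph
            for surface in (ph.ipa, *aliases):
                if surface in self._match and self._match[surface] != ph:
                    raise InventoryFormatError(
                        f"surface form {surface!r} maps to two phonemes"
                    )
                self._match[surface] = ph
        self._maxlen = max(len(s) for s in self._match)

    def __contains__(self, ipa: str) -> bool:
        return ipa in self.by_ipa

    def __getitem__(self, ipa: str) -> Phoneme:
        return self.by_ipa[ipa]

    def get(self, ipa: str) -> Phoneme | None:
        return self.by_ipa.get(ipa)

    @property
    def vowels(self) -> list[Phoneme]:
        return [p for p in self.phonemes if p.is_vowel]

    @property
    def consonants(self) -> list[Phoneme]:
        return [p for p in self.phonemes if not p.is_vowel]

    # -- tokenization -----------------------------------------------------

    def clean(self, transcription: str) -> str:
        """Strip delimiters/stress and normalize length-mark spelling."""
        text = transcription.replace(":", "ː")
        return "".join(ch for ch in text if ch not in _STRIP_CHARS)

    def tokenize(self, transcription: str) -> PhonemeString:
        """Greedy longest-match tokenization of an IPA transcription.

        Every character of the cleaned string must be consumed; an unknown
        symbol aborts tokenization (silent skipping would corrupt phoneme
        counts, the core measure of the analysis).
        """
        cleaned = self.clean(transcription)
        if not cleaned:
            raise TokenizationError(
                f"empty transcription after cleaning: {transcription!r}"
            )
        out: list[Phoneme] = []
        i = 0
        n = len(cleaned)
        while i < n:
            for length in range(min(self._maxlen, n - i), 0, -1):
                ph = self._match.get(cleaned[i : i + length])
                if ph is not None:
                    out.append(ph)
                    i += length
                    break
            else:
                raise UnknownSymbolError(cleaned[i], i, transcription)
        return PhonemeString(tuple(out), transcription)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "PhonemeInventory":
        entries: list[tuple[Phoneme, tuple[str, ...]]] = []
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InventoryFormatError("expected ipa<TAB>class", line=lineno)
            ipa, klass = fields[0], fields[1]
            if klass not in (VOWEL, CONSONANT):
                raise InventoryFormatError(f"bad class {klass!r}", line=lineno)
            aliases: tuple[str, ...] = ()
            if len(fields) > 2 and fields[2]:
                aliases = tuple(a.strip() for a in fields[2].split(",") if a.strip())
            entries.append((Phoneme(ipa, klass), aliases))
        return cls(entries)


_default: PhonemeInventory | None = None


def default_phoneme_inventory() -> PhonemeInventory:
    """The shipped General-English inventory (cached)."""
    global _default
    if _default is None:
        with resources.as_file(
            resources.files("graphovar.data") / "phonemes.tsv"
        ) as path:
            _default = PhonemeInventory.from_file(path)
    return _default


def tokenize_phonemes(
    transcription: str, inventory: PhonemeInventory | None = None
) -> PhonemeString:
    """Tokenize an IPA transcription string into a :class:`PhonemeString`."""
    inv = inventory if inventory is not None else default_phoneme_inventory()
    return inv.tokenize(transcription)
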