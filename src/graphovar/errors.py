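"""Exception hierarchy for graphovar.

All package-raised errors derive from :class:`GraphovarError` so callers can
catch the package's failures with a single except clause while letting
programming errors propagate.
"""

from __future__ import annotations


class GraphovarError(Exception):
    """Base class for all graphovar errors."""


class TokenizationError(GraphovarError):
    """A transcription could not be tokenized into phonemes."""


class UnknownSymbolError(TokenizationError):
    """A character in a transcription is outside the phoneme inventory.

    Carries the offending character and its offset in the cleaned string so a
    record can be flagged unanalysable with a precise diagnostic.
    """

    def __init__(self, symbol: str, offset: int, source: str = ""):
        self.symbol = symbol
        self.offset = offset
        self.source = source
        super().__init__(
            f"unknown symbol {symbol!r} at offset {offset} in {source!r}"
        )


class InventoryFormatError(GraphovarError):
    """A rule or phoneme file is malformed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateRuleError(InventoryFormatError):
    """Two rules share the same (pattern, position, context) triple."""


class MissingGraphemeError(GraphovarError):
    """A grapheme was looked up that the inventory does not contain."""


class NoParseError(GraphovarError):
    """A letter string admits no segmentation into inventory graphemes."""


class AlignmentError(GraphovarError):
    """No stimulus-response alignment below the cost ceiling exists."""


class EmptyLexiconError(GraphovarError):
    """A lexicon-driven derivation was requested with no usable words."""


class InvalidParamsError(GraphovarError):
    """Simulation parameters violate their documented ranges."""


class AnalysisError(GraphovarError):
    """An internal conservation check failed while building a report."""
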