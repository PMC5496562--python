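"""Exception hierarchy for the dtsb package."""

from __future__ import annotations

from collections.abc import Iterable


class DTSBError(Exception):
    """Base class for all dtsb-specific errors."""


class NotAlignedError(DTSBError, ValueError):
    """Input records do not form a rectangular alignment."""


class NoCommonRegionError(DTSBError, ValueError):
    """No alignment column is covered by every sequence."""


class IndistinguishableSpeciesError(DTSBError, ValueError):
    """Two or more species cannot be separated at any candidate site."""

    def __init__(self, labels: Iterable[str]):
        self.labels = tuple(labels)
        super().__init__(
            "indistinguishable species: no variable candidate position separates "
            + ", ".join(self.labels)
        )


class UnclassifiableError(DTSBError, ValueError):
    """A query sequence carries a gap/ambiguity symbol at a decision position."""

    def __init__(self, position: int, symbol: str):
        self.position = position
        self.symbol = symbol
        super().__init__(
            f"unclassifiable: symbol {symbol!r} at decision position {position}"
        )


class AmbiguousBarcodeError(DTSBError, ValueError):
    """More than one barcode matches a query; the barcode set is corrupt."""
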