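"""Exception hierarchy for the usm package."""


class UsmError(Exception):
    """Base class for all errors raised by this package."""


class AlphabetError(UsmError):
    """Invalid or empty alphabet, or a sequence no alphabet can be drawn from."""


class UnknownSymbolError(UsmError):
    """A sequence symbol is not covered by the supplied alphabet.

    Carries the offending symbol and its 0-based position.
    """

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"symbol {symbol!r} at position {position} is not in the alphabet"
        )


class DecodeError(UsmError):
    """Coordinate decoding failed (value out of range, or an orphan corner)."""


class FastaFormatError(UsmError):
    """Malformed FASTA input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
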