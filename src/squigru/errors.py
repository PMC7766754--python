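"""Exception hierarchy shared across the package."""


class SquigruError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SquigruError, ValueError):
    """An argument or data structure violates a documented invariant."""


class ParseError(SquigruError, ValueError):
    """A file could not be parsed; the message carries the line number."""


class MissingKmerError(SquigruError, KeyError):
    """A 6-mer window of the query sequence is absent from the pore model."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return self.args[0] if self.args else ""


class AlphabetError(SquigruError, ValueError):
    """A sequence contains characters outside the {A, C, G, T} alphabet."""


class DegenerateInputError(SquigruError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant signal)."""


class BandError(SquigruError, ValueError):
    """The warping band is too narrow to connect the corners of the DTW grid."""
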