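"""Exception hierarchy for the scarless design toolkit."""


class ScarlessError(Exception):
    """Base class for all package errors."""


class AlphabetError(ScarlessError, ValueError):
    """Sequence contains characters outside the ACGT alphabet."""


class CodingFrameError(ScarlessError, ValueError):
    """Sequence length is not compatible with codon-wise interpretation."""


class LibraryError(ScarlessError, ValueError):
    """Element library is malformed or missing a required part."""


class ParseError(ScarlessError, ValueError):
    """An input file could not be parsed or violates record invariants."""


class RecodeInfeasibleError(ScarlessError):
    """Synonymous recoding cannot satisfy the stated constraints.

    Carries the offending span (0-based, half-open, in fragment
    coordinates) so callers can report or relax it.
    """

    def __init__(self, message: str, span: tuple[int, int] | None = None):
        super().__init__(message)
        self.span = span


class TargetingError(ScarlessError):
    """Homology arms do not anchor uniquely in the target genome."""


class CleavageError(ScarlessError):
    """The intermediate genome does not carry exactly one I-SceI site."""


class ResolutionError(ScarlessError):
    """HR3-mediated excision cannot proceed or left foreign sequence behind."""


class DesignError(ScarlessError):
    """An edit specification cannot be turned into a valid cassette."""


class DesignInfeasibleError(DesignError):
    """The integration model has no eligible crossover position at all."""


class PrimerError(ScarlessError):
    """Primer design could not satisfy the melting-temperature constraints."""


class AssemblyAmbiguityError(ScarlessError):
    """Two junctions in an assembly share the same overlap sequence."""
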