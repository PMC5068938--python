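"""Exception hierarchy for the toolkit.

Every error raised by the library derives from :class:`MiniCRKitError`, so callers
(and the CLI, which maps them to exit code 3) can catch one type.
"""


class MiniCRKitError(Exception):
    """Base class for all toolkit errors."""


class SequenceAlphabetError(MiniCRKitError):
    """A sequence contains characters outside the declared nucleotide alphabet."""


class AmbiguityError(SequenceAlphabetError):
    """An IUPAC ambiguity code (N, R, Y, ...) was found where a concrete base is required."""


class EmptyInputError(MiniCRKitError):
    """An input file or record collection was empty."""


class DuplicateIdError(MiniCRKitError):
    """Two records in one file share an identifier."""


class CoordinateError(MiniCRKitError):
    """An annotation coordinate falls outside its genome, or a strand symbol is unknown."""


class DesignError(MiniCRKitError):
    """A design request is infeasible (candidate selection, nonsense-spacer sampling, ...)."""


class AssemblyError(MiniCRKitError):
    """A construct cannot be assembled as requested."""


class PrimerDesignError(MiniCRKitError):
    """Primer geometry constraints cannot be satisfied."""


class FusionAmbiguityError(AssemblyError):
    """Overlap-extension fusion admits more than one join (duplicate inner spacers)."""


class NoAmpliconError(AssemblyError):
    """No fragment flanked by both outer primers can be assembled from the given units."""


class QuantError(MiniCRKitError):
    """A quantification input is degenerate (range too small, zero control, ...)."""


class PackingError(DesignError):
    """Requested planted sites cannot be packed into the requested sequence length."""
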