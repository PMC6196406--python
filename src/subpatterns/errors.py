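"""Exception hierarchy for the substitution-pattern pipeline.

Every structured failure mode raised by the library derives from
:class:`SubpatternsError`, so callers (notably the CLI) can map errors to
exit codes without string matching.
"""


class SubpatternsError(Exception):
    """Base class for all errors raised by this package."""


class RstParseError(SubpatternsError):
    """Base class for failures while reading a PAML rst file."""


class UnrecognizedFormatError(RstParseError):
    """The text is neither a baseml nor a codeml reconstruction file."""


class GapOrAmbiguityError(RstParseError):
    """A sequence contains a character outside {A, C, G, T}.

    Ancestral-reconstruction input must be gap-free and ambiguity-free;
    anything else makes codon bookkeeping meaningless.
    """


class FrameError(RstParseError):
    """codeml-mode alignment length is not a multiple of three."""


class MalformedBlockError(RstParseError):
    """A branch block or change line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class InvalidCodonError(SubpatternsError):
    """A codon string is not three uppercase DNA bases."""


class InvalidBaseError(SubpatternsError):
    """A base is not a DNA base, or a 'change' has identical endpoints."""


class StopCodonError(SubpatternsError):
    """A stop codon appeared where only sense codons are valid."""


class MissingAncestorError(SubpatternsError):
    """A branch's parent node has no reconstructed sequence."""


class SiteOutOfRangeError(SubpatternsError):
    """An event's site falls outside the alignment."""


class WindowError(SubpatternsError):
    """Sliding-window or step parameters violate their bounds."""


class UnknownBranchError(SubpatternsError):
    """A branch referenced by labels or events is absent from the tree."""


class EmptyAnnotationError(SubpatternsError):
    """A branch annotation with zero counts cannot be formatted."""


class AnnotationSyntaxError(SubpatternsError):
    """An annotation string does not match the annotation grammar."""


class ParameterError(SubpatternsError):
    """Invalid simulation or configuration parameter."""


class EmptyInputError(SubpatternsError):
    """A report was requested with no computed inputs."""
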