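"""Exception hierarchy for clonepoly.

Every validation failure raises a distinct subclass so callers (and the
CLI's exit-code mapping) can tell malformed sequence data apart from
metadata or annotation problems.
"""


class ClonePolyError(Exception):
    """Base class for all clonepoly errors."""


class InputError(ClonePolyError):
    """Empty or otherwise unusable input to an operation."""


class FormatError(ClonePolyError):
    """A file or record violates the expected format (alphabet, emptiness)."""


class AlignmentInputError(ClonePolyError):
    """Sequences that must share one coordinate system do not (ragged input)."""


class MetadataError(ClonePolyError):
    """Sample sheet and FASTA disagree, or sheet records are malformed."""


class AnnotationError(ClonePolyError):
    """Region annotation does not tile the alignment or is inconsistent."""


class ConsistencyError(ClonePolyError):
    """Derived objects (events, sites) do not match the alignment they claim."""


class GenerationError(ClonePolyError):
    """The synthetic generator cannot satisfy the requested configuration."""
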