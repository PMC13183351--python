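"""Named exception types shared across the package.

Each distinct contract violation gets its own class so callers can react
selectively (skip a record, abort a run) instead of string-matching messages.
"""


class RoleprobeError(Exception):
    """Base class for all package errors."""


class SpanOutOfBoundsError(RoleprobeError):
    """An argument span does not fit inside its utterance's token list."""


class UnknownRoleError(RoleprobeError):
    """A role label outside {A, P} was encountered."""


class OverlappingSpansError(RoleprobeError):
    """The A and P spans of one clause overlap."""


class VerbNotInFramesError(RoleprobeError):
    """A verb lemma has no entry in the case-frame inventory."""


class CorpusTooSmallError(RoleprobeError):
    """A corpus cannot satisfy a requested token budget."""


class InfeasibleSplitError(RoleprobeError):
    """Requested split sizes cannot be met under verb disjointness."""


class SpecValidationError(RoleprobeError):
    """A register specification is internally inconsistent."""


class FormNotInParadigmError(RoleprobeError):
    """A surface form cannot be analysed by the case paradigm."""


class EncodingAlignmentError(RoleprobeError):
    """Subword alignment lost the tokens of an argument span."""


class ConvergenceError(RoleprobeError):
    """A sampler finished with diagnostics above the configured threshold."""
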