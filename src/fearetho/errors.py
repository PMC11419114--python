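"""Exception hierarchy. All validation failures raise; nothing truncates."""


class FearEthoError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FearEthoError):
    """A file or field could not be interpreted (bad label, bad time, ...)."""


class CompletenessError(FearEthoError):
    """A trial is missing frames; the message lists the gaps."""


class ConflictError(FearEthoError):
    """Duplicate (trial, frame, observer) rows in a frame-label file."""


class StructureError(FearEthoError):
    """Event-log structure violated (cue alternation, window overlap, ...)."""


class SelectionError(FearEthoError):
    """A filter selected no data."""


class DesignError(FearEthoError):
    """Statistical design unsupported (e.g. unbalanced split-plot ANOVA)."""


class AuthenticationError(FearEthoError):
    """A blind token failed verification under the supplied key."""
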