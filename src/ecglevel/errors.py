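"""Exception hierarchy for ecglevel."""


class EcgLevelError(Exception):
    """Base class for all package-specific errors."""


class MalformedRecordError(EcgLevelError):
    """A record file violates the 12-lead / 5000-sample contract."""


class RateMismatchError(EcgLevelError):
    """Stored sampling rate differs from 500 Hz and resampling was not requested."""


class DuplicateDrawError(EcgLevelError):
    """Two annotation rows describe the same (subject, timepoint) blood draw."""


class IncompleteTriplicateError(EcgLevelError):
    """A blood draw declares fewer than three replicate ECG paths."""


class DegeneratePKError(EcgLevelError):
    """ka == ke makes the two-exponential oral model singular."""


class UndetectableRhythmError(EcgLevelError):
    """Fewer than two R peaks could be located on the detection lead."""


class DelineationFailure(EcgLevelError):
    """Record-level QT measurement failed; carries per-lead diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDesignError(EcgLevelError):
    """Linear fit requested on a zero-variance or too-small design."""


class ConfigError(EcgLevelError):
    """Invalid network / pipeline configuration."""
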