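"""Exception hierarchy for the qspike pipeline."""


class QSpikeError(Exception):
    """Base class for all qspike-specific errors."""


class FormatError(QSpikeError):
    """Sidecar metadata missing or inconsistent with the binary payload."""


class TruncationError(FormatError):
    """Binary file size is not a whole number of frames."""


class DegenerateTraceError(QSpikeError):
    """Trace has no amplitude variation; a noise threshold cannot be estimated."""


class ConsolidationError(QSpikeError):
    """Consolidation attempted before every channel's spike train is available."""
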