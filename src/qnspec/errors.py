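"""Exception hierarchy."""


class QnspecError(Exception):
    """Base class for package errors."""


class FormatError(QnspecError):
    """Malformed input file (ragged rows, non-uniform axis, bad schema)."""


class AnalysisError(QnspecError):
    """A computation cannot proceed on the given data (e.g. no converged fits)."""
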