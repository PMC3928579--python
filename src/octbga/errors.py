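"""Exception hierarchy.

Errors are grouped by how a caller should react: bad parameters or
configuration (:class:`ConfigError`), unreadable/inconsistent input data
(:class:`FormatError`), and failures of the analysis itself on valid data
(:class:`AlgorithmError`, e.g. no optic disk found). The CLI maps these
groups onto distinct exit codes.
"""


class OctBgaError(Exception):
    """Base class for all package errors."""


class ValidationError(OctBgaError, ValueError):
    """A domain object violates one of its invariants."""


class ConfigError(OctBgaError):
    """Bad parameter value or unusable configuration/calibration."""


class FormatError(OctBgaError):
    """Input file missing, malformed or internally inconsistent."""


class DegenerateInputError(OctBgaError, ValueError):
    """Input is valid but degenerate for the requested operation
    (e.g. a constant sample offered to Otsu thresholding)."""


class AlgorithmError(OctBgaError):
    """A pipeline stage failed on otherwise valid data."""


class NoDiskError(AlgorithmError):
    """No optic-disk region survives thresholding and cleanup."""
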