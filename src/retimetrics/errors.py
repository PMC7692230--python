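"""Exception hierarchy.

``FormatError`` covers malformed on-disk inputs and invariant violations at
read time; ``AnalysisError`` covers degenerate inputs to analysis stages
(constant images, empty skeletons, flat traces, zero-variance regressors).
"""


class RetimetricsError(Exception):
    """Base class for all package errors."""


class FormatError(RetimetricsError):
    """Malformed input file or metadata violating a type invariant."""


class AnalysisError(RetimetricsError):
    """Degenerate or out-of-contract input to an analysis stage."""


class QualityGateError(AnalysisError):
    """Scan excluded by the signal-strength quality gate."""
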