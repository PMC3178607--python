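"""Exception hierarchy."""


class GrooveScoreError(Exception):
    """Base class for all package errors."""


class StructureError(GrooveScoreError):
    """Malformed or incomplete structural input."""


class ThreadingError(GrooveScoreError):
    """Peptide cannot be threaded onto the reference."""


class ParameterError(GrooveScoreError):
    """Invalid scoring-function or kernel parameters."""


class DataError(GrooveScoreError):
    """Invalid binding-data input (units, IC50 domain, parse failures)."""


class RegressionError(GrooveScoreError):
    """Degenerate or invalid regression problem."""
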