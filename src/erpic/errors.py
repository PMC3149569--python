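"""Exception hierarchy for the ERP independent-component pipeline."""


class ErpicError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ErpicError, ValueError):
    """A configuration or generator parameter is out of its admissible range."""


class InvalidInputError(ErpicError, ValueError):
    """An input object violates a precondition (shape, montage, missing data)."""


class DegenerateInputError(ErpicError, ValueError):
    """Numerically degenerate input, e.g. rank-deficient data below n_ics."""
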