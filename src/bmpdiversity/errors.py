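"""Exception hierarchy shared across the pipeline stages."""


class BmpDiversityError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BmpDiversityError, ValueError):
    """A model or design parameter violates its stated domain."""


class InvalidInputError(BmpDiversityError, ValueError):
    """Input data violate a contract (range, monotonicity, finiteness)."""


class GridMismatchError(BmpDiversityError, ValueError):
    """Two objects that must share a position/time grid do not."""


class InsufficientDataError(BmpDiversityError, ValueError):
    """Too few points/bins/repeats for the requested operation."""


class DegenerateSolutionError(BmpDiversityError, ValueError):
    """Parameter combination lands on a removable singularity of a closed form."""


class IntegrationError(BmpDiversityError, RuntimeError):
    """The ODE solver failed; message carries solver diagnostics."""
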