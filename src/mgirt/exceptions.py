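"""Exception hierarchy for mgirt."""


class MgirtError(Exception):
    """Base class for all mgirt errors."""


class InvalidInputError(MgirtError, ValueError):
    """Malformed item parameters, quadrature request, or latent value."""


class DataValidationError(MgirtError, ValueError):
    """Response data inconsistent with the declared model (range, missingness)."""


class UnsupportedScoresError(MgirtError, ValueError):
    """Category scores outside the nonnegative-integer lattice the recursion supports."""


class DegenerateTestError(MgirtError, ArithmeticError):
    """Observed score variance at or below the underflow floor."""


class DegenerateInformationError(MgirtError, ArithmeticError):
    """Test information (or a category probability) collapsed below the underflow floor."""


class RankDeficiencyError(MgirtError, ArithmeticError):
    """Hessian of the marginal log-likelihood is numerically singular."""


class PSDViolationError(MgirtError, ArithmeticError):
    """Quadratic form of the delta method is negative beyond tolerance."""
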