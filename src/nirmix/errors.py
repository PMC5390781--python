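"""Exception and warning types shared across the package."""


class NirmixError(Exception):
    """Base class for all nirmix errors."""


class ParseError(NirmixError):
    """Malformed spectral input (missing columns, non-numeric cells, duplicate wavenumbers)."""


class RangeError(NirmixError):
    """Requested spectral range does not overlap, or would require extrapolation."""


class FitError(NirmixError):
    """Spline fit cannot be performed (too few points, rank-deficient design)."""


class SolveError(NirmixError):
    """Linear unmixing system is rank deficient or otherwise unsolvable."""


class SingularityError(NirmixError):
    """Covariance matrix is singular / not positive definite."""


class WindowError(NirmixError):
    """Spectral window too small for a stable sub-solve."""


class SizeError(NirmixError):
    """Sample or subsample too small for the requested statistical procedure."""


class ConditioningWarning(UserWarning):
    """Component library is close to collinear; concentration estimates may be unstable."""


class TieWarning(UserWarning):
    """Mahalanobis distances tied between groups; tie broken toward 'normal'."""
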