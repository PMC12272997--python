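"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class NumericalError(RuntimeError):
    """Raised when a linear solve or other numeric step fails."""


class DivergenceError(NumericalError):
    """Raised when an iterative fit produces non-finite values.

    Usually means the orthogonality penalties (``lambda_v3``/``lambda_u2``)
    are too large for the data scale; try smaller values.
    """


class DegenerateDirectionError(NumericalError):
    """Raised when a weight vector projects to a (near-)zero score vector."""
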