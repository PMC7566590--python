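"""Exception hierarchy shared across the package.

``ValidationError`` signals bad input data (CLI exit code 2);
``NumericalError`` signals a failure inside a fit or model evaluation
(CLI exit code 3).
"""


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class NumericalError(RuntimeError):
    """A numerical routine produced a non-finite or undefined result."""
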