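"""Typed errors shared across the package.

The CLI maps these onto exit codes: validation errors exit 2, computation
failures exit 3.
"""


class AperiodicError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(AperiodicError, ValueError):
    """An argument violates a precondition (bad shape, range, or name)."""


class DegenerateInputError(AperiodicError, ValueError):
    """The input is degenerate for the requested measure.

    Raised instead of silently returning NaN, e.g. a constant signal has no
    defined autocorrelation, rescaled range, or fractal dimension.
    """


class FitError(AperiodicError, RuntimeError):
    """A model fit failed to converge or produced no usable estimate."""
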