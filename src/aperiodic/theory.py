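"""Analytic relationships between aperiodic measures on colored noise.

For pure 1/f^chi noise the DFA scaling exponent and the fractal dimension
have closed-form relations to the spectral exponent chi. Two conventions are
exposed for the alpha relation:

- ``standard``: alpha = (chi + 1) / 2, the form consistent with chi defined
  as the *negated* log-log slope (chi >= 0, so e.g. brown noise chi = 2
  gives alpha = 1.5). Simulations agree with this form.
- ``printed``: alpha = (-chi + 1) / 2, a sign variant that circulates in
  the literature when chi is identified with the (negative) slope itself.
  The two coincide at chi = 0 and diverge elsewhere; both are provided so
  either can be checked explicitly.

The fractal-dimension relations are FD = 3 - alpha and, directly,
D = (5 - chi) / 2 (derived in the fractional-Brownian-motion regime,
chi in [1, 3]). There are no closed forms for the complexity or entropy
measures on colored noise; these relations serve as test oracles and
expected-value overlays for the fluctuation and fractal measures only.
"""

from __future__ import annotations

from .exceptions import InvalidArgumentError

__all__ = ["expected_value", "dfa_alpha", "fractal_dim_from_alpha", "VALIDITY"]

# validity ranges of chi for each relation
VALIDITY = {
    "dfa_alpha": (0.0, 3.0),
    "fractal_dimension": (1.0, 3.0),
}


def dfa_alpha(exponent: float, convention: str = "standard") -> float:
    """Expected DFA alpha for colored noise of the given spectral exponent."""
    if convention == "standard":
        return (exponent + 1.0) / 2.0
    if convention == "printed":
        return (-exponent + 1.0) / 2.0
    raise InvalidArgumentError(
        f"convention must be 'standard' or 'printed', got {convention!r}"
    )


def fractal_dim_from_alpha(alpha: float) -> float:
    """Fractal dimension from the DFA alpha value: FD = 3 - alpha."""
    return 3.0 - alpha


def expected_value(
    measure: str, exponent: float, convention: str = "standard"
) -> float:
    """Closed-form expected value of a measure on 1/f^exponent noise.

    ``measure`` is 'dfa_alpha' or 'fractal_dimension'. Raises an
    out-of-range error when the exponent lies outside the relation's
    validity range (alpha: chi in [0, 3]; D = (5 - chi)/2: chi in [1, 3]).
    """
    if measure not in VALIDITY:
        raise InvalidArgumentError(
            f"no analytic relation for {measure!r}; known: {sorted(VALIDITY)}"
        )
    lo, hi = VALIDITY[measure]
    if not lo <= exponent <= hi:
        raise InvalidArgumentError(
            f"exponent {exponent} outside validity range [{lo}, {hi}] for {measure}"
        )
    if measure == "dfa_alpha":
        return dfa_alpha(exponent, convention)
    # fractal dimension: D = (5 - chi) / 2, identically 3 - alpha(standard)
    if convention == "printed":
        return fractal_dim_from_alpha(dfa_alpha(exponent, "printed"))
    return (5.0 - exponent) / 2.0
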