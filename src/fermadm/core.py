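"""Fermatean fuzzy numbers: the atomic value of the library.

A Fermatean fuzzy number (FFN) is a pair ``(mu, nu)`` of membership and
non-membership degrees in ``[0, 1]`` constrained by ``mu**3 + nu**3 <= 1``.
The cube relaxes the intuitionistic constraint ``mu + nu <= 1`` and the
Pythagorean constraint ``mu**2 + nu**2 <= 1``, so an expert may assert both
strong support and strong opposition (e.g. ``(0.9, 0.5)``) and still produce
a well-formed judgement.

This module provides construction with strict/permissive validation, the
score and accuracy ranking functions, the indeterminacy (hesitation) degree,
the score-then-accuracy total comparison, the componentwise dominance
partial order, and the complement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "VALIDATION_TOL",
    "COMPARISON_TOL",
    "FFN",
    "Ordering",
    "FFNValidationError",
    "make_ffn",
    "score",
    "accuracy",
    "indeterminacy",
    "compare",
    "complement",
    "dominance_leq",
]

#: Slack allowed on the cube-sum constraint; absorbs decimal-literal rounding
#: without admitting genuinely invalid pairs.
VALIDATION_TOL = 1e-9

#: Tolerance for score/accuracy ties in :func:`compare`.
COMPARISON_TOL = 1e-12


class FFNValidationError(ValueError):
    """A membership/non-membership pair violates the FFN constraints."""


class Ordering(enum.Enum):
    """Outcome of the score-then-accuracy comparison of two FFNs."""

    FIRST_GREATER = "first_greater"
    SECOND_GREATER = "second_greater"
    EQUIVALENT = "equivalent"


@dataclass(frozen=True, slots=True)
class FFN:
    """A Fermatean fuzzy number ``(mu, nu)``.

    ``flagged`` marks a pair that was admitted in permissive mode despite
    violating ``mu**3 + nu**3 <= 1``; it does not participate in equality.
    """

    mu: float
    nu: float
    flagged: bool = field(default=False, compare=False)

    def __iter__(self):
        yield self.mu
        yield self.nu

    def __repr__(self) -> str:  # compact: FFN(0.7, 0.4)
        base = f"FFN({self.mu:.6g}, {self.nu:.6g})"
        return base + ("*" if self.flagged else "")


def make_ffn(mu: float, nu: float, mode: str = "strict") -> FFN:
    """Validate and build an FFN.

    Parameters
    ----------
    mu, nu
        Membership and non-membership degrees.
    mode
        ``"strict"`` raises :class:`FFNValidationError` on any violation;
        ``"permissive"`` still rejects non-finite or out-of-``[0, 1]``
        components but admits cube-sum violations with ``flagged=True``.
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"mode must be 'strict' or 'permissive', got {mode!r}")
    mu = float(mu)
    nu = float(nu)
    if not (math.isfinite(mu) and math.isfinite(nu)):
        raise FFNValidationError(f"components must be finite, got ({mu}, {nu})")
    if not (0.0 <= mu <= 1.0 and 0.0 <= nu <= 1.0):
        raise FFNValidationError(
            f"components must lie in [0, 1], got ({mu}, {nu})"
        )
    cube_sum = mu**3 + nu**3
    if cube_sum > 1.0 + VALIDATION_TOL:
        if mode == "strict":
            raise FFNValidationError(
                f"({mu}, {nu}) violates mu^3 + nu^3 <= 1 (sum = {cube_sum:.6f})"
            )
        return FFN(mu, nu, flagged=True)
    return FFN(mu, nu)


def score(f: FFN) -> float:
    """Score ``g(F) = mu**3 - nu**3`` in ``[-1, 1]``; the primary ranking key."""
    return f.mu**3 - f.nu**3


def accuracy(f: FFN) -> float:
    """Accuracy ``H(F) = mu**3 + nu**3`` in ``[0, 1]``; the tie-breaking key."""
    return f.mu**3 + f.nu**3


def indeterminacy(f: FFN) -> float:
    """Hesitation degree ``pi = (1 - mu**3 - nu**3) ** (1/3)``.

    Radicands within ``-VALIDATION_TOL`` of zero are clamped to zero; a more
    negative radicand means an invalid FFN slipped through and raises.
    """
    radicand = 1.0 - f.mu**3 - f.nu**3
    if radicand < -VALIDATION_TOL:
        raise FFNValidationError(
            f"invalid FFN ({f.mu}, {f.nu}): 1 - mu^3 - nu^3 = {radicand:.3e} < 0"
        )
    return math.cbrt(max(radicand, 0.0))


def compare(f1: FFN, f2: FFN, tol: float = COMPARISON_TOL) -> Ordering:
    """Total comparison: order by score, break score ties by accuracy.

    Differences within ``tol`` count as ties; when both score and accuracy
    tie the numbers are equivalent.
    """
    ds = score(f1) - score(f2)
    if ds > tol:
        return Ordering.FIRST_GREATER
    if ds < -tol:
        return Ordering.SECOND_GREATER
    da = accuracy(f1) - accuracy(f2)
    if da > tol:
        return Ordering.FIRST_GREATER
    if da < -tol:
        return Ordering.SECOND_GREATER
    return Ordering.EQUIVALENT


def complement(f: FFN) -> FFN:
    """Complement ``(mu, nu) -> (nu, mu)``; an involution that negates the score."""
    return FFN(f.nu, f.mu, flagged=f.flagged)


def dominance_leq(f1: FFN, f2: FFN) -> bool:
    """Componentwise dominance partial order: ``f1 <= f2``.

    Holds when ``f1`` has no larger membership and no smaller non-membership
    than ``f2``. This is the order under which the aggregation operators are
    monotone and bounded by ``(min mu, max nu)`` and ``(max mu, min nu)``.
    It is deliberately distinct from :func:`compare`: two FFNs can be
    incomparable here yet strictly ordered by score.
    """
    return f1.mu <= f2.mu and f1.nu >= f2.nu
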