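"""Dynamic operational laws on FFNs and the FFDyWA / FFDyWG operators.

A Fermatean fuzzy variable observed at ``p`` time points yields a series of
FFNs ``F_{t_1}, ..., F_{t_p}``. The dynamic weighted averaging (FFDyWA) and
geometric (FFDyWG) operators collapse such a series into a single FFN under
a time-weight vector ``eps``, via the closed forms

    FFDyWA = ((1 - prod (1 - mu_k^3)^eps_k)^(1/3),  prod nu_k^eps_k)
    FFDyWG = (prod mu_k^eps_k,  (1 - prod (1 - nu_k^3)^eps_k)^(1/3))

which are the eps-weighted iterates of the dynamic sum and product laws
below. Both are idempotent, bounded by the componentwise extremes, monotone
in the dominance order, and closed on valid FFNs.
"""

from __future__ import annotations

import math
from typing import Sequence

from .core import FFN
from .kernel import q_weighted_average, q_weighted_geometric
from .weights import WeightVector, as_weights

__all__ = [
    "ff_add",
    "ff_mul",
    "ff_scale",
    "ff_power",
    "ffdywa",
    "ffdywg",
]


def ff_add(f1: FFN, f2: FFN) -> FFN:
    """Dynamic sum ``F1 (+) F2 = ((mu1^3 + mu2^3 - mu1^3 mu2^3)^(1/3), nu1 nu2)``.

    ``(0, 1)`` is the identity and ``(1, 0)`` absorbs.
    """
    m1, m2 = f1.mu**3, f2.mu**3
    return FFN(math.cbrt(m1 + m2 - m1 * m2), f1.nu * f2.nu)


def ff_mul(f1: FFN, f2: FFN) -> FFN:
    """Dynamic product ``F1 (x) F2 = (mu1 mu2, (nu1^3 + nu2^3 - nu1^3 nu2^3)^(1/3))``.

    The De Morgan dual of :func:`ff_add`: ``(1, 0)`` is the identity and
    ``(0, 1)`` absorbs.
    """
    n1, n2 = f1.nu**3, f2.nu**3
    return FFN(f1.mu * f2.mu, math.cbrt(n1 + n2 - n1 * n2))


def _check_eps(eps: float) -> None:
    if not (eps > 0):
        raise ValueError(f"scalar exponent must be positive, got {eps!r}")


def _attenuate(x: float, eps: float) -> float:
    # (1 - (1 - x^3)^eps)^(1/3) without cancellation at either boundary
    if x == 1.0:
        return 1.0
    return math.cbrt(-math.expm1(eps * math.log1p(-(x**3))))


def ff_scale(eps: float, f: FFN) -> FFN:
    """Scalar multiple ``eps * F = ((1 - (1 - mu^3)^eps)^(1/3), nu^eps)``, eps > 0."""
    _check_eps(eps)
    return FFN(_attenuate(f.mu, eps), f.nu**eps)


def ff_power(f: FFN, eps: float) -> FFN:
    """Power ``F^eps = (mu^eps, (1 - (1 - nu^3)^eps)^(1/3))``, eps > 0."""
    _check_eps(eps)
    return FFN(f.mu**eps, _attenuate(f.nu, eps))


def ffdywa(series: Sequence[FFN], eps: WeightVector | Sequence[float]) -> FFN:
    """Fermatean fuzzy dynamic weighted average of a time series of FFNs."""
    wv = as_weights(eps, "time", len(series))
    mu, nu = q_weighted_average(
        [f.mu for f in series], [f.nu for f in series], wv.weights, q=3
    )
    return FFN(mu, nu)


def ffdywg(series: Sequence[FFN], eps: WeightVector | Sequence[float]) -> FFN:
    """Fermatean fuzzy dynamic weighted geometric mean of a time series of FFNs."""
    wv = as_weights(eps, "time", len(series))
    mu, nu = q_weighted_geometric(
        [f.mu for f in series], [f.nu for f in series], wv.weights, q=3
    )
    return FFN(mu, nu)
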