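"""Generic exponent-q weighted aggregation kernel.

The dynamic and static averaging/geometric operators on q-rung orthopair
pairs all reduce to two weighted geometric products:

* averaging:  mu_out = (1 - prod_k (1 - mu_k**q)**w_k)**(1/q),
              nu_out = prod_k nu_k**w_k
* geometric:  mu_out = prod_k mu_k**w_k,
              nu_out = (1 - prod_k (1 - nu_k**q)**w_k)**(1/q)

with q = 3 for Fermatean pairs and q = 1 for intuitionistic pairs. A single
kernel removes duplicated numerics: the intuitionistic baselines and every
Fermatean operator (time-wise or attribute-wise) differ only in ``q`` and in
which weight vector they receive.

Products are evaluated as exponentials of weighted log sums so that long
series cannot underflow, with exact short-circuiting when a factor is 0 or 1
(conventions ``0**0 = 1`` and ``0**w = 0`` for ``w > 0``, so zero weights
drop a period and boundary components behave as limits).
"""

from __future__ import annotations

import math
from typing import Sequence

__all__ = [
    "weighted_product",
    "survival_complement",
    "q_weighted_average",
    "q_weighted_geometric",
]


def weighted_product(factors: Sequence[float], weights: Sequence[float]) -> float:
    """``prod_k factors[k] ** weights[k]`` in log space.

    Factors must be in ``[0, 1]`` and weights nonnegative. A zero factor with
    positive weight annihilates the product; zero-weight factors are skipped.
    """
    if len(factors) != len(weights):
        raise ValueError(
            f"{len(factors)} factors but {len(weights)} weights"
        )
    log_sum = 0.0
    for x, w in zip(factors, weights):
        if w == 0.0:
            continue
        if x == 0.0:
            return 0.0
        if x != 1.0:
            log_sum += w * math.log(x)
    return math.exp(log_sum) if log_sum != 0.0 else 1.0


def survival_complement(xs: Sequence[float], weights: Sequence[float]) -> float:
    """``1 - prod_k (1 - xs[k]) ** weights[k]`` for ``xs`` in ``[0, 1]``.

    Evaluated as ``-expm1(sum w * log1p(-x))`` so the result keeps full
    relative precision both when the product is close to 1 (all ``x`` tiny)
    and when it is close to 0 — a plain ``1 - prod`` would lose everything
    below machine epsilon in the first case.
    """
    if len(xs) != len(weights):
        raise ValueError(f"{len(xs)} factors but {len(weights)} weights")
    acc = 0.0
    for x, w in zip(xs, weights):
        if w == 0.0:
            continue
        if x == 1.0:
            return 1.0
        if x != 0.0:
            acc += w * math.log1p(-x)
    return -math.expm1(acc)


def q_weighted_average(
    mus: Sequence[float],
    nus: Sequence[float],
    weights: Sequence[float],
    q: int,
) -> tuple[float, float]:
    """Averaging-family aggregate of ``(mu_k, nu_k)`` pairs under exponent q."""
    mu = survival_complement([m**q for m in mus], weights) ** (1.0 / q)
    nu = weighted_product(nus, weights)
    return mu, nu


def q_weighted_geometric(
    mus: Sequence[float],
    nus: Sequence[float],
    weights: Sequence[float],
    q: int,
) -> tuple[float, float]:
    """Geometric-family aggregate; the De Morgan dual of :func:`q_weighted_average`."""
    mu = weighted_product(mus, weights)
    nu = survival_complement([n**q for n in nus], weights) ** (1.0 / q)
    return mu, nu
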