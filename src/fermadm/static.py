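"""Per-period weighted aggregation across attributes (FFWA / FFWG).

The pipeline's second stage collapses each alternative's row of the
collective matrix into one overall FFN under the attribute weights ``omega``.
The canonical forms are the *power* forms — numerically identical to the
dynamic operators with the weights relabelled, and the only forms that
reproduce the published overall values:

    FFWA = ((1 - prod (1 - mu_j^3)^w_j)^(1/3),  prod nu_j^w_j)
    FFWG = (prod mu_j^w_j,  (1 - prod (1 - nu_j^3)^w_j)^(1/3))

The literature also carries a componentwise *arithmetic* form under the same
FFWA name (weighted arithmetic means of mu and nu separately); it is a
different operator and is kept here as :func:`ffwa_arithmetic` for
completeness. Its result is always a valid FFN because the constraint region
``mu^3 + nu^3 <= 1`` is convex.
"""

from __future__ import annotations

import math
from typing import Sequence

from .core import FFN
from .kernel import q_weighted_average, q_weighted_geometric
from .weights import WeightVector, as_weights

__all__ = ["ffwa_power", "ffwg_power", "ffwa_arithmetic"]


def ffwa_power(row: Sequence[FFN], omega: WeightVector | Sequence[float]) -> FFN:
    """Power-form Fermatean fuzzy weighted average over attributes."""
    wv = as_weights(omega, "attribute", len(row))
    mu, nu = q_weighted_average(
        [f.mu for f in row], [f.nu for f in row], wv.weights, q=3
    )
    return FFN(mu, nu)


def ffwg_power(row: Sequence[FFN], omega: WeightVector | Sequence[float]) -> FFN:
    """Power-form Fermatean fuzzy weighted geometric mean over attributes."""
    wv = as_weights(omega, "attribute", len(row))
    mu, nu = q_weighted_geometric(
        [f.mu for f in row], [f.nu for f in row], wv.weights, q=3
    )
    return FFN(mu, nu)


def ffwa_arithmetic(row: Sequence[FFN], omega: WeightVector | Sequence[float]) -> FFN:
    """Componentwise weighted arithmetic mean ``(sum w mu_j, sum w nu_j)``."""
    wv = as_weights(omega, "attribute", len(row))
    mu = math.fsum(w * f.mu for w, f in zip(wv.weights, row))
    nu = math.fsum(w * f.nu for w, f in zip(wv.weights, row))
    return FFN(mu, nu)
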