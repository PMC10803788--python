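"""Intuitionistic fuzzy dynamic baselines (IFDWA / IFDWG).

These are the exponent-1 counterparts of the Fermatean operators, run
through the same two-stage pipeline for comparison. An intuitionistic fuzzy
number (IFN) requires ``mu + nu <= 1`` — a strictly smaller admissible
region than the Fermatean one, which is the point of the comparison: data
elicited as FFNs (e.g. ``(0.9, 0.6)``) routinely violate the IFN
constraint, so the baseline defaults to permissive validation and reports
every violating cell instead of refusing the input.

Scores here are ``mu - nu`` and accuracies ``mu + nu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core import FFNValidationError
from .kernel import q_weighted_average, q_weighted_geometric
from .pipeline import RankingReport, TemporalDecisionTensor
from .weights import WeightVector, as_weights

__all__ = [
    "IFN",
    "make_ifn",
    "ifdywa",
    "ifdywg",
    "if_score",
    "if_accuracy",
    "run_baseline",
    "BASELINE_FAMILIES",
]

BASELINE_FAMILIES = ("ifdywa", "ifdywg")

_TOL = 1e-9


@dataclass(frozen=True, slots=True)
class IFN:
    """An intuitionistic fuzzy pair; ``flagged`` marks ``mu + nu > 1``."""

    mu: float
    nu: float
    flagged: bool = field(default=False, compare=False)

    def __iter__(self):
        yield self.mu
        yield self.nu


def make_ifn(mu: float, nu: float, mode: str = "strict") -> IFN:
    """Validate an IFN; permissive mode flags ``mu + nu > 1`` and proceeds."""
    if mode not in ("strict", "permissive"):
        raise ValueError(f"mode must be 'strict' or 'permissive', got {mode!r}")
    mu, nu = float(mu), float(nu)
    if not (math.isfinite(mu) and math.isfinite(nu)):
        raise FFNValidationError(f"components must be finite, got ({mu}, {nu})")
    if not (0.0 <= mu <= 1.0 and 0.0 <= nu <= 1.0):
        raise FFNValidationError(f"components must lie in [0, 1], got ({mu}, {nu})")
    if mu + nu > 1.0 + _TOL:
        if mode == "strict":
            raise FFNValidationError(
                f"({mu}, {nu}) violates mu + nu <= 1 (sum = {mu + nu:.6f})"
            )
        return IFN(mu, nu, flagged=True)
    return IFN(mu, nu)


def ifdywa(series: Sequence[IFN], eps: WeightVector | Sequence[float]) -> IFN:
    """Intuitionistic dynamic weighted average: ``(1 - prod (1-mu)^e, prod nu^e)``."""
    wv = as_weights(eps, "time", len(series))
    mu, nu = q_weighted_average(
        [f.mu for f in series], [f.nu for f in series], wv.weights, q=1
    )
    return IFN(mu, nu, flagged=mu + nu > 1.0 + _TOL)


def ifdywg(series: Sequence[IFN], eps: WeightVector | Sequence[float]) -> IFN:
    """Intuitionistic dynamic weighted geometric: ``(prod mu^e, 1 - prod (1-nu)^e)``."""
    wv = as_weights(eps, "time", len(series))
    mu, nu = q_weighted_geometric(
        [f.mu for f in series], [f.nu for f in series], wv.weights, q=1
    )
    return IFN(mu, nu, flagged=mu + nu > 1.0 + _TOL)


def if_score(f: IFN) -> float:
    """Score ``mu - nu`` in ``[-1, 1]``."""
    return f.mu - f.nu


def if_accuracy(f: IFN) -> float:
    """Accuracy ``mu + nu`` in ``[0, 1]`` for valid IFNs."""
    return f.mu + f.nu


def run_baseline(
    tensor: TemporalDecisionTensor,
    eps: WeightVector | Sequence[float],
    omega: WeightVector | Sequence[float],
    family: str = "ifdywa",
    mode: str = "permissive",
) -> RankingReport:
    """Two-stage pipeline under the intuitionistic operators.

    The tensor's cells are reinterpreted as IF pairs. In strict mode any
    cell with ``mu + nu > 1`` raises; in permissive mode (the default, since
    Fermatean-elicited data routinely exceed the IF region) violations are
    listed in the report's ``violations`` field.
    """
    if family not in BASELINE_FAMILIES:
        raise ValueError(f"family must be one of {BASELINE_FAMILIES}, got {family!r}")
    op = ifdywa if family == "ifdywa" else ifdywg
    m, n, p = tensor.shape
    wv_eps = as_weights(eps, "time", p)
    wv_om = as_weights(omega, "attribute", n)

    violations: list[str] = []
    cells: list[list[list[IFN]]] = []
    for i, row in enumerate(tensor.cells):
        cells.append([])
        for j, series in enumerate(row):
            converted = []
            for k, f in enumerate(series):
                g = make_ifn(f.mu, f.nu, mode=mode)
                if g.flagged:
                    violations.append(
                        f"({tensor.alternatives[i]}, {tensor.attributes[j]}, "
                        f"{tensor.periods[k]}): mu + nu = {g.mu + g.nu:.3f} > 1"
                    )
                converted.append(g)
            cells[-1].append(converted)

    collective = tuple(
        tuple(op(cells[i][j], wv_eps) for j in range(n)) for i in range(m)
    )
    overall = tuple(op(collective[i], wv_om) for i in range(m))
    scores = tuple(if_score(f) for f in overall)
    accuracies = tuple(if_accuracy(f) for f in overall)
    order = sorted(range(m), key=lambda i: (-scores[i], -accuracies[i], i))
    groups: list[list[str]] = []
    prev = -1
    for pos, idx in enumerate(order):
        tied = (
            pos > 0
            and abs(scores[prev] - scores[idx]) <= 1e-12
            and abs(accuracies[prev] - accuracies[idx]) <= 1e-12
        )
        if tied:
            groups[-1].append(tensor.alternatives[idx])
        else:
            groups.append([tensor.alternatives[idx]])
        prev = idx
    return RankingReport(
        variant=family,
        alternatives=tensor.alternatives,
        collective=collective,
        overall=overall,
        scores=scores,
        accuracies=accuracies,
        ranking=tuple(tuple(g) for g in groups),
        violations=tuple(violations),
    )
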