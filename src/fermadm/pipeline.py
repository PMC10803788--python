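"""Two-stage dynamic MADM procedure: time aggregation, attribute
aggregation, scoring, ranking.

The decision problem is an ``m x n x p`` tensor of FFNs: ``m`` alternatives
judged against ``n`` attributes over ``p`` time periods. Stage 1 collapses
time per cell with FFDyWA (averaging variant) or FFDyWG (geometric variant)
under the time weights ``eps``, yielding the collective ``m x n`` matrix.
Stage 2 collapses each row across attributes with the matching power-form
operator under the attribute weights ``omega``, yielding one overall FFN per
alternative. Alternatives are then ordered by score ``mu^3 - nu^3`` with
accuracy ``mu^3 + nu^3`` breaking ties; residual ties are reported as
explicit groups rather than broken arbitrarily.

``collective_decimals`` optionally truncates the collective matrix to a
fixed number of decimals between the stages, mirroring the common practice
of tabulating intermediate matrices at three decimals before re-aggregating
them; the default is full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core import FFN, Ordering, accuracy, compare, make_ffn, score
from .dynamic import ffdywa, ffdywg
from .static import ffwa_power, ffwg_power
from .weights import WeightVector, as_weights

__all__ = [
    "TemporalDecisionTensor",
    "RankingReport",
    "aggregate_time",
    "aggregate_attributes",
    "rank",
    "run_method",
    "VARIANTS",
]

VARIANTS = ("averaging", "geometric")


@dataclass(frozen=True)
class TemporalDecisionTensor:
    """Labelled ``m x n x p`` array of FFNs, indexed ``cells[i][j][k]``."""

    cells: tuple[tuple[tuple[FFN, ...], ...], ...]
    alternatives: tuple[str, ...]
    attributes: tuple[str, ...]
    periods: tuple[str, ...]

    def __post_init__(self) -> None:
        m, n, p = len(self.alternatives), len(self.attributes), len(self.periods)
        if min(m, n, p) < 1:
            raise ValueError("tensor needs at least one alternative, attribute and period")
        for labels, kind in (
            (self.alternatives, "alternative"),
            (self.attributes, "attribute"),
            (self.periods, "period"),
        ):
            if len(set(labels)) != len(labels):
                raise ValueError(f"{kind} labels must be unique: {labels}")
        if len(self.cells) != m:
            raise ValueError(f"expected {m} alternative rows, got {len(self.cells)}")
        for i, row in enumerate(self.cells):
            if len(row) != n:
                raise ValueError(
                    f"alternative {self.alternatives[i]!r}: expected {n} attribute "
                    f"columns, got {len(row)}"
                )
            for j, series in enumerate(row):
                if len(series) != p:
                    raise ValueError(
                        f"cell ({self.alternatives[i]!r}, {self.attributes[j]!r}): "
                        f"expected {p} periods, got {len(series)}"
                    )

    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.alternatives), len(self.attributes), len(self.periods)

    @classmethod
    def from_period_matrices(
        cls,
        matrices: Sequence[Sequence[Sequence[tuple[float, float] | FFN]]],
        alternatives: Sequence[str] | None = None,
        attributes: Sequence[str] | None = None,
        periods: Sequence[str] | None = None,
        mode: str = "strict",
    ) -> "TemporalDecisionTensor":
        """Build from ``p`` matrices of ``m x n`` (mu, nu) pairs, one per period."""
        p = len(matrices)
        if p == 0:
            raise ValueError("need at least one period matrix")
        m = len(matrices[0])
        n = len(matrices[0][0]) if m else 0
        alternatives = tuple(alternatives or (f"A{i + 1}" for i in range(m)))
        attributes = tuple(attributes or (f"C{j + 1}" for j in range(n)))
        periods = tuple(periods or (f"t{k + 1}" for k in range(p)))
        cells = []
        for i in range(m):
            row = []
            for j in range(n):
                series = []
                for k in range(p):
                    try:
                        entry = matrices[k][i][j]
                    except IndexError:
                        raise ValueError(
                            f"period {periods[k]!r} matrix is missing cell "
                            f"({alternatives[i]!r}, {attributes[j]!r})"
                        ) from None
                    f = entry if isinstance(entry, FFN) else make_ffn(*entry, mode=mode)
                    series.append(f)
                row.append(tuple(series))
            cells.append(tuple(row))
        return cls(tuple(cells), alternatives, attributes, periods)

    def series(self, i: int, j: int) -> tuple[FFN, ...]:
        return self.cells[i][j]


@dataclass(frozen=True)
class RankingReport:
    """End-to-end result of one pipeline run."""

    variant: str
    alternatives: tuple[str, ...]
    collective: tuple[tuple[FFN, ...], ...]
    overall: tuple[FFN, ...]
    scores: tuple[float, ...]
    accuracies: tuple[float, ...]
    ranking: tuple[tuple[str, ...], ...]  # tie groups, best first
    violations: tuple[str, ...] = field(default=())

    def ranking_string(self) -> str:
        """Human-readable total order, e.g. ``A4 > A1 > {A2, A3}``."""
        parts = [
            g[0] if len(g) == 1 else "{" + ", ".join(g) + "}" for g in self.ranking
        ]
        return " ≻ ".join(parts)

    def best(self) -> tuple[str, ...]:
        """The optimal choice(s): the leading tie group."""
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "alternatives": list(self.alternatives),
            "collective": [
                [[f.mu, f.nu] for f in row] for row in self.collective
            ],
            "overall": [[f.mu, f.nu] for f in self.overall],
            "scores": list(self.scores),
            "accuracies": list(self.accuracies),
            "ranking": [list(g) for g in self.ranking],
            "violations": list(self.violations),
        }


def _pick(variant: str) -> tuple[Callable, Callable]:
    if variant == "averaging":
        return ffdywa, ffwa_power
    if variant == "geometric":
        return ffdywg, ffwg_power
    raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")


def aggregate_time(
    tensor: TemporalDecisionTensor,
    eps: WeightVector | Sequence[float],
    variant: str = "averaging",
) -> tuple[tuple[FFN, ...], ...]:
    """Stage 1: collapse the period axis, cell by cell."""
    time_op, _ = _pick(variant)
    wv = as_weights(eps, "time", tensor.shape[2])
    return tuple(
        tuple(time_op(series, wv) for series in row) for row in tensor.cells
    )


def aggregate_attributes(
    matrix: Sequence[Sequence[FFN]],
    omega: WeightVector | Sequence[float],
    variant: str = "averaging",
) -> tuple[FFN, ...]:
    """Stage 2: collapse each row of the collective matrix to one FFN."""
    _, attr_op = _pick(variant)
    n = len(matrix[0])
    wv = as_weights(omega, "attribute", n)
    for i, row in enumerate(matrix):
        if len(row) != n:
            raise ValueError(f"row {i} has {len(row)} entries, expected {n}")
    return tuple(attr_op(row, wv) for row in matrix)


def rank(
    overall: Sequence[FFN], labels: Sequence[str]
) -> tuple[tuple[tuple[str, ...], ...], tuple[float, ...], tuple[float, ...]]:
    """Order alternatives by score then accuracy, grouping residual ties.

    Returns ``(tie_groups, scores, accuracies)``; input order is preserved
    within a group.
    """
    if len(overall) != len(labels):
        raise ValueError("one label per overall value required")
    scores = tuple(score(f) for f in overall)
    accuracies = tuple(accuracy(f) for f in overall)
    order = sorted(
        range(len(overall)), key=lambda i: (-scores[i], -accuracies[i], i)
    )
    groups: list[list[str]] = []
    prev = -1
    for pos, idx in enumerate(order):
        if pos > 0 and compare(overall[prev], overall[idx]) is Ordering.EQUIVALENT:
            groups[-1].append(labels[idx])
        else:
            groups.append([labels[idx]])
        prev = idx
    return tuple(tuple(g) for g in groups), scores, accuracies


def _truncate(x: float, decimals: int) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale) / scale


def run_method(
    tensor: TemporalDecisionTensor,
    eps: WeightVector | Sequence[float],
    omega: WeightVector | Sequence[float],
    variant: str = "averaging",
    collective_decimals: int | None = None,
) -> RankingReport:
    """Run the full two-stage procedure and return a deterministic report."""
    try:
        collective = aggregate_time(tensor, eps, variant)
    except ValueError as exc:
        raise ValueError(f"time aggregation failed: {exc}") from exc
    if collective_decimals is not None:
        collective = tuple(
            tuple(
                FFN(_truncate(f.mu, collective_decimals), _truncate(f.nu, collective_decimals))
                for f in row
            )
            for row in collective
        )
    try:
        overall = aggregate_attributes(collective, omega, variant)
    except ValueError as exc:
        raise ValueError(f"attribute aggregation failed: {exc}") from exc
    groups, scores, accuracies = rank(overall, tensor.alternatives)
    return RankingReport(
        variant=variant,
        alternatives=tensor.alternatives,
        collective=collective,
        overall=overall,
        scores=scores,
        accuracies=accuracies,
        ranking=groups,
    )
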