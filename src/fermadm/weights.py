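"""Weight vectors for time periods and attributes."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["WEIGHT_SUM_TOL", "WeightVector"]

#: Allowed deviation of the weight sum from 1; user files carry rounded weights.
WEIGHT_SUM_TOL = 1e-6


@dataclass(frozen=True, slots=True)
class WeightVector:
    """Nonnegative weights summing to 1, labelled ``"time"`` or ``"attribute"``."""

    weights: tuple[float, ...]
    label: str = "time"

    def __post_init__(self) -> None:
        if self.label not in ("time", "attribute"):
            raise ValueError(f"label must be 'time' or 'attribute', got {self.label!r}")
        if len(self.weights) == 0:
            raise ValueError("weight vector must be non-empty")
        for w in self.weights:
            if not (math.isfinite(w) and 0.0 <= w <= 1.0):
                raise ValueError(
                    f"{self.label} weights must lie in [0, 1], got {w!r}"
                )
        total = math.fsum(self.weights)
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(
                f"{self.label} weights must sum to 1 (got {total:.8f}); "
                "pass normalize=True to WeightVector.of to rescale"
            )

    @classmethod
    def of(
        cls,
        weights: Iterable[float],
        label: str = "time",
        normalize: bool = False,
    ) -> "WeightVector":
        """Build a weight vector, optionally rescaling to unit sum."""
        ws = tuple(float(w) for w in weights)
        if normalize:
            total = math.fsum(ws)
            if total <= 0:
                raise ValueError(f"cannot normalize {label} weights summing to {total}")
            ws = tuple(w / total for w in ws)
        return cls(ws, label)

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self):
        return iter(self.weights)


def as_weights(
    eps: "WeightVector | Sequence[float]", label: str, n: int
) -> WeightVector:
    """Coerce raw sequences to a validated WeightVector of expected length."""
    wv = eps if isinstance(eps, WeightVector) else WeightVector.of(eps, label)
    if len(wv) != n:
        raise ValueError(
            f"{wv.label} weight vector has length {len(wv)}, expected {n}"
        )
    return wv
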