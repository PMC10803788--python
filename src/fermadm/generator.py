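"""Seeded synthetic decision-tensor generator.

Cells are drawn uniformly from the admissible orthopair region: ``mu`` is
uniform on ``[0, 1]`` and, conditional on it, ``nu`` is uniform on
``[0, (1 - mu**q) ** (1/q)]`` with ``q = 3`` (Fermatean) or ``q = 1``
(intuitionistic). Every draw therefore satisfies the constraint by
construction, and identical configurations reproduce identical tensors.
All randomness flows through one ``numpy`` generator seeded from the
config; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FFN
from .pipeline import TemporalDecisionTensor

__all__ = ["GeneratorConfig", "generate_tensor"]


@dataclass(frozen=True, slots=True)
class GeneratorConfig:
    m: int
    n: int
    p: int
    seed: int
    constraint_exponent: int = 3

    def __post_init__(self) -> None:
        if min(self.m, self.n, self.p) < 1:
            raise ValueError("m, n and p must all be positive")
        if self.constraint_exponent not in (1, 3):
            raise ValueError(
                f"constraint_exponent must be 1 or 3, got {self.constraint_exponent}"
            )


def generate_tensor(config: GeneratorConfig) -> TemporalDecisionTensor:
    """Draw a reproducible ``m x n x p`` tensor of valid orthopair cells."""
    rng = np.random.default_rng(config.seed)
    q = config.constraint_exponent
    mu = rng.uniform(size=(config.m, config.n, config.p))
    cap = (1.0 - mu**q) ** (1.0 / q)
    nu = rng.uniform(size=mu.shape) * cap
    cells = tuple(
        tuple(
            tuple(FFN(float(mu[i, j, k]), float(nu[i, j, k])) for k in range(config.p))
            for j in range(config.n)
        )
        for i in range(config.m)
    )
    return TemporalDecisionTensor(
        cells,
        alternatives=tuple(f"A{i + 1}" for i in range(config.m)),
        attributes=tuple(f"C{j + 1}" for j in range(config.n)),
        periods=tuple(f"t{k + 1}" for k in range(config.p)),
    )
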