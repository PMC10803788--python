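"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import math

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from fermadm import FFN, all_treatment

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=150,
    suppress_health_check=[HealthCheck.filter_too_much],
)
settings.load_profile("det")


@st.composite
def ffns(draw) -> FFN:
    """A valid FFN: mu uniform-ish, nu scaled into the admissible cap."""
    mu = draw(st.floats(0.0, 1.0, allow_nan=False))
    frac = draw(st.floats(0.0, 1.0, allow_nan=False))
    cap = math.cbrt(max(1.0 - mu**3, 0.0))
    return FFN(mu, min(frac * cap, cap))


@st.composite
def ffn_series(draw, min_size: int = 1, max_size: int = 6):
    vals = draw(st.lists(ffns(), min_size=min_size, max_size=max_size))
    # weights summing to 1 exactly in float, each in [0, 1]
    raw = draw(
        st.lists(
            st.floats(0.05, 1.0), min_size=len(vals), max_size=len(vals)
        )
    )
    total = math.fsum(raw)
    ws = [r / total for r in raw]
    ws[-1] = 1.0 - math.fsum(ws[:-1])
    return vals, ws


@pytest.fixture(scope="session")
def treatment_case():
    """The packaged 4x5x3 treatment-selection tensor with its weights."""
    return all_treatment()


#: Published collective matrix of the averaging method (3-decimal tabulation).
TABLE_AVG = [
    [(0.674, 0.528), (0.683, 0.528), (0.877, 0.489), (0.8, 0.528), (0.756, 0.403)],
    [(0.775, 0.648), (0.784, 0.607), (0.674, 0.478), (0.647, 0.677), (0.656, 0.655)],
    [(0.574, 0.607), (0.583, 0.505), (0.775, 0.547), (0.656, 0.472), (0.555, 0.505)],
    [(0.864, 0.518), (0.775, 0.478), (0.388, 0.543), (0.825, 0.447), (0.784, 0.528)],
]

#: Published collective matrix of the geometric method.
TABLE_GEO = [
    [(0.668, 0.571), (0.678, 0.535), (0.868, 0.523), (0.8, 0.571), (0.748, 0.411)],
    [(0.768, 0.656), (0.778, 0.658), (0.668, 0.483), (0.668, 0.754), (0.648, 0.711)],
    [(0.568, 0.658), (0.578, 0.557), (0.768, 0.555), (0.648, 0.499), (0.547, 0.521)],
    [(0.834, 0.524), (0.768, 0.483), (0.362, 0.639), (0.769, 0.456), (0.778, 0.535)],
]

OMEGA = [0.3, 0.25, 0.1, 0.2, 0.15]
EPS = [0.2, 0.3, 0.5]
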