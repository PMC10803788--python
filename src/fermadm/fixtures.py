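"""Packaged case-study fixture.

``all_treatment()`` returns the 4x5x3 leukemia treatment-selection tensor:
four therapy alternatives (chemotherapy, hematopoietic stem-cell
transplantation, radiation therapy, CAR T-cell therapy) evaluated against
survival rate, remission, side effects, efficiency and reliability over
three two-year periods, with time weights (0.2, 0.3, 0.5) and attribute
weights (0.3, 0.25, 0.1, 0.2, 0.15).
"""

from __future__ import annotations

from importlib import resources

from .io import load_tensor
from .pipeline import TemporalDecisionTensor
from .weights import WeightVector

__all__ = ["all_treatment"]


def all_treatment() -> tuple[TemporalDecisionTensor, WeightVector, WeightVector]:
    """Load the packaged treatment-selection tensor and its weight vectors."""
    ref = resources.files("fermadm.data") / "all_treatment.json"
    with resources.as_file(ref) as path:
        return load_tensor(path, format="json")
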