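"""Bioequivalence windows and verdicts.

Builds acceptance windows on ARC (and, through the IVIVC model, on predicted
AUC) around the pooled reference ARC, and classifies test products by whether
their ARC falls inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ivivc import IVIVCModel, predict_auc

__all__ = ["BEBounds", "BEVerdict", "be_limits", "classify_be"]

#: regulatory ratio limits as conventionally printed (≤20% difference)
DEFAULT_LOWER_RATIO = 0.7999
DEFAULT_UPPER_RATIO = 1.2501


@dataclass
class BEBounds:
    """Acceptance windows on ARC and on model-predicted AUC."""

    lower_ratio: float
    upper_ratio: float
    pooled_reference_arc: float  # µg/cm²/min^½
    arc_lower: float
    arc_upper: float
    auc_lower: float  # µg·% skin depth
    auc_upper: float

    def __post_init__(self) -> None:
        if not self.lower_ratio < 1 < self.upper_ratio:
            raise ValueError("ratios must bracket 1 (lower < 1 < upper)")
        if not self.arc_lower < self.arc_upper:
            raise ValueError("ARC window is empty")
        if not self.auc_lower < self.auc_upper:
            raise ValueError("AUC window is empty")


@dataclass
class BEVerdict:
    """BE classification of one product against reference-derived windows."""

    product_id: str
    arc: float
    predicted_auc: float
    within_arc_window: bool
    within_auc_window: bool
    verdict: str = field(init=False)  # "BE" | "non-BE", driven by the ARC window

    def __post_init__(self) -> None:
        self.verdict = "BE" if self.within_arc_window else "non-BE"


def be_limits(model: IVIVCModel, reference_arcs: Sequence[float],
              lower_ratio: float = DEFAULT_LOWER_RATIO,
              upper_ratio: float = DEFAULT_UPPER_RATIO) -> BEBounds:
    """Acceptance windows from the pooled reference ARC and the IVIVC model.

    The pooled reference ARC is the arithmetic mean of the per-run reference
    ARCs; the ARC window scales it by the ratio limits and the AUC window maps
    the ARC window through the model.
    """
    if len(reference_arcs) == 0:
        raise ValueError("need at least one reference ARC")
    pooled = float(np.mean(reference_arcs))
    arc_lower = pooled * lower_ratio
    arc_upper = pooled * upper_ratio
    return BEBounds(
        lower_ratio=lower_ratio,
        upper_ratio=upper_ratio,
        pooled_reference_arc=pooled,
        arc_lower=arc_lower,
        arc_upper=arc_upper,
        auc_lower=predict_auc(model, arc_lower),
        auc_upper=predict_auc(model, arc_upper),
    )


def classify_be(product_id: str, arc: float, bounds: BEBounds,
                model: IVIVCModel) -> BEVerdict:
    """Inclusive window test on ARC; the AUC window is reported alongside."""
    pred = predict_auc(model, arc)
    return BEVerdict(
        product_id=product_id,
        arc=arc,
        predicted_auc=pred,
        within_arc_window=bool(bounds.arc_lower <= arc <= bounds.arc_upper),
        within_auc_window=bool(bounds.auc_lower <= pred <= bounds.auc_upper),
    )
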