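"""Level C in vitro–in vivo correlation.

Linear regression of in vivo tape-strip AUC on in vitro apparent release
constant (ARC), prediction of AUCs from ARCs, and the two-value CV measure
of observed-versus-predicted agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IVIVCPoint",
    "IVIVCModel",
    "fit_level_c",
    "predict_auc",
    "prediction_cv",
]


@dataclass(frozen=True)
class IVIVCPoint:
    """One product/run pairing of in vitro ARC with in vivo AUC.

    A product measured in more than one IVRT run contributes one point per
    run, with the same observed AUC attached to each.
    """

    product_id: str
    run_label: str
    arc: float  # µg/cm²/min^½
    auc: float  # µg·% skin depth

    def __post_init__(self) -> None:
        if self.arc <= 0:
            raise ValueError("arc must be > 0")
        if self.auc < 0:
            raise ValueError("auc must be ≥ 0")


@dataclass
class IVIVCModel:
    """AUC = slope · ARC + intercept, with fit diagnostics."""

    slope: float  # µg·%depth per µg/cm²/min^½
    intercept: float  # µg·%depth
    r_squared: float
    points: list[IVIVCPoint]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("an IVIVC model needs ≥3 points")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")

    @property
    def n_points(self) -> int:
        return len(self.points)


def fit_level_c(points: Sequence[IVIVCPoint],
                weights: Sequence[float] | None = None) -> IVIVCModel:
    """Ordinary least squares of AUC on ARC over product/run points.

    ``weights`` enables an optional weighted fit (e.g. 1/SD²); the default is
    unweighted OLS.
    """
    if len(points) < 3:
        raise ValueError(f"need ≥3 points, have {len(points)}")
    x = np.array([p.arc for p in points])
    y = np.array([p.auc for p in points])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ARC: correlation not identifiable")
    if weights is None:
        res = stats.linregress(x, y)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
        if not np.isfinite(r2):  # zero variance in AUC: the flat fit is exact
            r2 = 1.0
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(points) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per point")
        coef = np.polyfit(x, y, 1, w=np.sqrt(w))
        slope, intercept = coef
        fitted = slope * x + intercept
        ybar = np.average(y, weights=w)
        ss_res = np.sum(w * (y - fitted) ** 2)
        ss_tot = np.sum(w * (y - ybar) ** 2)
        r2 = 1 - ss_res / ss_tot
    return IVIVCModel(slope=float(slope), intercept=float(intercept),
                      r_squared=float(r2), points=list(points))


def predict_auc(model: IVIVCModel, arc: float) -> float:
    """Predicted in vivo AUC for a given ARC (full precision)."""
    if arc <= 0:
        raise ValueError("arc must be > 0")
    return model.slope * arc + model.intercept


def prediction_cv(observed: float, predicted: float) -> float:
    """Two-value CV (%) between an observed and a predicted AUC.

    Sample SD of the pair (n−1, i.e. |obs − pred|/√2) over the pair mean,
    times 100.
    """
    mean = (observed + predicted) / 2.0
    if mean <= 0:
        raise ValueError("mean of observed and predicted must be > 0")
    return abs(observed - predicted) / math.sqrt(2.0) / mean * 100.0


def max_prediction_cv(pairs: Sequence[tuple[float, float]]) -> float:
    """Maximum two-value CV (%) over (observed, predicted) pairs."""
    if not pairs:
        raise ValueError("no pairs supplied")
    return max(prediction_cv(o, p) for o, p in pairs)
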