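"""Plain-text report tables for the IVIVC/BE pipeline.

Displayed values are rounded half-to-even at 2 decimals; everything is
computed and stored at full precision upstream.
"""

from __future__ import annotations

from typing import Sequence

from .be import BEBounds, BEVerdict
from .ivivc import IVIVCModel, predict_auc, prediction_cv


def _r2(x: float) -> str:
    return f"{round(x, 2):.2f}"


def correlation_table(model: IVIVCModel,
                      observed_sd: dict[tuple[str, str], float] | None = None,
                      arc_sd: dict[tuple[str, str], float] | None = None) -> str:
    """Observed vs predicted AUC per product/run point (Table-1 style)."""
    lines = [
        "Product/run        Observed AUC        ARC                 Predicted AUC",
        "                   (ug.% skin depth)   (ug/cm2/min^1/2)    (ug.% skin depth)",
        "-" * 78,
    ]
    for p in model.points:
        key = (p.product_id, p.run_label)
        obs = _r2(p.auc)
        if observed_sd and key in observed_sd:
            obs += f" ± {_r2(observed_sd[key])}"
        arc = _r2(p.arc)
        if arc_sd and key in arc_sd:
            arc += f" ± {_r2(arc_sd[key])}"
        pred = _r2(predict_auc(model, p.arc))
        label = f"{p.product_id} ({p.run_label})"
        lines.append(f"{label:<19}{obs:<20}{arc:<20}{pred}")
    max_cv = max(prediction_cv(p.auc, predict_auc(model, p.arc)) for p in model.points)
    lines.append("-" * 78)
    lines.append(
        f"Fit: AUC = {model.slope:.4f}·ARC + {model.intercept:.3f}   "
        f"R² = {model.r_squared:.4f}   n = {model.n_points}"
    )
    lines.append(f"Max observed-vs-predicted CV (two-value, n−1): {_r2(max_cv)}%")
    lines.append("CV uses the pair sample SD (|obs−pred|/√2) over the pair mean.")
    return "\n".join(lines)


def be_limits_table(bounds: BEBounds) -> str:
    """BE acceptance windows (Table-2 style)."""
    lines = [
        "BE limits          Predicted AUC       ARC",
        "                   (ug.% skin depth)   (ug/cm2/min^1/2)",
        "-" * 58,
        f"{bounds.lower_ratio} (lower)    {_r2(bounds.auc_lower):<20}{_r2(bounds.arc_lower)}",
        f"{bounds.upper_ratio} (upper)    {_r2(bounds.auc_upper):<20}{_r2(bounds.arc_upper)}",
        "-" * 58,
        f"Pooled reference ARC: {_r2(bounds.pooled_reference_arc)}",
    ]
    return "\n".join(lines)


def verdict_lines(verdicts: Sequence[BEVerdict]) -> str:
    lines = []
    for v in verdicts:
        lines.append(
            f"{v.product_id}: ARC {_r2(v.arc)} "
            f"({'inside' if v.within_arc_window else 'outside'} ARC window), "
            f"predicted AUC {_r2(v.predicted_auc)} "
            f"({'inside' if v.within_auc_window else 'outside'} AUC window) "
            f"→ {v.verdict}"
        )
    return "\n".join(lines)
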