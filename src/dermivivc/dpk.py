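"""Tape-stripping (dermatopharmacokinetic) analysis.

Converts per-strip tape weights into removed stratum-corneum mass, estimates
each participant's SC thickness from blank-site TEWL readings, builds
drug-amount versus relative-SC-depth profiles, and integrates them into
per-participant and study-level AUCs (µg·% skin depth).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy import stats

__all__ = [
    "StripSite",
    "TEWLSeries",
    "SCProfile",
    "AUCResult",
    "strip_masses",
    "estimate_sc_thickness_tewl",
    "relative_depth_profile",
    "profile_auc",
    "study_auc",
]

#: weights are in µg; reweighing noise below this magnitude is clipped to zero
NEGATIVE_MASS_TOLERANCE_UG = 5.0


@dataclass
class StripSite:
    """One participant/site tape-strip record (20 sequential strips)."""

    participant_id: str
    arm: str
    site: str
    product_id: str  # "" or "blank" for the blank site
    strip_index: np.ndarray  # 1..n, sequential
    pre_weight: np.ndarray  # µg
    post_weight: np.ndarray  # µg
    drug_amount: np.ndarray  # µg
    site_area: float = 4.0  # cm²
    application_time: float = 60.0  # min

    def __post_init__(self) -> None:
        self.strip_index = np.asarray(self.strip_index, dtype=int)
        self.pre_weight = np.asarray(self.pre_weight, dtype=float)
        self.post_weight = np.asarray(self.post_weight, dtype=float)
        self.drug_amount = np.asarray(self.drug_amount, dtype=float)
        n = len(self.strip_index)
        for name in ("pre_weight", "post_weight", "drug_amount"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match strip count {n}")
        if not np.array_equal(self.strip_index, np.arange(1, n + 1)):
            raise ValueError("strips must be sequential, indexed 1..n")
        if np.any(self.drug_amount < 0):
            raise ValueError("negative drug amount")
        if self.site_area <= 0:
            raise ValueError("site_area must be > 0")

    @property
    def n_strips(self) -> int:
        return len(self.strip_index)


@dataclass
class TEWLSeries:
    """Blank-site TEWL readings over progressive stripping."""

    participant_id: str
    cumulative_mass: np.ndarray  # µg of SC removed before each reading
    tewl: np.ndarray  # g/m²/h

    def __post_init__(self) -> None:
        self.cumulative_mass = np.asarray(self.cumulative_mass, dtype=float)
        self.tewl = np.asarray(self.tewl, dtype=float)
        if len(self.cumulative_mass) != len(self.tewl):
            raise ValueError("cumulative_mass and tewl must have equal length")
        if np.any(np.diff(self.cumulative_mass) <= 0):
            raise ValueError("cumulative mass must be strictly increasing")
        if np.any(self.tewl <= 0):
            raise ValueError("TEWL readings must be positive")


@dataclass
class SCProfile:
    """Drug amount per strip against relative SC depth (% of thickness L)."""

    participant_id: str
    product_id: str
    relative_depth_percent: np.ndarray  # strip midpoint, % of L
    drug_amount: np.ndarray  # µg
    sc_thickness_um: float
    total_depth_um: float
    beyond_full_thickness: np.ndarray = field(default=None)  # per-strip flag
    dropped_strips: int = 0

    def __post_init__(self) -> None:
        self.relative_depth_percent = np.asarray(self.relative_depth_percent, dtype=float)
        self.drug_amount = np.asarray(self.drug_amount, dtype=float)
        if self.beyond_full_thickness is None:
            self.beyond_full_thickness = np.zeros(len(self.drug_amount), dtype=bool)
        if len(self.relative_depth_percent) != len(self.drug_amount):
            raise ValueError("depth and drug arrays must have equal length")
        if np.any(np.diff(self.relative_depth_percent) <= 0):
            raise ValueError("relative depths must be strictly increasing")

    @property
    def total_depth_percent(self) -> float:
        return 100.0 * self.total_depth_um / self.sc_thickness_um


@dataclass
class AUCResult:
    """Study-level AUC summary for one product."""

    product_id: str
    participant_ids: list[str]
    participant_aucs: np.ndarray  # µg·% skin depth
    auc_mean: float = field(init=False)
    auc_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.participant_aucs = np.asarray(self.participant_aucs, dtype=float)
        if len(self.participant_aucs) < 2:
            raise ValueError("need ≥2 participants for a study summary")
        self.auc_mean = float(np.mean(self.participant_aucs))
        self.auc_sd = float(np.std(self.participant_aucs, ddof=1))

    @property
    def n_participants(self) -> int:
        return len(self.participant_aucs)


def strip_masses(site: StripSite,
                 tolerance: float = NEGATIVE_MASS_TOLERANCE_UG) -> np.ndarray:
    """Per-strip SC mass removed (µg): post-weight minus pre-weight.

    Differences in (−tolerance, 0) are weighing noise and are clipped to zero
    with a warning; anything below −tolerance is a data error.
    """
    missing = np.flatnonzero(np.isnan(site.pre_weight) | np.isnan(site.post_weight))
    if missing.size:
        raise ValueError(
            f"missing weights at strip index {site.strip_index[missing[0]]}"
        )
    masses = site.post_weight - site.pre_weight
    bad = masses < -tolerance
    if np.any(bad):
        raise ValueError(
            f"post-weight below pre-weight beyond tolerance at strip index "
            f"{site.strip_index[np.flatnonzero(bad)[0]]}"
        )
    if np.any(masses < 0):
        warnings.warn(
            f"{site.participant_id}/{site.site}: clipped "
            f"{int(np.sum(masses < 0))} slightly negative strip mass(es) to 0",
            stacklevel=2,
        )
        masses = np.clip(masses, 0.0, None)
    return masses


def mass_to_depth_um(mass_ug: np.ndarray | float, site_area: float,
                     sc_density: float = 1.0) -> np.ndarray | float:
    """SC depth (µm) removed by a given SC mass (µg) over ``site_area`` cm².

    depth[cm] = mass[g] / (area[cm²] · density[g/cm³]); 1 cm = 1e4 µm.
    """
    return np.asarray(mass_ug) * 1e-6 / (site_area * sc_density) * 1e4


def estimate_sc_thickness_tewl(series: TEWLSeries, site_area: float,
                               sc_density: float = 1.0,
                               r_squared_floor: float = 0.8) -> float:
    """SC thickness L (µm) by linear extrapolation of 1/TEWL to zero.

    Under Fick steady state TEWL ∝ 1/(L − x), so 1/TEWL is linear in removed
    depth x and hits zero at x = L. Fits 1/TEWL = a − b·x and returns a/b.
    """
    if len(series.tewl) < 3:
        raise ValueError("need ≥3 TEWL readings")
    x = mass_to_depth_um(series.cumulative_mass, site_area, sc_density)
    y = 1.0 / series.tewl
    res = stats.linregress(x, y)
    b = -res.slope
    r2 = res.rvalue**2
    if b <= 0 or r2 < r_squared_floor:
        raise ValueError(
            f"thickness not identifiable: slope sign {'ok' if b > 0 else 'wrong'}, "
            f"R²={r2:.3f} (floor {r_squared_floor})"
        )
    return float(res.intercept / b)


def relative_depth_profile(site: StripSite, sc_thickness_um: float,
                           sc_density: float = 1.0, drop_first_n: int = 0,
                           position: Literal["midpoint", "leading", "trailing"] = "midpoint",
                           ) -> SCProfile:
    """Drug-vs-relative-depth profile for one stripped site.

    Each strip is plotted at the midpoint (default) of the depth interval it
    removed, as a percent of the participant's SC thickness L. Strips whose
    interval extends beyond 100% of L are retained and flagged; a total depth
    beyond 150% of L indicates a thickness/weighing inconsistency.
    """
    if sc_thickness_um <= 0:
        raise ValueError("SC thickness must be > 0")
    masses = strip_masses(site)
    increments = mass_to_depth_um(masses, site.site_area, sc_density)
    upper = np.cumsum(increments)
    lower = upper - increments
    total_depth = float(upper[-1])
    if total_depth > 1.5 * sc_thickness_um:
        raise ValueError(
            f"total stripped depth {total_depth:.2f} µm exceeds 150% of "
            f"SC thickness {sc_thickness_um:.2f} µm"
        )
    if position == "midpoint":
        pos = (lower + upper) / 2.0
    elif position == "leading":
        pos = lower
    elif position == "trailing":
        pos = upper
    else:
        raise ValueError(f"unknown position rule {position!r}")
    pct = 100.0 * pos / sc_thickness_um
    flags = upper > sc_thickness_um
    keep = slice(drop_first_n, None)
    return SCProfile(
        participant_id=site.participant_id,
        product_id=site.product_id,
        relative_depth_percent=pct[keep],
        drug_amount=site.drug_amount[keep],
        sc_thickness_um=sc_thickness_um,
        total_depth_um=total_depth,
        beyond_full_thickness=flags[keep],
        dropped_strips=drop_first_n,
    )


def profile_auc(profile: SCProfile, anchor_zero: bool = False) -> float:
    """Composite trapezoidal AUC of drug amount over relative depth (%).

    By default integrates only between the first and last plotting positions;
    ``anchor_zero`` adds zero-amount anchor points at 0% depth and at the last
    position (useful when profiles should start/end at zero).
    """
    x = profile.relative_depth_percent
    y = profile.drug_amount
    if len(x) < 2:
        raise ValueError("need ≥2 profile points for an AUC")
    if np.any(np.diff(x) <= 0):
        raise ValueError("profile depths must be strictly increasing")
    if anchor_zero:
        x = np.concatenate([[0.0], x, [x[-1]]])
        y = np.concatenate([[0.0], y, [0.0]])
    return float(np.trapezoid(y, x))


def study_auc(profiles: Iterable[SCProfile], product_id: str,
              average_replicates: bool = True,
              blank_profiles: dict[str, SCProfile] | None = None,
              subtract_blank: bool = False,
              anchor_zero: bool = False) -> AUCResult:
    """Per-participant then study-level AUC for one product.

    Replicate sites within a participant are averaged by default. With
    ``subtract_blank`` each participant's blank-site drug amounts are
    subtracted strip-wise before integration.
    """
    per_participant: dict[str, list[float]] = {}
    for prof in profiles:
        if prof.product_id != product_id:
            continue
        p = prof
        if subtract_blank:
            if blank_profiles is None or prof.participant_id not in blank_profiles:
                raise ValueError(
                    f"blank profile missing for participant {prof.participant_id}"
                )
            blank = blank_profiles[prof.participant_id]
            adjusted = np.clip(
                prof.drug_amount - np.interp(
                    prof.relative_depth_percent,
                    blank.relative_depth_percent,
                    blank.drug_amount,
                ),
                0.0,
                None,
            )
            p = SCProfile(
                participant_id=prof.participant_id,
                product_id=prof.product_id,
                relative_depth_percent=prof.relative_depth_percent,
                drug_amount=adjusted,
                sc_thickness_um=prof.sc_thickness_um,
                total_depth_um=prof.total_depth_um,
            )
        per_participant.setdefault(prof.participant_id, []).append(
            profile_auc(p, anchor_zero=anchor_zero)
        )
    if not per_participant:
        raise ValueError(f"no profiles for product {product_id!r}")
    pids = sorted(per_participant)
    aucs = np.array(
        [np.mean(per_participant[pid]) if average_replicates
         else per_participant[pid][0] for pid in pids]
    )
    return AUCResult(product_id=product_id, participant_ids=pids, participant_aucs=aucs)
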