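"""In vitro release testing (IVRT) analysis.

Turns per-cell receptor concentrations from a vertical-diffusion-cell run
into withdrawal-corrected cumulative release per unit area, fits the
Higuchi (square-root-of-time) model to obtain apparent release constants
(ARCs), and compares test against reference release rates with a
confidence interval on the ARC ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CellRecord",
    "IVRTRun",
    "ReleaseProfile",
    "HiguchiFit",
    "ARCResult",
    "RatioCI",
    "cumulative_release",
    "fit_higuchi",
    "run_arc",
    "release_ratio_ci",
    "orifice_area_from_diameter",
]


def orifice_area_from_diameter(diameter_mm: float) -> float:
    """Circular orifice area in cm² from its diameter in mm."""
    if diameter_mm <= 0:
        raise ValueError(f"orifice diameter must be > 0, got {diameter_mm}")
    radius_cm = diameter_mm / 10.0 / 2.0
    return math.pi * radius_cm**2


@dataclass
class CellRecord:
    """One diffusion cell: receptor concentrations at each sample time."""

    cell_id: str
    times: np.ndarray  # minutes
    concentrations: np.ndarray  # µg/mL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.concentrations.ndim != 1:
            raise ValueError("times and concentrations must be 1-D")
        if len(self.times) != len(self.concentrations):
            raise ValueError(
                f"cell {self.cell_id}: {len(self.concentrations)} concentrations "
                f"for {len(self.times)} sample times"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"cell {self.cell_id}: sample times must be strictly increasing")
        if np.any(self.times <= 0):
            raise ValueError(f"cell {self.cell_id}: sample times must be positive")
        if np.any(self.concentrations < 0):
            raise ValueError(f"cell {self.cell_id}: negative concentration")


@dataclass
class IVRTRun:
    """One product's diffusion-cell experiment."""

    product_id: str
    role: str  # "test" | "reference"
    cells: list[CellRecord]
    cell_volume: float  # mL
    sample_volume: float  # mL
    orifice_area: float  # cm²
    run_id: str = "run1"
    temperature: float = 32.0  # °C, metadata

    def __post_init__(self) -> None:
        if self.role not in ("test", "reference"):
            raise ValueError(f"role must be 'test' or 'reference', got {self.role!r}")
        if len(self.cells) < 2:
            raise ValueError("an IVRT run needs at least 2 cells")
        if self.orifice_area <= 0:
            raise ValueError("orifice_area must be > 0")
        if not 0 < self.sample_volume < self.cell_volume:
            raise ValueError("sample_volume must be positive and smaller than cell_volume")


@dataclass
class ReleaseProfile:
    """Cumulative amount released per unit area at each sample time."""

    cell_id: str
    times: np.ndarray  # minutes
    q: np.ndarray  # µg/cm²

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if len(self.times) != len(self.q):
            raise ValueError("times and Q must have equal length")


@dataclass
class HiguchiFit:
    """Per-cell ordinary least-squares fit of Q on √t."""

    cell_id: str
    slope: float  # µg/cm²/min^½
    intercept: float  # µg/cm²
    r_squared: float
    slope_se: float
    n_points: int


@dataclass
class ARCResult:
    """Run-level apparent release constant: per-cell fits plus mean ± SD."""

    product_id: str
    run_id: str
    fits: list[HiguchiFit]
    arc_mean: float = field(init=False)
    arc_sd: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.fits) < 2:
            raise ValueError("ARCResult needs at least 2 cell fits")
        slopes = self.cell_slopes
        self.arc_mean = float(np.mean(slopes))
        self.arc_sd = float(np.std(slopes, ddof=1))

    @property
    def cell_slopes(self) -> np.ndarray:
        return np.array([f.slope for f in self.fits])

    @property
    def n_cells(self) -> int:
        return len(self.fits)


@dataclass
class RatioCI:
    """Test/reference ratio with a two-sided confidence interval."""

    ratio: float
    lower: float
    upper: float
    level: float = 0.90
    method: str = "log-welch"

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def cumulative_release(cell: CellRecord, *, cell_volume: float, sample_volume: float,
                       orifice_area: float) -> ReleaseProfile:
    """Withdrawal-corrected cumulative release per unit area.

    At sample n the receptor holds ``C_n · V_cell``; every earlier withdrawal
    removed ``C_i · V_sample`` that must be added back because the cell was
    refilled with blank medium:

        Q_n = (C_n · V_cell + Σ_{i<n} C_i · V_sample) / A
    """
    c = cell.concentrations
    withdrawn = np.concatenate([[0.0], np.cumsum(c[:-1] * sample_volume)])
    q = (c * cell_volume + withdrawn) / orifice_area
    return ReleaseProfile(cell_id=cell.cell_id, times=cell.times, q=q)


def fit_higuchi(profile: ReleaseProfile,
                time_window: tuple[float, float] | None = None) -> HiguchiFit:
    """OLS of cumulative release per area on √time (minutes).

    The intercept is estimated, not forced through the origin. An optional
    ``time_window`` (t_min, t_max), inclusive, restricts the points used.
    """
    t = profile.times
    q = profile.q
    if time_window is not None:
        lo, hi = time_window
        keep = (t >= lo) & (t <= hi)
        t, q = t[keep], q[keep]
    if len(t) < 3:
        raise ValueError(
            f"cell {profile.cell_id}: need ≥3 points to fit, have {len(t)}"
        )
    x = np.sqrt(t)
    if np.ptp(x) == 0:
        raise ValueError(f"cell {profile.cell_id}: zero variance in √t")
    res = stats.linregress(x, q)
    return HiguchiFit(
        cell_id=profile.cell_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        n_points=len(t),
    )


def run_arc(run: IVRTRun, time_window: tuple[float, float] | None = None) -> ARCResult:
    """Fit every cell in a run; ARC mean and sample SD (n−1) across cells."""
    fits: list[HiguchiFit] = []
    failures: list[str] = []
    for cell in run.cells:
        profile = cumulative_release(
            cell,
            cell_volume=run.cell_volume,
            sample_volume=run.sample_volume,
            orifice_area=run.orifice_area,
        )
        try:
            fits.append(fit_higuchi(profile, time_window=time_window))
        except ValueError:
            failures.append(cell.cell_id)
    if failures:
        raise ValueError(f"Higuchi fit failed for cells: {', '.join(failures)}")
    return ARCResult(product_id=run.product_id, run_id=run.run_id, fits=fits)


def _welch_df(se_a: float, n_a: int, se_b: float, n_b: int) -> float:
    num = (se_a**2 + se_b**2) ** 2
    den = se_a**4 / (n_a - 1) + se_b**4 / (n_b - 1)
    return num / den


def release_ratio_ci(test: ARCResult, reference: ARCResult, level: float = 0.90,
                     method: str = "log-welch") -> RatioCI:
    """Test/reference ARC ratio with a two-sided CI over per-cell slopes.

    Default method is a Welch two-sample t interval on mean log slopes,
    exponentiated. ``method="fieller"`` gives Fieller's interval for the
    ratio of the untransformed means; use it when slopes can be ≤ 0.
    """
    ts = test.cell_slopes
    rs = reference.cell_slopes
    if len(ts) < 2 or len(rs) < 2:
        raise ValueError("need ≥2 cells on each side")
    ratio = float(np.mean(ts) / np.mean(rs))
    alpha = 1 - level

    if method == "log-welch":
        if np.any(ts <= 0) or np.any(rs <= 0):
            raise ValueError(
                "non-positive slope: log-scale interval undefined; use method='fieller'"
            )
        lt, lr = np.log(ts), np.log(rs)
        se_t = lt.std(ddof=1) / math.sqrt(len(lt))
        se_r = lr.std(ddof=1) / math.sqrt(len(lr))
        se = math.hypot(se_t, se_r)
        if se == 0:
            return RatioCI(ratio=ratio, lower=ratio, upper=ratio, level=level, method=method)
        df = _welch_df(se_t, len(lt), se_r, len(lr))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        diff = lt.mean() - lr.mean()
        return RatioCI(
            ratio=ratio,
            lower=float(math.exp(diff - tcrit * se)),
            upper=float(math.exp(diff + tcrit * se)),
            level=level,
            method=method,
        )

    if method == "fieller":
        mt, mr = ts.mean(), rs.mean()
        se_t = ts.std(ddof=1) / math.sqrt(len(ts))
        se_r = rs.std(ddof=1) / math.sqrt(len(rs))
        if se_t == 0 and se_r == 0:
            return RatioCI(ratio=ratio, lower=ratio, upper=ratio, level=level, method=method)
        df = _welch_df(se_t, len(ts), se_r, len(rs))
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        a = mr**2 - (tcrit * se_r) ** 2
        if a <= 0:
            raise ValueError("Fieller interval unbounded: reference mean not distinguishable from 0")
        b = mt * mr
        c = mt**2 - (tcrit * se_t) ** 2
        disc = b**2 - a * c
        if disc < 0:
            raise ValueError("Fieller interval empty (numerical degeneracy)")
        root = math.sqrt(disc)
        return RatioCI(
            ratio=ratio,
            lower=float((b - root) / a),
            upper=float((b + root) / a),
            level=level,
            method=method,
        )

    raise ValueError(f"unknown CI method {method!r}")
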