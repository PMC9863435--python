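"""Synthetic IVRT and tape-strip study generator.

Produces datasets with the statistical structure the analysis pipeline
assumes — Higuchi √time release sampled with withdrawal dilution, transient
Fickian drug-depth profiles in the stratum corneum after a timed
application, geometrically decaying strip masses, and TEWL series that are
consistent with each participant's SC thickness — so that parameter
recovery can be proven end to end without any external data.

All randomness flows from the integer ``seed`` in the config through a
single ``numpy`` generator stream; identical configs give identical output.
Every simulated object is returned together with the ground truth that was
drawn for it, which is what the zero-noise round-trip tests check against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .dpk import StripSite, TEWLSeries, mass_to_depth_um
from .ivrt import CellRecord, IVRTRun, orifice_area_from_diameter

__all__ = [
    "IVRTSimConfig",
    "TSSimConfig",
    "IVRTTruth",
    "TapeStripStudy",
    "simulate_ivrt_run",
    "sc_concentration_profile",
    "sc_depth_fraction_integral",
    "simulate_tape_strip_study",
]

#: fraction of the SC mass the 20 strips are allowed to remove in total
_STRIP_TOTAL_CAP = 0.9


def _require(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ValueError(f"{fieldname}: {message}")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


@dataclass
class IVRTSimConfig:
    """Design constants and noise levels for one simulated IVRT run."""

    true_arc: float  # µg/cm²/min^½
    intercept_true: float = 0.0  # µg/cm²
    n_cells: int = 6
    sample_times: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0)  # min
    cell_volume: float = 7.9  # mL
    sample_volume: float = 0.2  # mL
    orifice_diameter: float = 15.0  # mm
    noise_cv: float = 0.02
    cell_arc_cv: float = 0.05  # between-cell slope variability
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.true_arc > 0, "true_arc", "must be > 0")
        _require(self.n_cells >= 2, "n_cells", "must be ≥ 2")
        times = np.asarray(self.sample_times, dtype=float)
        _require(bool(np.all(times > 0)), "sample_times", "must be positive")
        _require(bool(np.all(np.diff(times) > 0)), "sample_times",
                 "must be strictly increasing")
        _require(0 < self.sample_volume < self.cell_volume, "sample_volume",
                 "must be positive and smaller than cell_volume")
        _require(self.orifice_diameter > 0, "orifice_diameter", "must be > 0")
        _require(self.noise_cv >= 0, "noise_cv", "must be ≥ 0")
        _require(self.cell_arc_cv >= 0, "cell_arc_cv", "must be ≥ 0")


@dataclass
class TSSimConfig:
    """Design constants and noise levels for one simulated tape-strip study."""

    n_participants: int = 10
    n_strips: int = 20
    site_area: float = 4.0  # cm² (2 × 2 cm)
    dose_mass: float = 15.0  # mg of cream per site
    application_time: float = 60.0  # min
    sc_thickness_mean: float = 10.0  # µm
    sc_thickness_cv: float = 0.2
    strip_mass_first: float = 400.0  # µg removed by the first strip
    strip_mass_decay: float = 0.05  # fractional decline per strip
    strip_mass_cv: float = 0.1
    sc_density: float = 1.0  # g/cm³
    partition_surface_conc: float = 10000.0  # K·Cv, µg/cm³
    diffusivity_ratio: float = 0.002  # D/L², 1/min
    drug_noise_cv: float = 0.05
    tewl_noise_cv: float = 0.05
    tewl_baseline: float = 8.0  # g/m²/h at intact SC
    replicate_sites: int = 1  # sites per product per participant (e.g. 2 arms)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_participants >= 1, "n_participants", "must be ≥ 1")
        _require(self.n_strips >= 3, "n_strips", "must be ≥ 3")
        for name in ("site_area", "dose_mass", "application_time",
                     "sc_thickness_mean", "strip_mass_first", "sc_density",
                     "partition_surface_conc", "diffusivity_ratio",
                     "tewl_baseline"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(0 <= self.strip_mass_decay < 1, "strip_mass_decay",
                 "must be in [0, 1)")
        for name in ("sc_thickness_cv", "strip_mass_cv", "drug_noise_cv",
                     "tewl_noise_cv"):
            _require(getattr(self, name) >= 0, name, "must be ≥ 0")
        _require(self.replicate_sites >= 1, "replicate_sites", "must be ≥ 1")


@dataclass
class IVRTTruth:
    """Ground truth behind one simulated IVRT run."""

    true_arc: float
    cell_slopes: np.ndarray  # slope actually drawn per cell
    intercept: float
    q_true: dict[str, np.ndarray]  # noiseless Q(t) per cell, µg/cm²


def simulate_ivrt_run(config: IVRTSimConfig, product_id: str, *,
                      role: str = "test", run_id: str = "run1",
                      rng: np.random.Generator | None = None,
                      ) -> tuple[IVRTRun, IVRTTruth]:
    """Simulate one diffusion-cell run following Higuchi kinetics.

    Each cell draws its own slope from a lognormal with mean ``true_arc`` and
    CV ``cell_arc_cv``; the noiseless cumulative release Q(t) = slope·√t + b
    is converted to receptor concentrations through the exact inverse of the
    withdrawal-replenishment bookkeeping, so the analysis-side correction
    undoes the dilution identically at zero noise. Multiplicative lognormal
    noise (CV ``noise_cv``, mean-preserving) is then applied per sample.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.asarray(config.sample_times, dtype=float)
    area = orifice_area_from_diameter(config.orifice_diameter)
    slopes = config.true_arc * _lognormal_factors(rng, config.cell_arc_cv,
                                                  config.n_cells)
    cells: list[CellRecord] = []
    q_true: dict[str, np.ndarray] = {}
    for i, slope in enumerate(slopes):
        cell_id = f"cell{i + 1}"
        q = slope * np.sqrt(times) + config.intercept_true
        amounts = q * area  # µg released through the orifice
        conc = np.empty_like(amounts)
        withdrawn = 0.0  # µg removed by earlier samplings
        for n, a_n in enumerate(amounts):
            conc[n] = (a_n - withdrawn) / config.cell_volume
            withdrawn += conc[n] * config.sample_volume
        conc = conc * _lognormal_factors(rng, config.noise_cv, len(conc))
        cells.append(CellRecord(cell_id=cell_id, times=times.copy(),
                                concentrations=conc))
        q_true[cell_id] = q
    run = IVRTRun(
        product_id=product_id,
        role=role,
        cells=cells,
        cell_volume=config.cell_volume,
        sample_volume=config.sample_volume,
        orifice_area=area,
        run_id=run_id,
    )
    truth = IVRTTruth(true_arc=config.true_arc, cell_slopes=slopes,
                      intercept=config.intercept_true, q_true=q_true)
    return run, truth


def sc_concentration_profile(depth_fraction, time: float,
                             partition_surface_conc: float,
                             diffusivity_ratio: float,
                             tol: float = 1e-14, max_terms: int = 100_000):
    """Transient Fickian drug concentration across the SC (µg/cm³).

    Solution of the diffusion equation on 0 ≤ x/L ≤ 1 with a constant-source
    surface boundary and a sink at the SC base:

        C = K·Cv · [(1 − u) − (2/π) Σ_{n≥1} (1/n)·sin(nπu)·exp(−n²π²·(D/L²)·t)]

    with u the depth fraction. The series is truncated once its term bound
    drops below ``tol``; truncation residue is clipped so the result is
    non-negative. Accepts scalar or array ``depth_fraction``.
    """
    u = np.asarray(depth_fraction, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("depth_fraction must lie in [0, 1]")
    if time <= 0:
        raise ValueError("time must be > 0")
    tau = diffusivity_ratio * time
    series = np.zeros_like(u)
    for n in range(1, max_terms + 1):
        damp = math.exp(-(n**2) * math.pi**2 * tau)
        if (2.0 / math.pi) * damp / n < tol:
            break
        series += (damp / n) * np.sin(n * math.pi * u)
    conc = partition_surface_conc * ((1.0 - u) - (2.0 / math.pi) * series)
    conc = np.clip(conc, 0.0, None)
    return float(conc) if np.isscalar(depth_fraction) else conc


def sc_depth_fraction_integral(u1: float, u2: float, time: float,
                               diffusivity_ratio: float,
                               tol: float = 1e-14,
                               max_terms: int = 100_000) -> float:
    """∫ over depth fraction of the profile shape (unit surface concentration).

    Term-by-term analytic integral of the series in
    :func:`sc_concentration_profile`; multiplying by K·Cv, SC thickness and
    site area converts it to a drug amount.
    """
    if not 0 <= u1 <= u2 <= 1:
        raise ValueError("need 0 ≤ u1 ≤ u2 ≤ 1")
    if time <= 0:
        raise ValueError("time must be > 0")
    tau = diffusivity_ratio * time
    total = (u2 - u1) - (u2**2 - u1**2) / 2.0
    for n in range(1, max_terms + 1):
        damp = math.exp(-(n**2) * math.pi**2 * tau)
        term = (2.0 / math.pi**2) * (damp / n**2) * (
            math.cos(n * math.pi * u2) - math.cos(n * math.pi * u1)
        )
        total += term
        if (4.0 / math.pi**2) * damp / n**2 < tol:
            break
    return max(total, 0.0)


@dataclass
class TapeStripStudy:
    """Simulated tape-strip study: observed records plus generator truth."""

    sites: list[StripSite]
    tewl_series: dict[str, TEWLSeries]  # participant_id -> blank-site series
    sc_thickness: dict[str, float]  # drawn truth, µm
    true_site_masses: dict[tuple[str, str], np.ndarray]  # (pid, site) -> µg
    true_site_amounts: dict[tuple[str, str], np.ndarray]  # noiseless drug, µg
    config: TSSimConfig = None

    def sites_for(self, product_id: str) -> list[StripSite]:
        return [s for s in self.sites if s.product_id == product_id]


def _draw_strip_masses(rng: np.random.Generator, config: TSSimConfig,
                       sc_thickness_um: float) -> np.ndarray:
    """Geometrically decaying strip masses, capped below the site's SC mass."""
    means = config.strip_mass_first * (1.0 - config.strip_mass_decay) ** np.arange(
        config.n_strips
    )
    masses = means * _lognormal_factors(rng, config.strip_mass_cv, config.n_strips)
    # SC mass over the site: thickness[cm] · area[cm²] · density[g/cm³] in µg
    sc_mass_ug = sc_thickness_um * 1e-4 * config.site_area * config.sc_density * 1e6
    cap = _STRIP_TOTAL_CAP * sc_mass_ug
    total = masses.sum()
    if total > cap:
        masses = masses * (cap / total)
    return masses


def simulate_tape_strip_study(config: TSSimConfig,
                              product_ids: Sequence[str],
                              product_scale: Mapping[str, float],
                              include_blank: bool = True) -> TapeStripStudy:
    """Simulate a multi-product tape-strip study with blank-site TEWL.

    Per participant: draws an SC thickness, then for every product (and a
    blank) generates decreasing strip masses; each strip is assigned the drug
    amount in the SC depth interval it removed — the analytic integral of the
    transient Fickian profile at ``application_time`` — scaled by the
    product's factor on the surface concentration. The blank site carries no
    drug and provides the TEWL series, modelled as TEWL = C/(L − x) with
    C = baseline·L, so the 1/TEWL extrapolation recovers L exactly at zero
    noise.
    """
    missing = [p for p in product_ids if p not in product_scale]
    if missing:
        raise ValueError(f"product_scale missing entries for: {', '.join(missing)}")
    rng = np.random.default_rng(config.seed)
    sites: list[StripSite] = []
    tewl_series: dict[str, TEWLSeries] = {}
    sc_thickness: dict[str, float] = {}
    true_masses: dict[tuple[str, str], np.ndarray] = {}
    true_amounts: dict[tuple[str, str], np.ndarray] = {}

    for p in range(config.n_participants):
        pid = f"P{p + 1:02d}"
        thickness = config.sc_thickness_mean * float(
            _lognormal_factors(rng, config.sc_thickness_cv, 1)[0]
        )
        sc_thickness[pid] = thickness

        site_no = 0
        for product in product_ids:
            for rep in range(config.replicate_sites):
                site_no += 1
                arm = "L" if rep % 2 == 0 else "R"
                label = f"site{site_no}"
                masses = _draw_strip_masses(rng, config, thickness)
                increments_um = mass_to_depth_um(masses, config.site_area,
                                                 config.sc_density)
                edges_u = np.concatenate([[0.0], np.cumsum(increments_um)]) / thickness
                edges_u = np.clip(edges_u, 0.0, 1.0)
                shape = np.array([
                    sc_depth_fraction_integral(edges_u[i], edges_u[i + 1],
                                               config.application_time,
                                               config.diffusivity_ratio)
                    for i in range(config.n_strips)
                ])
                amounts = (
                    product_scale[product]
                    * config.partition_surface_conc
                    * config.site_area
                    * thickness * 1e-4  # µm → cm
                    * shape
                )
                observed = amounts * _lognormal_factors(rng, config.drug_noise_cv,
                                                        config.n_strips)
                pre = rng.uniform(2.4e5, 2.6e5, config.n_strips)  # tape tare, µg
                sites.append(StripSite(
                    participant_id=pid, arm=arm, site=label, product_id=product,
                    strip_index=np.arange(1, config.n_strips + 1),
                    pre_weight=pre, post_weight=pre + masses,
                    drug_amount=observed,
                    site_area=config.site_area,
                    application_time=config.application_time,
                ))
                true_masses[(pid, label)] = masses
                true_amounts[(pid, label)] = amounts

        if include_blank:
            site_no += 1
            label = f"site{site_no}"
            masses = _draw_strip_masses(rng, config, thickness)
            pre = rng.uniform(2.4e5, 2.6e5, config.n_strips)
            sites.append(StripSite(
                participant_id=pid, arm="L", site=label, product_id="blank",
                strip_index=np.arange(1, config.n_strips + 1),
                pre_weight=pre, post_weight=pre + masses,
                drug_amount=np.zeros(config.n_strips),
                site_area=config.site_area,
                application_time=config.application_time,
            ))
            true_masses[(pid, label)] = masses
            cum_mass = np.cumsum(masses)
            depth_um = mass_to_depth_um(cum_mass, config.site_area,
                                        config.sc_density)
            c_const = config.tewl_baseline * thickness  # TEWL·(L−x) is constant
            tewl = c_const / (thickness - depth_um)
            tewl = tewl * _lognormal_factors(rng, config.tewl_noise_cv,
                                             config.n_strips)
            tewl_series[pid] = TEWLSeries(participant_id=pid,
                                          cumulative_mass=cum_mass, tewl=tewl)

    return TapeStripStudy(sites=sites, tewl_series=tewl_series,
                          sc_thickness=sc_thickness,
                          true_site_masses=true_masses,
                          true_site_amounts=true_amounts,
                          config=config)
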