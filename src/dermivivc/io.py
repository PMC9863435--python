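"""CSV readers and writers for IVRT, tape-strip, TEWL and IVIVC-point data.

All writers emit exactly the dialect the readers accept, and floats are
written at full round-trip precision, so write∘read is the identity on
every dataset.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dpk import StripSite, TEWLSeries
from .ivivc import IVIVCPoint
from .ivrt import CellRecord, IVRTRun, orifice_area_from_diameter

IVRT_COLUMNS = ["run_id", "product_id", "role", "cell_id", "time_min", "conc_ug_per_ml"]
IVRT_META_COLUMNS = ["run_id", "product_id", "cell_volume_ml", "sample_volume_ml",
                     "orifice_diameter_mm", "temperature_c"]
TS_COLUMNS = ["participant_id", "arm", "site", "product_id", "strip_index",
              "pre_weight_ug", "post_weight_ug", "drug_ug",
              "site_area_cm2", "application_time_min"]
TEWL_COLUMNS = ["participant_id", "cum_mass_ug", "tewl"]
POINTS_COLUMNS = ["product_id", "run_label", "arc", "auc"]


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise ValueError(
            f"{path}: schema mismatch — missing columns {missing}, extra columns {extra}"
        )


def write_ivrt_csv(runs: Sequence[IVRTRun], data_path, meta_path) -> None:
    rows = []
    meta = []
    for run in runs:
        # diameter back-derived from the stored area; writers/readers agree
        diameter_mm = 2.0 * np.sqrt(run.orifice_area / np.pi) * 10.0
        meta.append({
            "run_id": run.run_id, "product_id": run.product_id,
            "cell_volume_ml": run.cell_volume, "sample_volume_ml": run.sample_volume,
            "orifice_diameter_mm": diameter_mm, "temperature_c": run.temperature,
        })
        for cell in run.cells:
            for t, c in zip(cell.times, cell.concentrations):
                rows.append({
                    "run_id": run.run_id, "product_id": run.product_id,
                    "role": run.role, "cell_id": cell.cell_id,
                    "time_min": t, "conc_ug_per_ml": c,
                })
    pd.DataFrame(rows, columns=IVRT_COLUMNS).to_csv(data_path, index=False)
    pd.DataFrame(meta, columns=IVRT_META_COLUMNS).to_csv(meta_path, index=False)


def read_ivrt_csv(data_path, meta_path) -> list[IVRTRun]:
    df = pd.read_csv(data_path, float_precision="round_trip")
    meta = pd.read_csv(meta_path, float_precision="round_trip")
    _check_columns(df, IVRT_COLUMNS, data_path)
    _check_columns(meta, IVRT_META_COLUMNS, meta_path)
    bad = df.index[df["conc_ug_per_ml"] < 0]
    if len(bad):
        raise ValueError(
            f"{data_path}: negative concentration at row {int(bad[0]) + 2}"
        )
    meta_idx = meta.set_index(["run_id", "product_id"])
    runs: list[IVRTRun] = []
    for (run_id, product_id), grp in df.groupby(["run_id", "product_id"], sort=False):
        try:
            m = meta_idx.loc[(run_id, product_id)]
        except KeyError:
            raise ValueError(
                f"{meta_path}: no metadata for run {run_id!r}, product {product_id!r}"
            ) from None
        roles = grp["role"].unique()
        if len(roles) != 1:
            raise ValueError(f"{data_path}: inconsistent role for {run_id}/{product_id}")
        cells = []
        for cell_id, cg in grp.groupby("cell_id", sort=False):
            cg = cg.sort_values("time_min")
            cells.append(CellRecord(
                cell_id=str(cell_id),
                times=cg["time_min"].to_numpy(),
                concentrations=cg["conc_ug_per_ml"].to_numpy(),
            ))
        runs.append(IVRTRun(
            product_id=str(product_id), role=str(roles[0]), cells=cells,
            cell_volume=float(m["cell_volume_ml"]),
            sample_volume=float(m["sample_volume_ml"]),
            orifice_area=orifice_area_from_diameter(float(m["orifice_diameter_mm"])),
            run_id=str(run_id), temperature=float(m["temperature_c"]),
        ))
    return runs


def write_tapestrip_csv(sites: Sequence[StripSite], path) -> None:
    rows = []
    for s in sites:
        for i in range(s.n_strips):
            rows.append({
                "participant_id": s.participant_id, "arm": s.arm, "site": s.site,
                "product_id": s.product_id, "strip_index": int(s.strip_index[i]),
                "pre_weight_ug": s.pre_weight[i], "post_weight_ug": s.post_weight[i],
                "drug_ug": s.drug_amount[i], "site_area_cm2": s.site_area,
                "application_time_min": s.application_time,
            })
    pd.DataFrame(rows, columns=TS_COLUMNS).to_csv(path, index=False)


def read_tapestrip_csv(path) -> list[StripSite]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TS_COLUMNS, path)
    bad = df.index[df["drug_ug"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative drug amount at row {int(bad[0]) + 2}")
    sites: list[StripSite] = []
    for (pid, arm, site, product), grp in df.groupby(
            ["participant_id", "arm", "site", "product_id"], sort=False):
        grp = grp.sort_values("strip_index")
        areas = grp["site_area_cm2"].unique()
        app = grp["application_time_min"].unique()
        if len(areas) != 1 or len(app) != 1:
            raise ValueError(f"{path}: inconsistent site metadata for {pid}/{site}")
        sites.append(StripSite(
            participant_id=str(pid), arm=str(arm), site=str(site),
            product_id=str(product),
            strip_index=grp["strip_index"].to_numpy(),
            pre_weight=grp["pre_weight_ug"].to_numpy(),
            post_weight=grp["post_weight_ug"].to_numpy(),
            drug_amount=grp["drug_ug"].to_numpy(),
            site_area=float(areas[0]), application_time=float(app[0]),
        ))
    return sites


def write_tewl_csv(series: Sequence[TEWLSeries], path) -> None:
    rows = []
    for s in series:
        for m, t in zip(s.cumulative_mass, s.tewl):
            rows.append({"participant_id": s.participant_id,
                         "cum_mass_ug": m, "tewl": t})
    pd.DataFrame(rows, columns=TEWL_COLUMNS).to_csv(path, index=False)


def read_tewl_csv(path) -> dict[str, TEWLSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TEWL_COLUMNS, path)
    out: dict[str, TEWLSeries] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        out[str(pid)] = TEWLSeries(
            participant_id=str(pid),
            cumulative_mass=grp["cum_mass_ug"].to_numpy(),
            tewl=grp["tewl"].to_numpy(),
        )
    return out


def write_points_csv(points: Sequence[IVIVCPoint], path) -> None:
    rows = [{"product_id": p.product_id, "run_label": p.run_label,
             "arc": p.arc, "auc": p.auc} for p in points]
    pd.DataFrame(rows, columns=POINTS_COLUMNS).to_csv(path, index=False)


def read_points_csv(path) -> list[IVIVCPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, POINTS_COLUMNS, path)
    points = []
    for i, row in df.iterrows():
        try:
            points.append(IVIVCPoint(
                product_id=str(row["product_id"]), run_label=str(row["run_label"]),
                arc=float(row["arc"]), auc=float(row["auc"]),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: row {int(i) + 2}: {exc}") from None
    return points


def bundled_example_points() -> Path:
    """Path to the bundled metronidazole-cream summary points CSV."""
    return Path(__file__).parent / "data" / "mtz_cream_summary.csv"
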