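"""Readers/writers and run configuration for the pipeline.

Patient event histories travel as a long-format table (CSV, or JSON with
nested per-patient lists): one row per dose, HD session, or observation,
with patient-level fields (weight, circuit settings, MIC, outcome flag)
repeated or given once.  All times are hours since the first infusion
start (0-based, half-open intervals); flows are mL/min.  CSV dialect:
UTF-8, comma-separated, "." decimal, mandatory header row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .pk import DoseEvent, HDSession, HDSettings, Observation, PopulationPKModel

CSV_COLUMNS = [
    "patient_id", "weight_kg", "dose_time_h", "dose_mg", "t_inf_h",
    "hd_start_h", "hd_duration_h", "qb_ml_min", "qd_ml_min", "quf_ml_min",
    "clb12_ml_min", "clcr_ml_min", "obs_time_h", "obs_conc_ug_ml",
    "mic_ug_ml", "responder",
]


class SchemaError(ValueError):
    """Input violates the patient-table schema (reported with row/field)."""


@dataclass
class PatientData:
    patient_id: str
    weight_kg: float
    doses: list[DoseEvent] = field(default_factory=list)
    sessions: list[HDSession] = field(default_factory=list)
    settings: HDSettings | None = None
    observations: list[Observation] = field(default_factory=list)
    mic: float | None = None
    responder: bool | None = None


class RunConfig(BaseModel):
    """Configuration shared by the CLI subcommands."""

    patients: Path | None = None
    population: Path | None = None
    step: float = Field(default=0.05, gt=0)
    est_step: float = Field(default=0.1, gt=0)
    seed: int = 0
    n: int = Field(default=100, ge=1)
    terms: tuple[int, ...] = (1, 2)
    auc_mic_threshold: float = 400.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_population_yaml(path: str | Path) -> PopulationPKModel:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: population config must be a mapping")
    if "omega" in data:
        data["omega"] = tuple(data["omega"])
    return PopulationPKModel(**data)


def _num(row: pd.Series, col: str, idx: Any) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    try:
        return float(row[col])
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"row {idx}, field {col!r}: not numeric ({row[col]!r})") from exc


def read_patients_csv(path: str | Path) -> list[PatientData]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty patient table") from exc
    if df.empty:
        raise SchemaError(f"{path}: no patient rows")
    if "patient_id" not in df.columns or "weight_kg" not in df.columns:
        raise SchemaError(f"{path}: required columns patient_id, weight_kg missing")
    patients: list[PatientData] = []
    for pid, group in df.groupby("patient_id", sort=False):
        first = group.iloc[0]
        weight = _num(first, "weight_kg", first.name)
        if weight is None or weight <= 0:
            raise SchemaError(f"row {first.name}, field 'weight_kg': must be > 0")
        p = PatientData(patient_id=str(pid), weight_kg=weight)
        for idx, row in group.iterrows():
            t_dose = _num(row, "dose_time_h", idx)
            if t_dose is not None:
                amount = _num(row, "dose_mg", idx)
                t_inf = _num(row, "t_inf_h", idx) or 1.0
                if amount is None:
                    raise SchemaError(f"row {idx}, field 'dose_mg': required with dose_time_h")
                try:
                    p.doses.append(DoseEvent(time=t_dose, amount=amount, t_inf=t_inf))
                except ValueError as exc:
                    raise SchemaError(f"row {idx}: invalid dose ({exc})") from exc
            t_hd = _num(row, "hd_start_h", idx)
            if t_hd is not None:
                dur = _num(row, "hd_duration_h", idx)
                if dur is None:
                    raise SchemaError(f"row {idx}, field 'hd_duration_h': required")
                p.sessions.append(HDSession(start=t_hd, duration=dur))
            t_obs = _num(row, "obs_time_h", idx)
            if t_obs is not None:
                conc = _num(row, "obs_conc_ug_ml", idx)
                if conc is None:
                    raise SchemaError(f"row {idx}, field 'obs_conc_ug_ml': required")
                p.observations.append(Observation(time=t_obs, conc=conc))
            if p.settings is None:
                qb = _num(row, "qb_ml_min", idx)
                clb12 = _num(row, "clb12_ml_min", idx)
                if qb is not None and clb12 is not None:
                    p.settings = HDSettings(
                        q_blood=qb,
                        q_dialysate=_num(row, "qd_ml_min", idx) or 500.0,
                        q_uf=_num(row, "quf_ml_min", idx) or 0.0,
                        cl_b12_baseline=clb12,
                        cl_cr_baseline=_num(row, "clcr_ml_min", idx) or 0.0,
                    )
            if p.mic is None:
                p.mic = _num(row, "mic_ug_ml", idx)
            if p.responder is None and "responder" in row and pd.notna(row["responder"]):
                p.responder = bool(int(row["responder"]))
        p.sessions.sort(key=lambda s: s.start)
        p.doses.sort(key=lambda d: d.time)
        patients.append(p)
    return patients


def write_patients_csv(patients: Sequence[PatientData], path: str | Path) -> None:
    rows = []
    for p in patients:
        base = {"patient_id": p.patient_id, "weight_kg": p.weight_kg}
        settings_row = {}
        if p.settings is not None:
            settings_row = {
                "qb_ml_min": p.settings.q_blood, "qd_ml_min": p.settings.q_dialysate,
                "quf_ml_min": p.settings.q_uf, "clb12_ml_min": p.settings.cl_b12_baseline,
                "clcr_ml_min": p.settings.cl_cr_baseline,
            }
        meta = dict(settings_row)
        if p.mic is not None:
            meta["mic_ug_ml"] = p.mic
        if p.responder is not None:
            meta["responder"] = int(p.responder)
        first = True
        for d in p.doses:
            row = dict(base, dose_time_h=d.time, dose_mg=d.amount, t_inf_h=d.t_inf)
            if first:
                row.update(meta)
                first = False
            rows.append(row)
        for s in p.sessions:
            row = dict(base, hd_start_h=s.start, hd_duration_h=s.duration)
            if first:
                row.update(meta)
                first = False
            rows.append(row)
        for o in p.observations:
            row = dict(base, obs_time_h=o.time, obs_conc_ug_ml=o.conc)
            if first:
                row.update(meta)
                first = False
            rows.append(row)
        if first:  # patient with no events still gets one row
            rows.append(dict(base, **meta))
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def patients_to_json(patients: Sequence[PatientData]) -> list[dict]:
    out = []
    for p in patients:
        out.append(
            {
                "patient_id": p.patient_id,
                "weight_kg": p.weight_kg,
                "doses": [d.model_dump() for d in p.doses],
                "sessions": [s.model_dump() for s in p.sessions],
                "settings": p.settings.model_dump() if p.settings else None,
                "observations": [
                    {"time": o.time, "conc": o.conc} for o in p.observations
                ],
                "mic": p.mic,
                "responder": p.responder,
            }
        )
    return out


def write_patients_json(patients: Sequence[PatientData], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(patients_to_json(patients), fh, indent=1)


def read_patients_json(path: str | Path) -> list[PatientData]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list) or not data:
        raise SchemaError(f"{path}: expected a non-empty list of patients")
    patients = []
    for i, rec in enumerate(data):
        try:
            patients.append(
                PatientData(
                    patient_id=str(rec["patient_id"]),
                    weight_kg=float(rec["weight_kg"]),
                    doses=[DoseEvent(**d) for d in rec.get("doses", [])],
                    sessions=[HDSession(**s) for s in rec.get("sessions", [])],
                    settings=HDSettings(**rec["settings"]) if rec.get("settings") else None,
                    observations=[Observation(**o) for o in rec.get("observations", [])],
                    mic=rec.get("mic"),
                    responder=rec.get("responder"),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise SchemaError(f"patient record {i}: {exc}") from exc
    return patients


def provenance(config: dict | BaseModel, seed: int) -> dict:
    """Provenance header recorded next to every CLI output."""
    import scipy

    import vancohd

    cfg = config.model_dump(mode="json") if isinstance(config, BaseModel) else dict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "vancohd": vancohd.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }


def write_provenance(path: str | Path, config: dict | BaseModel, seed: int) -> None:
    with open(path, "w") as fh:
        json.dump(provenance(config, seed), fh, indent=1)
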