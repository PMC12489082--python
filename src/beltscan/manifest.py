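"""Case-manifest I/O.

The manifest is a UTF-8 CSV with one row per simulated measurement. The
binary detection label and the stage are always *recomputed* from the
stored tumor diameter; they are never persisted as authoritative columns.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError
from .types import CaseManifestRow

COLUMNS = [
    "case_id",
    "phantom_id",
    "tumor_diameter_mm",
    "lung_side",
    "belt_offset_mm",
    "body_sweep_path",
    "empty_sweep_path",
    "simulation_set",
]


def write_manifest(rows: list[CaseManifestRow], path: str | os.PathLike) -> Path:
    path = Path(path)
    ids = [r.case_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate case_id in manifest")
    df = pd.DataFrame([{c: getattr(r, c) for c in COLUMNS} for r in rows])
    df.to_csv(path, index=False)
    return path


def read_manifest(path: str | os.PathLike) -> list[CaseManifestRow]:
    df = pd.read_csv(path, dtype={"case_id": str, "phantom_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest missing columns: {missing}")
    rows = []
    for rec in df[COLUMNS].to_dict("records"):
        rec["tumor_diameter_mm"] = float(rec["tumor_diameter_mm"])
        rec["belt_offset_mm"] = float(rec["belt_offset_mm"])
        rows.append(CaseManifestRow(**rec))
    return rows


def manifest_frame(rows: list[CaseManifestRow]) -> pd.DataFrame:
    """Manifest as a DataFrame with derived label/radius/stage columns."""
    df = pd.DataFrame([{c: getattr(r, c) for c in COLUMNS} for r in rows])
    df["label"] = [r.label for r in rows]
    df["radius_mm"] = [r.radius_mm for r in rows]
    return df
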