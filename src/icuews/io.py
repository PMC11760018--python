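"""Dataset formats: metadata CSV, per-series CSV files, JSON manifest.

Layout of a dataset directory::

    metadata.csv            one row per PatientRecord
    series/<pid>_<VAR>.csv  columns time_s,value; missing values empty
    manifest.json           seed, config echo, relative paths

All files are plain UTF-8 CSV/JSON with '.' decimals; writing is
deterministic (fixed float formats, no timestamps), so regenerating a
dataset from the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import PatientRecord, VitalSignSeries

__all__ = ["DatasetError", "write_dataset", "read_dataset", "write_series", "read_series"]

_METADATA_COLUMNS = [
    "patient_id",
    "cohort",
    "ward",
    "age",
    "sex",
    "extubation_time",
    "endpoint_time",
    "death_flag",
]


class DatasetError(ValueError):
    """Raised for malformed or inconsistent dataset files."""


def _config_to_jsonable(config) -> dict | None:
    if config is None:
        return None

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def write_series(path: Path, series: VitalSignSeries) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.0f},\n" if np.isnan(v) else f"{t:.0f},{v:.4f}\n")


def read_series(path: Path, variable: str) -> VitalSignSeries:
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "value"]:
        raise DatasetError(f"{path}: expected columns time_s,value")
    times = df["time_s"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    if len(times) >= 2:
        steps = np.diff(times)
        if not np.allclose(steps, steps[0]) or steps[0] <= 0:
            raise DatasetError(f"{path}: non-uniform sampling grid")
    return VitalSignSeries(variable=variable, times=times, values=values)


def write_dataset(
    out_dir,
    records: Sequence[PatientRecord],
    store: Mapping[str, Mapping[str, VitalSignSeries]],
    config=None,
    seed: int | None = None,
) -> Path:
    """Write a dataset directory; returns the manifest path."""
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    series_dir.mkdir(parents=True, exist_ok=True)

    meta = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "cohort": r.cohort,
                "ward": r.ward,
                "age": r.age,
                "sex": r.sex,
                "extubation_time": r.extubation_time,
                "endpoint_time": r.endpoint_time,
                "death_flag": int(r.death_flag),
            }
            for r in records
        ],
        columns=_METADATA_COLUMNS,
    )
    meta.to_csv(out_dir / "metadata.csv", index=False, float_format="%.3f")

    series_paths: dict[str, dict[str, str]] = {}
    for r in records:
        per_var = store.get(r.patient_id, {})
        series_paths[r.patient_id] = {}
        for var, series in per_var.items():
            rel = f"series/{r.patient_id}_{var}.csv"
            write_series(out_dir / rel, series)
            series_paths[r.patient_id][var] = rel

    manifest = {
        "format": "icuews-dataset-v1",
        "seed": seed,
        "config": _config_to_jsonable(config),
        "metadata": "metadata.csv",
        "series": series_paths,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path


def read_dataset(
    manifest_path,
) -> tuple[list[PatientRecord], dict[str, dict[str, VitalSignSeries]]]:
    """Read and validate a dataset directory from its manifest.

    Validation: unique patient ids, cohort/death-flag consistency, uniform
    5 s sampling grids.  A variable listed in the manifest but absent on
    disk leaves the record with that variable marked unavailable.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    meta = pd.read_csv(root / manifest["metadata"])
    missing_cols = set(_METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise DatasetError(f"metadata lacks columns {sorted(missing_cols)}")
    if meta["patient_id"].duplicated().any():
        dupes = meta.loc[meta["patient_id"].duplicated(), "patient_id"].tolist()
        raise DatasetError(f"duplicate patient ids: {dupes}")

    records: list[PatientRecord] = []
    for lineno, row in enumerate(meta.itertuples(index=False), start=2):
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    cohort=int(row.cohort),
                    ward=str(row.ward),
                    age=float(row.age),
                    sex=str(row.sex),
                    extubation_time=float(row.extubation_time),
                    endpoint_time=float(row.endpoint_time),
                    death_flag=bool(row.death_flag),
                )
            )
        except ValueError as exc:
            raise DatasetError(f"metadata.csv line {lineno}: {exc}") from exc

    store: dict[str, dict[str, VitalSignSeries]] = {}
    for record in records:
        per_var: dict[str, VitalSignSeries] = {}
        for var, rel in manifest["series"].get(record.patient_id, {}).items():
            path = root / rel
            if not path.exists():
                continue  # variable unavailable for this record
            per_var[var] = read_series(path, var)
        store[record.patient_id] = per_var
    return records, store
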