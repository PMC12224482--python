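"""Reading and writing datasets, configs, and result tables.

Datasets travel as tidy UTF-8 CSV with the exact columns
``participant_id, site, scanner, measure, region, value_t1, value_t2``;
configs as YAML; result tables as RFC-4180 CSV plus pretty-printed JSON.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .errors import SchemaError
from .simulate import DATASET_COLUMNS, SimulationConfig

__all__ = [
    "read_dataset",
    "validate_dataset",
    "write_dataset",
    "read_simulation_config",
    "write_simulation_config",
    "write_tables",
]

_KEY = ["participant_id", "measure", "region"]


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the tidy two-timepoint schema; return the typed frame.

    Checks: required columns present; values numeric and complete; each
    (participant, measure, region) key unique; each participant in exactly one
    site; each site on exactly one scanner.
    """
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df[list(DATASET_COLUMNS)].copy()
    for col in ("value_t1", "value_t2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise SchemaError(f"non-numeric or missing {col} at rows {bad[:10]}")
        df[col] = vals.astype(float)
    dupes = df[df.duplicated(_KEY, keep=False)]
    if not dupes.empty:
        offenders = dupes[_KEY].drop_duplicates().head(5).to_dict("records")
        raise SchemaError(f"duplicate (participant, measure, region) keys: {offenders}")
    multi_site = df.groupby("participant_id")["site"].nunique()
    if (multi_site > 1).any():
        raise SchemaError(
            f"participants in multiple sites: {multi_site[multi_site > 1].index.tolist()[:5]}"
        )
    multi_scanner = df.groupby("site")["scanner"].nunique()
    if (multi_scanner > 1).any():
        raise SchemaError(
            f"sites with multiple scanners: {multi_scanner[multi_scanner > 1].index.tolist()}"
        )
    return df


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset CSV (header row required, UTF-8)."""
    df = pd.read_csv(path, encoding="utf-8")
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\r\n", encoding="utf-8")


def write_simulation_config(config: SimulationConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["regions"] = list(payload["regions"])
    payload["measures"] = list(payload["measures"])
    if not isinstance(payload["n_per_site"], int):
        payload["n_per_site"] = list(payload["n_per_site"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_simulation_config(path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return SimulationConfig(**payload)


def _jsonable(obj: Any):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if hasattr(obj, "item"):  # numpy scalars
        return _jsonable(obj.item())
    return obj


def write_tables(results: Mapping[str, Any], out_dir) -> list[str]:
    """Write each result to ``out_dir``: DataFrames as CSV, everything else as JSON.

    Returns the list of file names written (used by the pipeline manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            obj.to_csv(out / fname, index=False, lineterminator="\r\n",
                       encoding="utf-8")
        else:
            fname = f"{name}.json"
            with open(out / fname, "w", encoding="utf-8") as fh:
                json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
                fh.write("\n")
        written.append(fname)
    return written
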