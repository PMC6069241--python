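"""CSV and YAML interfaces.

All tables are plain CSV with unit-carrying headers; dates are ISO-8601.
Campaign tables use the same dialect the synthetic generator emits, so the
loaders double as readers for externally compiled monitoring tables (one
row per storm event with EMC/EML columns per analyte).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .catchment import CatchmentParams, Hyetograph
from .ledger import ApplicationRecord, AreaScaling, AvailableMassState
from .washoff import WashoffParams

APPLICATION_COLUMNS = ["date", "use_category", "active_ingredient", "mass_applied_g", "county"]


def read_application_records(path: str | Path) -> list[ApplicationRecord]:
    """Read pesticide-use records (PUR-style monthly entries)."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in APPLICATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        ApplicationRecord(
            date=row.date.date(),
            use_category=str(row.use_category),
            active_ingredient=str(row.active_ingredient),
            mass_applied=float(row.mass_applied_g),
            county=str(row.county),
        )
        for row in df.itertuples()
    ]


def write_application_records(
    records: Sequence[ApplicationRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "use_category": [r.use_category for r in records],
            "active_ingredient": [r.active_ingredient for r in records],
            "mass_applied_g": [r.mass_applied for r in records],
            "county": [r.county for r in records],
        }
    ).to_csv(path, index=False)


def read_hyetograph(path: str | Path) -> Hyetograph:
    df = pd.read_csv(path)
    return Hyetograph(
        timestamps=df["timestamp_h"].to_numpy(float),
        intensities=df["intensity_mm_per_h"].to_numpy(float),
    )


def write_hyetograph(hyeto: Hyetograph, path: str | Path) -> None:
    pd.DataFrame(
        {"timestamp_h": hyeto.timestamps, "intensity_mm_per_h": hyeto.intensities}
    ).to_csv(path, index=False)


def read_campaign_csv(path: str | Path) -> pd.DataFrame:
    """Load a storm-event monitoring table (synthetic or externally
    compiled): one row per event, indexed by event_id, with hydrology
    columns and per-analyte EMC (ng/L) / EML (ug) columns."""
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    return df.set_index("event_id")


def write_campaign_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=True)


def write_ledger_csv(series: Sequence[AvailableMassState], path: str | Path) -> None:
    """Daily availability ledger for one analyte."""
    pd.DataFrame(
        {
            "day": [s.day.isoformat() for s in series],
            "applied_g": [s.applied for s in series],
            "available_g": [s.available for s in series],
            "washed_g": [s.washed for s in series],
        }
    ).to_csv(path, index=False)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dt.date):
        return obj.isoformat()
    return obj


def dump_yaml(obj, path: str | Path) -> None:
    """Serialize a (possibly nested dataclass) object to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(obj), sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def washoff_params_from_dict(d: dict) -> WashoffParams:
    return WashoffParams(**d)


def catchment_params_from_dict(d: dict) -> CatchmentParams:
    return CatchmentParams(**d)


def area_scaling_from_dict(d: dict) -> AreaScaling:
    return AreaScaling(**d)
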