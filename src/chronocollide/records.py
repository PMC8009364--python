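"""Accident-record schema and CSV ingest.

A record is one police-reported collision: calendar date, local clock time
(minute resolution), species, and optional location fields (district, road
id, mileage).  Ingest is deliberately strict about accounting: every input
row is either kept or counted under a discard reason — vague or fragmentary
reports are dropped, never silently lost.  Records whose date parses but
whose time is missing are kept (flagged) so they can still enter date-level
analyses while being excluded from illumination analyses.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import StudyConfig

__all__ = [
    "AccidentRecord",
    "IngestReport",
    "read_records",
    "records_to_frame",
    "write_records",
    "convert_xlsx",
]

DEFAULT_COLUMN_MAP = {
    "date": "date",
    "time": "time",
    "species": "species",
    "district": "district",
    "road_id": "road_id",
    "mileage_km": "mileage_km",
}


@dataclass(frozen=True)
class AccidentRecord:
    """One timestamped collision event — the unit of analysis."""

    date: dt.date
    time: dt.time | None
    species: str
    district: str | None = None
    road_id: str | None = None
    mileage_km: float | None = None

    @property
    def timestamp(self) -> dt.datetime | None:
        """Naive local civil datetime, or None when the time is missing."""
        if self.time is None:
            return None
        return dt.datetime.combine(self.date, self.time)


@dataclass
class IngestReport:
    """Row accounting for one ingest: kept + discarded == input rows."""

    total_rows: int = 0
    kept: int = 0
    discarded: Counter = dataclasses.field(default_factory=Counter)
    kept_without_time: int = 0

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    def as_dict(self) -> dict:
        return {
            "total_rows": self.total_rows,
            "kept": self.kept,
            "kept_without_time": self.kept_without_time,
            "discarded": dict(self.discarded),
        }


def _parse_date(value) -> dt.date | None:
    if value is None:
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    if not text:
        return None
    for fmt in ("%Y-%m-%d", "%d.%m.%Y", "%d/%m/%Y"):
        try:
            return dt.datetime.strptime(text, fmt).date()
        except ValueError:
            continue
    return None


def _parse_time(value) -> dt.time | None:
    if value is None:
        return None
    if isinstance(value, dt.datetime):
        return value.time().replace(second=0, microsecond=0)
    if isinstance(value, dt.time):
        return value.replace(second=0, microsecond=0)
    text = str(value).strip()
    if not text:
        return None
    for fmt in ("%H:%M", "%H:%M:%S"):
        try:
            return dt.datetime.strptime(text, fmt).time()
        except ValueError:
            continue
    return None


def read_records(
    path: str | Path,
    config: StudyConfig,
    column_map: dict | None = None,
    require_time: bool = False,
) -> tuple[list[AccidentRecord], IngestReport]:
    """Read and validate an accident CSV.

    Returns the retained records and an :class:`IngestReport` counting
    discarded rows by reason (``missing_date``, ``species_mismatch``,
    ``out_of_window``, and ``missing_time`` when ``require_time``).
    An unreadable file raises; a malformed row never does.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_frame(frame, config, cmap, require_time=require_time)


def records_from_frame(
    frame: pd.DataFrame,
    config: StudyConfig,
    column_map: dict | None = None,
    require_time: bool = False,
) -> tuple[list[AccidentRecord], IngestReport]:
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    for key in ("date", "time", "species"):
        if cmap[key] not in frame.columns:
            raise ValueError(f"required column {cmap[key]!r} missing from input")
    target = config.target_species.strip().lower()
    window = (
        dt.date(min(config.study_years), 1, 1),
        dt.date(max(config.study_years), 12, 31),
    )
    report = IngestReport(total_rows=len(frame))
    records: list[AccidentRecord] = []
    for row in frame.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(frame.columns, row))
        date = _parse_date(row.get(cmap["date"]))
        if date is None:
            report.discarded["missing_date"] += 1
            continue
        species = str(row.get(cmap["species"], "")).strip()
        if species.lower() != target:
            report.discarded["species_mismatch"] += 1
            continue
        if not window[0] <= date <= window[1]:
            report.discarded["out_of_window"] += 1
            continue
        time = _parse_time(row.get(cmap["time"]))
        if time is None:
            if require_time:
                report.discarded["missing_time"] += 1
                continue
            report.kept_without_time += 1
        mileage_raw = str(row.get(cmap["mileage_km"], "") or "").strip()
        records.append(
            AccidentRecord(
                date=date,
                time=time,
                species=species,
                district=str(row.get(cmap["district"], "") or "").strip() or None,
                road_id=str(row.get(cmap["road_id"], "") or "").strip() or None,
                mileage_km=float(mileage_raw) if mileage_raw else None,
            )
        )
        report.kept += 1
    return records, report


def records_to_frame(records: list[AccidentRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the canonical CSV columns."""
    return pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "time": [r.time.strftime("%H:%M") if r.time else "" for r in records],
            "species": [r.species for r in records],
            "district": [r.district or "" for r in records],
            "road_id": [r.road_id or "" for r in records],
            "mileage_km": [r.mileage_km if r.mileage_km is not None else "" for r in records],
        }
    )


def write_records(records: list[AccidentRecord], path: str | Path) -> None:
    """Write the canonical CSV; a subsequent ``read_records`` round-trips."""
    records_to_frame(records).to_csv(path, index=False)


def convert_xlsx(
    xlsx_path: str | Path, csv_path: str | Path, sheet: int | str = 0
) -> None:
    """Thin helper converting a deposited XLSX sheet to the canonical CSV.

    The core pipeline only reads CSV; this keeps spreadsheet handling at the
    edge.  Requires ``openpyxl``.
    """
    frame = pd.read_excel(xlsx_path, sheet_name=sheet)
    frame.to_csv(csv_path, index=False)
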