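"""Readers and writers for the four input table kinds.

All downstream stages consume only the outputs of this module. Column
mapping is config-driven so that both the PhysioNet dialect (Dexcom G6
export, Empatica E4 per-channel CSVs, Food_Log) and synthetic fixtures load
through one code path.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from glycowear.datatypes import (
    CHANNELS,
    NUTRIENTS,
    Cohort,
    GlucoseSeries,
    MealEvent,
    ParticipantRecord,
    SensorStream,
)

log = logging.getLogger(__name__)

#: Default column maps for the package's own canonical CSV dialect.
DEFAULT_CGM_COLUMNS = {"time": "time", "glucose": "glucose"}
DEFAULT_FOOD_COLUMNS = {"time": "time", **{n: n for n in NUTRIENTS}}
DEFAULT_PARTICIPANT_COLUMNS = {"participant_id": "participant_id", "sex": "sex", "hba1c": "hba1c"}

#: Column map for the Dexcom G6 export dialect of the PhysioNet accession.
DEXCOM_CGM_COLUMNS = {
    "time": "Timestamp (YYYY-MM-DDThh:mm:ss)",
    "glucose": "Glucose Value (mg/dL)",
}

#: Physiologically plausible interstitial glucose range (mg/dL); rows
#: outside it are treated as unparseable and skipped with a count.
GLUCOSE_RANGE = (20.0, 500.0)

_FLOAT_FMT = "%.12g"  # 12 significant digits: round-trips reals to <1e-9 relative


class ConfigurationError(ValueError):
    """A mapped column is missing or the reader config is unusable."""


class DataError(ValueError):
    """The file parsed but contains no usable rows."""


def _parse_times(raw: pd.Series) -> np.ndarray:
    """Parse a timestamp column: numeric values are epoch seconds, anything
    else goes through pandas datetime parsing (naive times taken as UTC)."""
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().mean() >= 0.5:
        return numeric.to_numpy(dtype=float)
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="mixed")
    out = parsed.astype("int64").to_numpy(dtype=float) / 1e9
    out[parsed.isna().to_numpy()] = np.nan
    return out


def _require_columns(df: pd.DataFrame, column_map: Mapping[str, str], keys: Iterable[str], path) -> None:
    for key in keys:
        col = column_map.get(key)
        if col is None or col not in df.columns:
            raise ConfigurationError(
                f"{path}: mapped column for {key!r} ({col!r}) not present; "
                f"available columns: {list(df.columns)}"
            )


def read_cgm(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    participant_id: str = "",
) -> GlucoseSeries:
    """Read a CGM export table into a :class:`GlucoseSeries`.

    Rows are sorted by time; rows with an unparseable timestamp or a
    non-numeric / out-of-range glucose value are skipped and counted.
    Duplicate timestamps keep the first occurrence.
    """
    column_map = dict(DEFAULT_CGM_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path)
    _require_columns(df, column_map, ("time", "glucose"), path)

    times = _parse_times(df[column_map["time"]])
    glucose = pd.to_numeric(df[column_map["glucose"]], errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(times) & np.isfinite(glucose)
    ok &= (glucose > GLUCOSE_RANGE[0]) & (glucose < GLUCOSE_RANGE[1])
    skipped = int((~ok).sum())
    if skipped:
        log.info("read_cgm(%s): skipped %d unparseable/out-of-range rows", path, skipped)
    times, glucose = times[ok], glucose[ok]
    if times.size == 0:
        raise DataError(f"{path}: no valid CGM rows")

    order = np.argsort(times, kind="stable")
    times, glucose = times[order], glucose[order]
    keep = np.concatenate([[True], np.diff(times) > 0])
    if not keep.all():
        log.info("read_cgm(%s): dropped %d duplicate timestamps", path, int((~keep).sum()))
    return GlucoseSeries(participant_id=participant_id, times=times[keep], glucose=glucose[keep])


def read_e4_channel(path: str | Path, channel: str, participant_id: str = "") -> SensorStream:
    """Read one Empatica-E4-dialect channel file.

    Rated channels: line 1 = start epoch, line 2 = sampling rate in Hz,
    remaining lines = samples (three comma-separated columns for ACC).
    IBI: line 1 = start epoch, remaining lines = ``offset,interval`` pairs.
    """
    if channel not in CHANNELS:
        raise ConfigurationError(f"unknown channel {channel!r}")
    path = Path(path)
    with open(path) as fh:
        header = [fh.readline().strip() for _ in range(1 if channel == "IBI" else 2)]
    if not header[0]:
        raise DataError(f"{path}: empty channel file")
    start_epoch = float(header[0].split(",")[0])
    skip = len(header)
    try:
        body = pd.read_csv(path, skiprows=skip, header=None).to_numpy(dtype=float)
    except pd.errors.EmptyDataError:
        body = np.empty((0, 1))
    except (pd.errors.ParserError, ValueError) as err:
        raise DataError(f"{path}: malformed sample rows ({err})") from err

    if channel == "IBI":
        if body.shape[1] != 2 or np.isnan(body).any():
            raise DataError(f"{path}: IBI rows must be offset,interval pairs")
        return SensorStream(participant_id, channel, 0.0, start_epoch, body)

    rate = float(header[1].split(",")[0])
    if rate <= 0:
        raise DataError(f"{path}: non-positive sampling rate {rate} for rated channel {channel}")
    if channel == "ACC":
        if body.shape[1] != 3 or np.isnan(body).any():
            raise DataError(f"{path}: ACC rows must have 3 fields")
        samples = body
    else:
        if body.shape[1] != 1:
            raise DataError(f"{path}: expected one sample per row for {channel}")
        samples = body[:, 0]
    return SensorStream(participant_id, channel, rate, start_epoch, samples)


def read_food_log(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    participant_id: str = "",
) -> list[MealEvent]:
    """Read a food log into time-sorted :class:`MealEvent` objects.

    Missing nutrient cells are stored as absent (``None``), not zero. An
    entry with sugar exceeding carbohydrate is loaded with a validation
    warning rather than rejected.
    """
    column_map = dict(DEFAULT_FOOD_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path)
    _require_columns(df, column_map, ("time",), path)
    present_nutrients = [n for n in NUTRIENTS if column_map.get(n) in df.columns]
    if not present_nutrients:
        raise ConfigurationError(f"{path}: no mapped nutrient columns present")

    times = _parse_times(df[column_map["time"]])
    events: list[MealEvent] = []
    for i in range(len(df)):
        if not np.isfinite(times[i]):
            log.info("read_food_log(%s): skipped row %d (bad time)", path, i)
            continue
        fields: dict[str, Optional[float]] = {}
        for n in present_nutrients:
            v = pd.to_numeric(pd.Series([df[column_map[n]].iloc[i]]), errors="coerce").iloc[0]
            fields[n] = None if pd.isna(v) else float(v)
        ev = MealEvent(participant_id=participant_id, time=float(times[i]), **fields)
        if ev.sugar is not None and ev.carbohydrate is not None and ev.sugar > ev.carbohydrate:
            warnings.warn(
                f"{path}: meal at t={ev.time:.0f} has sugar {ev.sugar} g > "
                f"carbohydrate {ev.carbohydrate} g",
                stacklevel=2,
            )
        events.append(ev)
    events.sort(key=lambda e: e.time)
    return events


def read_participants(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[ParticipantRecord]:
    """Read the participant table (id, sex, HbA1c percent)."""
    column_map = dict(DEFAULT_PARTICIPANT_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path)
    _require_columns(df, column_map, ("participant_id", "sex", "hba1c"), path)
    records = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = str(row[column_map["participant_id"]])
        if pid in seen:
            raise DataError(f"{path}: duplicate participant_id {pid!r}")
        seen.add(pid)
        records.append(
            ParticipantRecord(
                participant_id=pid,
                sex=str(row[column_map["sex"]]).strip().lower(),
                hba1c=float(row[column_map["hba1c"]]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cohort validation


@dataclass
class ValidationReport:
    """Report-only summary of cohort completeness; never mutates data."""

    problems: list[str] = field(default_factory=list)
    missing_channels: dict[str, list[str]] = field(default_factory=dict)
    coverage_days: dict[str, float] = field(default_factory=dict)
    meal_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """List participants missing channels or glucose, glucose coverage in
    days, and meal counts."""
    report = ValidationReport()
    for p in cohort.participants:
        pid = p.participant_id
        gs = cohort.glucose.get(pid)
        if gs is None or len(gs) == 0:
            report.problems.append(f"{pid}: no glucose series")
        else:
            report.coverage_days[pid] = float(gs.times[-1] - gs.times[0]) / 86400.0
        missing = [ch for ch in CHANNELS if ch not in cohort.streams.get(pid, {})]
        if missing:
            report.missing_channels[pid] = missing
            for ch in missing:
                report.problems.append(f"{pid}: missing channel {ch}")
        report.meal_counts[pid] = len(cohort.meals.get(pid, []))
        if report.meal_counts[pid] == 0:
            report.problems.append(f"{pid}: no meal events")
    return report


# ---------------------------------------------------------------------------
# Canonical on-disk cohort layout
#
#   <dir>/manifest.json
#   <dir>/participants.csv
#   <dir>/<pid>/glucose.csv          time,glucose
#   <dir>/<pid>/meals.csv            time,<nutrients>   (empty cell = absent)
#   <dir>/<pid>/<CHANNEL>.csv        E4 dialect


def save_cohort(cohort: Cohort, out_dir: str | Path, force: bool = False) -> Path:
    """Write a cohort to the canonical directory layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (pass force=True to overwrite)")

    pd.DataFrame(
        [(p.participant_id, p.sex, p.hba1c) for p in cohort.participants],
        columns=["participant_id", "sex", "hba1c"],
    ).to_csv(out / "participants.csv", index=False, float_format=_FLOAT_FMT)

    for pid in cohort.participant_ids:
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        gs = cohort.glucose.get(pid)
        if gs is not None:
            pd.DataFrame({"time": gs.times, "glucose": gs.glucose}).to_csv(
                pdir / "glucose.csv", index=False, float_format=_FLOAT_FMT
            )
        meals = cohort.meals.get(pid, [])
        rows = []
        for m in meals:
            row = {"time": m.time}
            for n in NUTRIENTS:
                v = m.nutrient(n)
                row[n] = np.nan if v is None else v
            rows.append(row)
        pd.DataFrame(rows, columns=["time", *NUTRIENTS]).to_csv(
            pdir / "meals.csv", index=False, float_format=_FLOAT_FMT
        )
        for ch, stream in cohort.streams.get(pid, {}).items():
            write_e4_channel(stream, pdir / f"{ch}.csv")

    manifest = {
        "format": "glycowear-cohort-v1",
        "participants": cohort.participant_ids,
        "channels": {pid: sorted(chs) for pid, chs in cohort.streams.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def write_e4_channel(stream: SensorStream, path: str | Path) -> None:
    """Write a stream in the E4 file dialect read by :func:`read_e4_channel`."""
    samples = stream.samples if stream.samples.ndim == 2 else stream.samples[:, None]
    body = pd.DataFrame(samples).to_csv(
        header=False, index=False, float_format=_FLOAT_FMT
    )
    with open(path, "w") as fh:
        fh.write(_FLOAT_FMT % stream.start_epoch + "\n")
        if stream.channel != "IBI":
            fh.write(_FLOAT_FMT % stream.rate_hz + "\n")
        fh.write(body)


def load_cohort(in_dir: str | Path) -> Cohort:
    """Read a canonical cohort directory back into memory."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    cohort = Cohort(participants=read_participants(root / "participants.csv"))
    for pid in manifest["participants"]:
        pdir = root / pid
        if (pdir / "glucose.csv").exists():
            cohort.glucose[pid] = read_cgm(pdir / "glucose.csv", participant_id=pid)
        if (pdir / "meals.csv").exists():
            cohort.meals[pid] = read_food_log(pdir / "meals.csv", participant_id=pid)
        cohort.streams[pid] = {}
        for ch in CHANNELS:
            fp = pdir / f"{ch}.csv"
            if fp.exists():
                cohort.streams[pid][ch] = read_e4_channel(fp, ch, participant_id=pid)
    return cohort


def ingest_raw(
    cgm_paths: Mapping[str, str | Path],
    e4_dirs: Mapping[str, str | Path],
    food_paths: Mapping[str, str | Path],
    participants_path: str | Path,
    cgm_columns: Mapping[str, str] | None = None,
    food_columns: Mapping[str, str] | None = None,
    participant_columns: Mapping[str, str] | None = None,
    channels: Sequence[str] = CHANNELS,
) -> Cohort:
    """Assemble a cohort from per-participant raw file paths.

    ``e4_dirs`` maps each participant id to a directory holding
    ``ACC.csv``/``EDA.csv``/... in the E4 dialect; channels without a file
    are simply absent (reported by :func:`validate_cohort`).
    """
    cohort = Cohort(participants=read_participants(participants_path, participant_columns))
    for pid in cohort.participant_ids:
        if pid in cgm_paths:
            cohort.glucose[pid] = read_cgm(cgm_paths[pid], cgm_columns, participant_id=pid)
        if pid in food_paths:
            cohort.meals[pid] = read_food_log(food_paths[pid], food_columns, participant_id=pid)
        cohort.streams[pid] = {}
        if pid in e4_dirs:
            for ch in channels:
                fp = Path(e4_dirs[pid]) / f"{ch}.csv"
                if fp.exists():
                    cohort.streams[pid][ch] = read_e4_channel(fp, ch, participant_id=pid)
    return cohort
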