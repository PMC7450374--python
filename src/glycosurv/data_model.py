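"""Domain types for self-recorded type 1 diabetes data and CSV import/export.

The unit of analysis is one *patient-year*: a timestamped log of blood
glucose samples (finger-prick SMBG and sensor CGM, mg/dL), insulin doses
(bolus and basal, units), carbohydrate intakes (grams) and self-reported
acute infection episodes.  Everything downstream (resampling, smoothing,
weekly deviation statistics, density estimation, detection) consumes an
:class:`EventLog`.

Timestamps are stored at minute precision in local clock time; no time-zone
arithmetic is performed, matching how diabetes diary apps record events.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GlucoseSource",
    "InsulinKind",
    "GlucoseSample",
    "InsulinDose",
    "CarbIntake",
    "InfectionEvent",
    "EventLog",
    "ValidationReport",
    "FormatError",
    "read_event_log",
    "write_event_log",
    "PLAUSIBLE_BG_RANGE",
]

#: Physiological plausibility gate for glucose values, mg/dL.  Chosen to
#: bracket common CGM device reporting limits; values outside are dropped
#: during import and counted in the validation report.
PLAUSIBLE_BG_RANGE = (20.0, 600.0)


class GlucoseSource(str, enum.Enum):
    SMBG = "SMBG"
    CGM = "CGM"


class InsulinKind(str, enum.Enum):
    BOLUS = "bolus"
    BASAL = "basal"


class FormatError(ValueError):
    """Raised when an input file does not match the expected CSV schema."""


def _as_minute(ts) -> pd.Timestamp:
    return pd.Timestamp(ts).floor("min")


@dataclass(frozen=True)
class GlucoseSample:
    timestamp: pd.Timestamp
    value: float  # mg/dL
    source: GlucoseSource = GlucoseSource.CGM

    def __post_init__(self):
        object.__setattr__(self, "timestamp", _as_minute(self.timestamp))
        object.__setattr__(self, "source", GlucoseSource(self.source))
        lo, hi = PLAUSIBLE_BG_RANGE
        if not (lo <= self.value <= hi):
            raise ValueError(
                f"glucose value {self.value} mg/dL outside plausible range {PLAUSIBLE_BG_RANGE}"
            )


@dataclass(frozen=True)
class InsulinDose:
    timestamp: pd.Timestamp
    units: float  # insulin units, >= 0
    kind: InsulinKind = InsulinKind.BOLUS

    def __post_init__(self):
        object.__setattr__(self, "timestamp", _as_minute(self.timestamp))
        object.__setattr__(self, "kind", InsulinKind(self.kind))
        if self.units < 0:
            raise ValueError(f"insulin dose must be >= 0 U, got {self.units}")


@dataclass(frozen=True)
class CarbIntake:
    timestamp: pd.Timestamp
    grams: float  # >= 0

    def __post_init__(self):
        object.__setattr__(self, "timestamp", _as_minute(self.timestamp))
        if self.grams < 0:
            raise ValueError(f"carbohydrate intake must be >= 0 g, got {self.grams}")


@dataclass(frozen=True)
class InfectionEvent:
    """A self-reported acute infection episode (e.g. flu, common cold)."""

    onset: pd.Timestamp  # date, midnight-normalised
    duration_days: int = 7
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "onset", pd.Timestamp(self.onset).normalize())
        if self.duration_days < 1:
            raise ValueError("infection duration must be >= 1 day")

    @property
    def end(self) -> pd.Timestamp:
        """First day after the episode (exclusive)."""
        return self.onset + pd.Timedelta(days=self.duration_days)

    def covers(self, day: pd.Timestamp) -> bool:
        day = pd.Timestamp(day).normalize()
        return self.onset <= day < self.end


@dataclass
class ValidationReport:
    """Counts of rows adjusted or dropped during import; values are never mutated."""

    n_rows: int = 0
    n_implausible: int = 0
    n_unparseable: int = 0
    n_duplicates: int = 0
    n_zero_doses: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_implausible + self.n_unparseable + self.n_duplicates


@dataclass
class EventLog:
    """One patient-year of self-recorded events, sorted by timestamp."""

    patient_id: str
    glucose: list[GlucoseSample] = field(default_factory=list)
    insulin: list[InsulinDose] = field(default_factory=list)
    carbs: list[CarbIntake] = field(default_factory=list)
    infections: list[InfectionEvent] = field(default_factory=list)
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None  # [start day, end day] inclusive
    validation: ValidationReport = field(default_factory=ValidationReport, compare=False)

    def __post_init__(self):
        self.glucose = sorted(self.glucose, key=lambda r: r.timestamp)
        self.insulin = sorted(self.insulin, key=lambda r: r.timestamp)
        self.carbs = sorted(self.carbs, key=lambda r: r.timestamp)
        self.infections = sorted(self.infections, key=lambda r: r.onset)
        if self.span is None and self._timestamps():
            ts = self._timestamps()
            self.span = (min(ts).normalize(), max(ts).normalize())
        if self.span is not None:
            self.span = (pd.Timestamp(self.span[0]).normalize(), pd.Timestamp(self.span[1]).normalize())
            lo, hi = self.span[0], self.span[1] + pd.Timedelta(days=1)
            for ts in self._timestamps():
                if not (lo <= ts < hi):
                    raise ValueError(f"record timestamp {ts} outside span {self.span}")
        for a, b in zip(self.infections, self.infections[1:]):
            if b.onset < a.end:
                raise ValueError(f"overlapping infection episodes at {a.onset} and {b.onset}")

    def _timestamps(self) -> list[pd.Timestamp]:
        return (
            [r.timestamp for r in self.glucose]
            + [r.timestamp for r in self.insulin]
            + [r.timestamp for r in self.carbs]
        )

    def infection_days(self) -> pd.DatetimeIndex:
        """All calendar days covered by reported episodes."""
        days: list[pd.Timestamp] = []
        for ep in self.infections:
            days.extend(pd.date_range(ep.onset, ep.end - pd.Timedelta(days=1), freq="D"))
        return pd.DatetimeIndex(days)

    def __eq__(self, other):
        if not isinstance(other, EventLog):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.glucose == other.glucose
            and self.insulin == other.insulin
            and self.carbs == other.carbs
            and self.infections == other.infections
            and self.span == other.span
        )


# ---------------------------------------------------------------------------
# CSV import / export
#
# Long-format event CSV: patient_id, timestamp (ISO 8601, minute precision),
# stream (glucose|bolus|basal|carbs), value, unit, source.
# Infection CSV: patient_id, onset (ISO date), duration_days, label.
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["patient_id", "timestamp", "stream", "value", "unit", "source"]
INFECTION_COLUMNS = ["patient_id", "onset", "duration_days", "label"]

_STREAM_UNIT = {"glucose": "mg/dL", "bolus": "U", "basal": "U", "carbs": "g"}


def events_path(path: Path) -> Path:
    return Path(path) / "events.csv"


def infections_path(path: Path) -> Path:
    return Path(path) / "infections.csv"


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write ``log`` as two CSV files (events.csv, infections.csv) under ``path``.

    Lossless for minute-precision timestamps; a round trip through
    :func:`read_event_log` reconstructs an equal :class:`EventLog`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in log.glucose:
        rows.append((log.patient_id, g.timestamp, "glucose", g.value, "mg/dL", g.source.value))
    for d in log.insulin:
        rows.append((log.patient_id, d.timestamp, d.kind.value, d.units, "U", ""))
    for c in log.carbs:
        rows.append((log.patient_id, c.timestamp, "carbs", c.grams, "g", ""))
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(frame):
        frame = frame.sort_values("timestamp", kind="stable")
        frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    frame.to_csv(events_path(path), index=False)

    inf = pd.DataFrame(
        [(log.patient_id, ep.onset.strftime("%Y-%m-%d"), ep.duration_days, ep.label) for ep in log.infections],
        columns=INFECTION_COLUMNS,
    )
    inf.to_csv(infections_path(path), index=False)


def _require_columns(frame: pd.DataFrame, required: Iterable[str], where: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{where}: missing required column(s) {missing}")


def read_event_log(path: str | Path, patient_id: str | None = None) -> EventLog:
    """Read an :class:`EventLog` from the CSV layout written by :func:`write_event_log`.

    Rows with implausible glucose values are dropped and counted; exactly
    duplicated rows are collapsed to one occurrence; unparseable timestamps
    are collected and only fatal when they exceed 10% of rows.
    """
    path = Path(path)
    frame = pd.read_csv(events_path(path), dtype={"patient_id": str, "source": str}, keep_default_na=False)
    _require_columns(frame, ["patient_id", "timestamp", "stream", "value"], str(events_path(path)))
    report = ValidationReport(n_rows=len(frame))

    if len(frame):
        n_before = len(frame)
        frame = frame.drop_duplicates()
        report.n_duplicates = n_before - len(frame)
        parsed = pd.to_datetime(frame["timestamp"], errors="coerce", format="ISO8601")
        report.n_unparseable = int(parsed.isna().sum())
        if report.n_unparseable > 0.10 * len(frame):
            raise FormatError(
                f"{events_path(path)}: {report.n_unparseable} of {len(frame)} timestamps unparseable"
            )
        frame = frame.loc[parsed.notna()].assign(timestamp=parsed[parsed.notna()].dt.floor("min"))
        if patient_id is None:
            ids = frame["patient_id"].unique()
            patient_id = str(ids[0]) if len(ids) else "unknown"
        frame = frame[frame["patient_id"] == patient_id]
    elif patient_id is None:
        patient_id = "unknown"

    glucose: list[GlucoseSample] = []
    insulin: list[InsulinDose] = []
    carbs: list[CarbIntake] = []
    lo, hi = PLAUSIBLE_BG_RANGE
    for row in frame.itertuples(index=False):
        stream = row.stream
        value = float(row.value)
        if stream == "glucose":
            if not (lo <= value <= hi):
                report.n_implausible += 1
                continue
            source = getattr(row, "source", "") or "CGM"
            glucose.append(GlucoseSample(row.timestamp, value, GlucoseSource(source)))
        elif stream in ("bolus", "basal"):
            if value < 0:
                report.n_implausible += 1
                continue
            if value == 0:
                report.n_zero_doses += 1
            insulin.append(InsulinDose(row.timestamp, value, InsulinKind(stream)))
        elif stream == "carbs":
            if value < 0:
                report.n_implausible += 1
                continue
            carbs.append(CarbIntake(row.timestamp, value))
        else:
            raise FormatError(f"{events_path(path)}: unknown stream {stream!r}")

    infections: list[InfectionEvent] = []
    inf_file = infections_path(path)
    if inf_file.exists():
        inf = pd.read_csv(inf_file, dtype={"patient_id": str, "label": str}, keep_default_na=False)
        _require_columns(inf, ["patient_id", "onset", "duration_days"], str(inf_file))
        for row in inf.itertuples(index=False):
            if str(row.patient_id) != patient_id:
                continue
            infections.append(
                InfectionEvent(pd.Timestamp(row.onset), int(row.duration_days), getattr(row, "label", ""))
            )

    return EventLog(
        patient_id=patient_id,
        glucose=glucose,
        insulin=insulin,
        carbs=carbs,
        infections=infections,
        validation=report,
    )
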