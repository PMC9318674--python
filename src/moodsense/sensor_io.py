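"""Reading, validating, anonymizing and bundling per-participant tables.

The collection app stores each stream as a CSV table with a fixed name
(SCREEN_ONOFF, LOCATIONS, ACTIVITY_TRANSITION, FACE_LANDMARK, plus auxiliary
tables that are parsed and validated but never feed the feature extractor).
One directory per participant; a cohort manifest CSV lists participant ids,
collection windows and the optional clinician diagnosis.

Malformed rows are skipped and counted in a :class:`ParseReport`; a table in
which more than half the rows fail validation is rejected outright.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional

from .types import (
    EMBEDDING_DIM,
    ActivityClass,
    ActivityTransitionEvent,
    Diagnosis,
    FaceEmbeddingRecord,
    GenericRecord,
    GpsFix,
    Instrument,
    QuestionnaireRecord,
    ScreenEvent,
    ScreenState,
    SensorBundle,
    Transition,
    Wave,
    sorted_by_time,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Unknown table name or inconsistent configuration."""


class TableValidationError(ValueError):
    """Table-level failure: bad header or majority-malformed rows."""


class BundleValidationError(ValueError):
    """Cross-stream inconsistency inside one participant bundle."""


# Feature-bearing tables and their columns.
FEATURE_TABLE_COLUMNS: dict[str, list[str]] = {
    "SCREEN_ONOFF": ["participant_id", "timestamp", "state"],
    "LOCATIONS": ["participant_id", "timestamp", "latitude", "longitude"],
    "ACTIVITY_TRANSITION": ["participant_id", "timestamp", "activity_class", "transition"],
    "FACE_LANDMARK": ["participant_id", "timestamp"]
    + [f"emb_{i}" for i in range(EMBEDDING_DIM)],
}

# Collected-but-unused tables: parsed and validated, never featurized.
AUX_TABLE_COLUMNS: dict[str, list[str]] = {
    "CALL_LOGS": ["participant_id", "timestamp", "direction", "duration_s"],
    "SMS_LOGS": ["participant_id", "timestamp", "direction"],
    "WIFI_INFO": ["participant_id", "timestamp", "ssid_hash", "rssi"],
    "BLUETOOTH_DEVICES": ["participant_id", "timestamp", "device_hash", "device_type"],
    "BATTERY_INFO": ["participant_id", "timestamp", "level_pct", "charging"],
    "CELL_INFO": ["participant_id", "timestamp", "signal_level", "signal_quality"],
    "SENSORS": ["participant_id", "timestamp", "sensor_type", "value"],
}

TABLE_COLUMNS = {**FEATURE_TABLE_COLUMNS, **AUX_TABLE_COLUMNS}

QUESTIONNAIRE_TABLE = "QUESTIONNAIRES"
QUESTIONNAIRE_ITEM_COUNTS = {
    Instrument.PHQ9: 9,
    Instrument.CESDR: 20,
    Instrument.ISI: 7,
    Instrument.PHQ2: 2,
    Instrument.TAM: 12,
}


@dataclass
class ParseReport:
    table: str
    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    reasons: Counter = field(default_factory=Counter)

    def skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.reasons[reason] += 1


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.strip())
    if ts.tzinfo is None:
        raise ValueError("timestamp lacks a UTC offset")
    return ts


def _row_to_record(table_name: str, row: dict[str, str]):
    pid = row["participant_id"].strip()
    if not pid:
        raise ValueError("empty participant_id")
    ts = _parse_timestamp(row["timestamp"])
    if table_name == "SCREEN_ONOFF":
        return ScreenEvent(pid, ts, ScreenState(row["state"].strip().upper()))
    if table_name == "LOCATIONS":
        lat, lon = float(row["latitude"]), float(row["longitude"])
        if not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude {lat} out of bounds")
        if not (-180.0 <= lon <= 180.0):
            raise ValueError(f"longitude {lon} out of bounds")
        return GpsFix(pid, ts, lat, lon)
    if table_name == "ACTIVITY_TRANSITION":
        return ActivityTransitionEvent(
            pid,
            ts,
            ActivityClass(row["activity_class"].strip().upper()),
            Transition(row["transition"].strip().upper()),
        )
    if table_name == "FACE_LANDMARK":
        emb = tuple(float(row[f"emb_{i}"]) for i in range(EMBEDDING_DIM))
        return FaceEmbeddingRecord(pid, ts, emb)
    payload = tuple(
        (c, row[c]) for c in TABLE_COLUMNS[table_name] if c not in ("participant_id", "timestamp")
    )
    return GenericRecord(pid, ts, payload)


def read_table(path: str | Path, table_name: str) -> tuple[list, ParseReport]:
    """Parse one Table-1-style CSV into typed, timestamp-sorted records.

    Rows that fail type or bounds validation are skipped and tallied in the
    returned :class:`ParseReport`; extra columns (e.g. landmark coordinates in
    FACE_LANDMARK) are ignored.
    """
    if table_name not in TABLE_COLUMNS:
        raise ConfigurationError(f"unknown table name {table_name!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    required = TABLE_COLUMNS[table_name]
    report = ParseReport(table=table_name)
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise TableValidationError(
                f"{table_name}: header missing columns {missing} in {path}"
            )
        for row in reader:
            report.n_rows += 1
            try:
                records.append(_row_to_record(table_name, row))
            except (ValueError, KeyError, TypeError) as exc:
                report.skip(str(exc) or type(exc).__name__)
    report.n_parsed = len(records)
    if report.n_rows and report.n_skipped > report.n_rows / 2:
        raise TableValidationError(
            f"{table_name}: {report.n_skipped}/{report.n_rows} rows malformed in {path}"
        )
    return sorted_by_time(records), report


def read_questionnaires(path: str | Path) -> tuple[list[QuestionnaireRecord], ParseReport]:
    """Parse the questionnaire CSV (participant_id, instrument, wave, item_1..item_N)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ParseReport(table=QUESTIONNAIRE_TABLE)
    records: list[QuestionnaireRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            report.n_rows += 1
            try:
                instrument = Instrument(row["instrument"].strip().upper())
                wave = Wave(row["wave"].strip().upper())
                n_items = QUESTIONNAIRE_ITEM_COUNTS[instrument]
                items = tuple(int(row[f"item_{i + 1}"]) for i in range(n_items))
                records.append(
                    QuestionnaireRecord(row["participant_id"].strip(), instrument, wave, items)
                )
            except (ValueError, KeyError, TypeError) as exc:
                report.skip(str(exc) or type(exc).__name__)
    report.n_parsed = len(records)
    return records, report


def anonymize_id(raw_identifier: str, salt: str) -> str:
    """Deterministic salted hash standing in for the device's random hash id."""
    if not raw_identifier:
        raise ValueError("empty identifier")
    digest = hashlib.sha256(f"{salt}\x00{raw_identifier}".encode("utf-8")).hexdigest()
    return digest[:16]


def dedupe_screen_events(events: Iterable[ScreenEvent]) -> list[ScreenEvent]:
    """Collapse consecutive same-state events to the first occurrence.

    The downstream interval logic requires strict ON/OFF alternation; repeated
    same-state reports (device restarts, duplicated uploads) carry no extra
    information about the screen's trajectory.
    """
    out: list[ScreenEvent] = []
    for ev in sorted_by_time(events):
        if out and out[-1].state == ev.state:
            continue
        out.append(ev)
    return out


def assemble_bundle(
    tables: dict[str, list],
    window: tuple[datetime, datetime],
    diagnosis: Optional[Diagnosis] = None,
    questionnaires: Optional[list[QuestionnaireRecord]] = None,
) -> SensorBundle:
    """Combine parsed per-table records into a validated participant bundle.

    Records outside the collection window are dropped (and logged); screen
    events are deduplicated so states alternate.  All streams must agree on a
    single participant id.
    """
    start, end = window
    pids = set()
    for recs in tables.values():
        pids.update(r.participant_id for r in recs)
    for rec in questionnaires or []:
        pids.add(rec.participant_id)
    if len(pids) > 1:
        raise BundleValidationError(f"mixed participant ids: {sorted(pids)}")
    pid = pids.pop() if pids else "unknown"

    def in_window(recs: list, name: str) -> list:
        kept = [r for r in recs if start <= r.timestamp <= end]
        dropped = len(recs) - len(kept)
        if dropped:
            logger.info("%s/%s: dropped %d out-of-window records", pid, name, dropped)
        return kept

    bundle = SensorBundle(
        participant_id=pid,
        window_start=start,
        window_end=end,
        screen_events=dedupe_screen_events(
            in_window(tables.get("SCREEN_ONOFF", []), "SCREEN_ONOFF")
        ),
        gps_fixes=sorted_by_time(in_window(tables.get("LOCATIONS", []), "LOCATIONS")),
        activity_events=sorted_by_time(
            in_window(tables.get("ACTIVITY_TRANSITION", []), "ACTIVITY_TRANSITION")
        ),
        face_embeddings=sorted_by_time(
            in_window(tables.get("FACE_LANDMARK", []), "FACE_LANDMARK")
        ),
        questionnaires=list(questionnaires or []),
        aux_records={
            name: sorted_by_time(in_window(tables[name], name))
            for name in AUX_TABLE_COLUMNS
            if name in tables
        },
        diagnosis=diagnosis,
    )
    if not bundle.screen_events:
        bundle.flags.append("sleep features unavailable")
    if not bundle.gps_fixes:
        bundle.flags.append("mobility features unavailable")
    if not bundle.activity_events:
        bundle.flags.append("activity feature unavailable")
    if not bundle.face_embeddings:
        bundle.flags.append("expression features unavailable")
    return bundle


@dataclass
class ExclusionPolicy:
    """Participant-level exclusion rules applied before feature extraction.

    Defaults: every required instrument must be answered at every required
    wave; at least half the window's days must have at least one screen event;
    at least one facial-expression record must exist.
    """

    required_waves: tuple[Wave, ...] = (Wave.M1, Wave.M2, Wave.M3)
    required_instruments: tuple[Instrument, ...] = (Instrument.PHQ9, Instrument.CESDR)
    min_screen_day_fraction: float = 0.5
    min_face_records: int = 1
    min_gps_fixes: int = 0
    min_activity_events: int = 0


@dataclass
class ExclusionReport:
    n_input: int = 0
    n_retained: int = 0
    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained


def _exclusion_reasons(bundle: SensorBundle, policy: ExclusionPolicy) -> list[str]:
    reasons = []
    answered = {(q.instrument, q.wave) for q in bundle.questionnaires}
    for inst in policy.required_instruments:
        for wave in policy.required_waves:
            if (inst, wave) not in answered:
                reasons.append("questionnaire incomplete")
                break
        else:
            continue
        break
    n_days = max(bundle.window_days, 1e-9)
    screen_days = {ev.timestamp.date() for ev in bundle.screen_events}
    if len(screen_days) / n_days < policy.min_screen_day_fraction:
        reasons.append("sensor missing: screen")
    if len(bundle.face_embeddings) < policy.min_face_records:
        reasons.append("sensor missing: face")
    if len(bundle.gps_fixes) < policy.min_gps_fixes:
        reasons.append("sensor missing: gps")
    if len(bundle.activity_events) < policy.min_activity_events:
        reasons.append("sensor missing: activity")
    return reasons


def apply_exclusion_rules(
    bundles: list[SensorBundle], policy: Optional[ExclusionPolicy] = None
) -> tuple[list[SensorBundle], ExclusionReport]:
    """Drop participants with incomplete questionnaires or insufficient sensor coverage."""
    policy = policy or ExclusionPolicy()
    report = ExclusionReport(n_input=len(bundles))
    retained = []
    for bundle in bundles:
        reasons = _exclusion_reasons(bundle, policy)
        if reasons:
            report.reasons[bundle.participant_id] = reasons
        else:
            retained.append(bundle)
    report.n_retained = len(retained)
    return retained, report


# ---------------------------------------------------------------------------
# Round-trip serialization (one directory per participant + cohort manifest)
# ---------------------------------------------------------------------------


def _fmt_ts(ts: datetime) -> str:
    return ts.isoformat()


def write_bundle(bundle: SensorBundle, directory: str | Path) -> None:
    """Write a bundle back to per-table CSVs (inverse of :func:`load_participant_dir`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(name: str, rows: list[list[str]]) -> None:
        with (directory / f"{name}.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(TABLE_COLUMNS[name])
            writer.writerows(rows)

    dump(
        "SCREEN_ONOFF",
        [[e.participant_id, _fmt_ts(e.timestamp), e.state.value] for e in bundle.screen_events],
    )
    dump(
        "LOCATIONS",
        [
            [f.participant_id, _fmt_ts(f.timestamp), repr(float(f.latitude)), repr(float(f.longitude))]
            for f in bundle.gps_fixes
        ],
    )
    dump(
        "ACTIVITY_TRANSITION",
        [
            [e.participant_id, _fmt_ts(e.timestamp), e.activity_class.value, e.transition.value]
            for e in bundle.activity_events
        ],
    )
    dump(
        "FACE_LANDMARK",
        [
            [r.participant_id, _fmt_ts(r.timestamp)] + [repr(float(v)) for v in r.embedding]
            for r in bundle.face_embeddings
        ],
    )
    if bundle.questionnaires:
        max_items = max(QUESTIONNAIRE_ITEM_COUNTS.values())
        with (directory / "QUESTIONNAIRES.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["participant_id", "instrument", "wave"]
                + [f"item_{i + 1}" for i in range(max_items)]
            )
            for q in bundle.questionnaires:
                row = [q.participant_id, q.instrument.value, q.wave.value]
                row += [str(s) for s in q.item_scores]
                row += [""] * (max_items - len(q.item_scores))
                writer.writerow(row)


def load_participant_dir(
    directory: str | Path,
    window: tuple[datetime, datetime],
    diagnosis: Optional[Diagnosis] = None,
) -> tuple[SensorBundle, dict[str, ParseReport]]:
    """Read every table CSV present in a participant directory into a bundle."""
    directory = Path(directory)
    tables: dict[str, list] = {}
    reports: dict[str, ParseReport] = {}
    for name in TABLE_COLUMNS:
        path = directory / f"{name}.csv"
        if path.exists():
            tables[name], reports[name] = read_table(path, name)
    questionnaires: list[QuestionnaireRecord] = []
    qpath = directory / "QUESTIONNAIRES.csv"
    if qpath.exists():
        questionnaires, reports[QUESTIONNAIRE_TABLE] = read_questionnaires(qpath)
    bundle = assemble_bundle(tables, window, diagnosis, questionnaires)
    return bundle, reports


MANIFEST_COLUMNS = ["participant_id", "window_start", "window_end", "diagnosis"]


def write_cohort(bundles: list[SensorBundle], directory: str | Path) -> None:
    """Write one sub-directory per participant plus the cohort manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "manifest.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for b in bundles:
            writer.writerow(
                [
                    b.participant_id,
                    _fmt_ts(b.window_start),
                    _fmt_ts(b.window_end),
                    b.diagnosis.value if b.diagnosis else "",
                ]
            )
            write_bundle(b, directory / b.participant_id)


def load_cohort(directory: str | Path) -> tuple[list[SensorBundle], dict[str, dict[str, ParseReport]]]:
    """Load every participant listed in the cohort manifest."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    bundles = []
    reports: dict[str, dict[str, ParseReport]] = {}
    with manifest.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid = row["participant_id"]
            window = (
                _parse_timestamp(row["window_start"]),
                _parse_timestamp(row["window_end"]),
            )
            diagnosis = Diagnosis(row["diagnosis"]) if row.get("diagnosis") else None
            bundle, rep = load_participant_dir(directory / pid, window, diagnosis)
            bundle.participant_id = pid if bundle.participant_id == "unknown" else bundle.participant_id
            bundles.append(bundle)
            reports[pid] = rep
    return bundles, reports
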