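"""Core record types shared across the pipeline.

Every raw stream is a list of small frozen records keyed by an anonymized
participant id and a timezone-aware timestamp.  Timestamps are stored with the
offset they were recorded at: an aware :class:`datetime.datetime` is an exact
UTC instant, while its ``time()``/``date()`` accessors give the participant's
local clock, which is what the sleep and usage rules operate on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

EMBEDDING_DIM = 16


class ScreenState(str, enum.Enum):
    ON = "ON"
    OFF = "OFF"


class ActivityClass(str, enum.Enum):
    """The eight device-inferred motion classes."""

    VEHICLE = "VEHICLE"
    CYCLING = "CYCLING"
    WALKING = "WALKING"
    RUNNING = "RUNNING"
    WALKING_OR_RUNNING = "WALKING_OR_RUNNING"
    STATIONARY = "STATIONARY"
    TILTING = "TILTING"
    UNKNOWN = "UNKNOWN"


class Transition(str, enum.Enum):
    ENTER = "ENTER"
    EXIT = "EXIT"


class Instrument(str, enum.Enum):
    PHQ9 = "PHQ9"
    CESDR = "CESDR"
    ISI = "ISI"
    PHQ2 = "PHQ2"
    TAM = "TAM"


class Wave(str, enum.Enum):
    """Questionnaire administration: baseline, mid-study, final, or daily prompt."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    DAILY = "DAILY"


class Diagnosis(str, enum.Enum):
    DEPRESSIVE = "DEPRESSIVE"
    NON_DEPRESSIVE = "NON_DEPRESSIVE"


class MoodLabel(str, enum.Enum):
    DEPRESSED = "DEPRESSED"
    NON_DEPRESSED = "NON_DEPRESSED"


@dataclass(frozen=True)
class ScreenEvent:
    participant_id: str
    timestamp: datetime
    state: ScreenState


@dataclass(frozen=True)
class GpsFix:
    participant_id: str
    timestamp: datetime
    latitude: float
    longitude: float


@dataclass(frozen=True)
class ActivityTransitionEvent:
    participant_id: str
    timestamp: datetime
    activity_class: ActivityClass
    transition: Transition


@dataclass(frozen=True)
class FaceEmbeddingRecord:
    """A precomputed facial-expression embedding (16-d metric-learning vector)."""

    participant_id: str
    timestamp: datetime
    embedding: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.embedding) != EMBEDDING_DIM:
            raise ValueError(
                f"embedding must have dimension {EMBEDDING_DIM}, got {len(self.embedding)}"
            )
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError("embedding contains non-finite values")


@dataclass(frozen=True)
class GenericRecord:
    """A row from a collected-but-unused table (calls, SMS, WiFi, ...)."""

    participant_id: str
    timestamp: datetime
    payload: tuple[tuple[str, str], ...]


@dataclass
class QuestionnaireRecord:
    participant_id: str
    instrument: Instrument
    wave: Wave
    item_scores: tuple[int, ...]
    total: Optional[int] = None


@dataclass
class SensorBundle:
    """All raw streams for one participant over the collection window."""

    participant_id: str
    window_start: datetime
    window_end: datetime
    screen_events: list[ScreenEvent] = field(default_factory=list)
    gps_fixes: list[GpsFix] = field(default_factory=list)
    activity_events: list[ActivityTransitionEvent] = field(default_factory=list)
    face_embeddings: list[FaceEmbeddingRecord] = field(default_factory=list)
    questionnaires: list[QuestionnaireRecord] = field(default_factory=list)
    aux_records: dict[str, list[GenericRecord]] = field(default_factory=dict)
    diagnosis: Optional[Diagnosis] = None
    flags: list[str] = field(default_factory=list)

    @property
    def window_days(self) -> float:
        return (self.window_end - self.window_start).total_seconds() / 86400.0


@dataclass
class LabelSet:
    participant_id: str
    phq9_label: Optional[MoodLabel] = None
    cesdr_label: Optional[MoodLabel] = None
    phq9_severity: Optional[str] = None
    diagnosis: Optional[Diagnosis] = None


def sorted_by_time(records: Sequence) -> list:
    """Stable sort of any record sequence by timestamp."""
    return sorted(records, key=lambda r: r.timestamp)
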