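"""Synthetic smartphone-sensing cohorts with a latent mood state.

The study's raw data are private, so every pipeline stage is exercised on
simulated participants instead.  Each participant carries a latent group
(depressed / control) that shifts the generative parameters of four streams:

* screen events — one long nocturnal OFF interval per night (the sleep
  candidate) plus evenly spaced daytime usage sessions realizing the group's
  daily screen-on budget;
* GPS fixes — hourly fixes at one of a handful of well-separated "places",
  chosen i.i.d. from the group's visit-probability vector, with a few meters
  of jitter, so expected location entropy is the entropy of that vector;
* activity transitions — walking/running episodes realizing the group's daily
  physical-activity budget, plus vehicle/cycling distractor episodes that the
  extractor must exclude;
* weekly expression embeddings and M1/M2/M3 questionnaire waves whose totals
  follow the group's score distribution.

Ground truth (realized per-participant means, entropies and totals) is
emitted alongside, enabling exact round-trip tests in the noiseless limit and
correlation tests under noise.  All randomness flows from one root seed via
named (participant, stream) sub-streams, so adding a stream type never
perturbs existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    EMBEDDING_DIM,
    ActivityClass,
    ActivityTransitionEvent,
    Diagnosis,
    FaceEmbeddingRecord,
    GpsFix,
    Instrument,
    QuestionnaireRecord,
    ScreenEvent,
    ScreenState,
    SensorBundle,
    Transition,
    Wave,
)

KST = timezone(timedelta(hours=9))

_STREAM_CODES = {
    "screen": 0,
    "gps": 1,
    "activity": 2,
    "expression": 3,
    "questionnaire": 4,
    "diagnosis": 5,
}

_DEPRESSED_EXPR_MEAN = tuple(
    [0.5, -0.5, 0.5, -0.5] + [0.0] * (EMBEDDING_DIM - 4)
)  # norm 1.0 -> 2 within-group SDs from the control centroid at default sd 0.5
_CONTROL_EXPR_MEAN = tuple([0.0] * EMBEDDING_DIM)


@dataclass
class GroupParams:
    """Generative parameters for one latent group."""

    sleep_mean_h: float
    sleep_sd_h: float
    usage_mean_h: float
    usage_sd_h: float
    visit_probs: tuple[float, ...]
    activity_mean_h: float
    activity_sd_h: float
    expression_mean: tuple[float, ...]
    expression_sd: float
    phq9_mean: float
    phq9_sd: float
    cesdr_mean: float
    cesdr_sd: float

    def __post_init__(self) -> None:
        if abs(sum(self.visit_probs) - 1.0) > 1e-9:
            raise ValueError("visit probabilities must sum to 1")
        for name in ("sleep_sd_h", "usage_sd_h", "activity_sd_h", "expression_sd",
                     "phq9_sd", "cesdr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def visit_entropy(self) -> float:
        p = np.asarray(self.visit_probs)
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))


def default_depressed_params() -> GroupParams:
    """Hypersomnic, homebound, screen-heavy profile with elevated scores."""
    return GroupParams(
        sleep_mean_h=9.5, sleep_sd_h=1.0,
        usage_mean_h=6.0, usage_sd_h=1.2,
        visit_probs=(0.85, 0.09, 0.03, 0.03),
        activity_mean_h=0.8, activity_sd_h=0.3,
        expression_mean=_DEPRESSED_EXPR_MEAN, expression_sd=0.5,
        phq9_mean=16.0, phq9_sd=4.0,
        cesdr_mean=30.0, cesdr_sd=9.0,
    )


def default_control_params() -> GroupParams:
    return GroupParams(
        sleep_mean_h=7.0, sleep_sd_h=0.8,
        usage_mean_h=3.5, usage_sd_h=1.0,
        visit_probs=(0.4, 0.25, 0.2, 0.15),
        activity_mean_h=2.5, activity_sd_h=0.6,
        expression_mean=_CONTROL_EXPR_MEAN, expression_sd=0.5,
        phq9_mean=5.0, phq9_sd=2.5,
        cesdr_mean=7.0, cesdr_sd=3.5,
    )


@dataclass
class CohortSpec:
    """Study-shaped cohort: 106 participants, 28 days, mood-imbalanced groups."""

    n_participants: int = 106
    depressed_fraction: float = 84 / 106
    days: int = 28
    seed: int = 0
    depressed: GroupParams = field(default_factory=default_depressed_params)
    control: GroupParams = field(default_factory=default_control_params)
    window_start: datetime = datetime(2021, 8, 19, 0, 0, tzinfo=KST)
    bedtime_h: float = 22.5
    schedule_jitter_h: float = 0.5
    fixes_per_day: int = 24
    gps_jitter_m: float = 10.0
    place_spacing_m: float = 5000.0
    base_lat: float = 37.50
    base_lon: float = 127.00
    diagnosis_agreement: float = 0.9

    def __post_init__(self) -> None:
        if self.n_participants < 0 or self.days < 1:
            raise ValueError("need n_participants >= 0 and days >= 1")
        if not 0.0 <= self.depressed_fraction <= 1.0:
            raise ValueError("depressed_fraction must lie in [0, 1]")

    def noiseless(self) -> "CohortSpec":
        """Copy with every noise source zeroed, for exact round-trip checks."""
        def quiet(p: GroupParams) -> GroupParams:
            return replace(
                p, sleep_sd_h=0.0, usage_sd_h=0.0, activity_sd_h=0.0,
                expression_sd=0.0, phq9_sd=0.0, cesdr_sd=0.0,
            )
        return replace(
            self,
            depressed=quiet(self.depressed),
            control=quiet(self.control),
            schedule_jitter_h=0.0,
            gps_jitter_m=0.0,
            diagnosis_agreement=1.0,
        )


def phq9_like_spec(**overrides) -> CohortSpec:
    """Scenario mirroring the 55:51 depressed/non-depressed split."""
    return CohortSpec(depressed_fraction=55 / 106, **overrides)


def cesdr_like_spec(**overrides) -> CohortSpec:
    """Scenario mirroring the 84:22 depressed/non-depressed split (the default)."""
    return CohortSpec(depressed_fraction=84 / 106, **overrides)


@dataclass
class ParticipantTruth:
    participant_id: str
    group: str  # "depressed" | "control"
    mean_sleep_h: float
    mean_usage_h: float
    entropy: float
    mean_activity_h: float
    phq9_total_m1: int
    cesdr_total_m1: int
    diagnosis: Diagnosis


def _rng(spec: CohortSpec, pidx: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), pidx, _STREAM_CODES[stream]])


def _day(spec: CohortSpec, d: int, hours: float) -> datetime:
    return spec.window_start + timedelta(days=d, hours=hours)


def generate_screen_stream(
    params: GroupParams, spec: CohortSpec, pid: str, rng: np.random.Generator
) -> tuple[list[ScreenEvent], datetime, float, float]:
    """Screen events for one participant.

    Returns (events, window_end, realized mean nightly sleep, realized mean
    daily usage).  Nights d = 0..days-1 each contribute one OFF interval of the
    drawn duration; usage days d = 0..days each realize the drawn screen-on
    budget exactly, split over 8 evenly spaced sessions ending at bedtime.
    Daytime gaps are bounded well below the minimum sleep duration, so the
    nightly interval is always the day's longest.
    """
    days = spec.days
    jitter = spec.schedule_jitter_h
    bedtimes = [
        _day(spec, d, spec.bedtime_h + (rng.uniform(-jitter, jitter) if jitter else 0.0))
        for d in range(days + 1)
    ]
    sleep_h = np.clip(rng.normal(params.sleep_mean_h, params.sleep_sd_h, days), 3.0, 12.0)
    usage_h = np.clip(
        rng.normal(params.usage_mean_h, params.usage_sd_h, days + 1), 0.25, 10.0
    )
    wake: list[datetime] = [_day(spec, 0, 7.0)]  # first morning; no prior night
    for d in range(days):
        wake.append(bedtimes[d] + timedelta(hours=float(sleep_h[d])))
    events: list[ScreenEvent] = []
    for d in range(days + 1):
        w, b = wake[d], bedtimes[d]
        span_h = (b - w).total_seconds() / 3600.0
        n_sessions = 8
        sess_len = float(usage_h[d]) / n_sessions
        step_h = (span_h - sess_len) / (n_sessions - 1)
        for k in range(n_sessions):
            start = w + timedelta(hours=k * step_h)
            events.append(ScreenEvent(pid, start, ScreenState.ON))
            events.append(ScreenEvent(pid, start + timedelta(hours=sess_len), ScreenState.OFF))
    window_end = bedtimes[days]
    return events, window_end, float(np.mean(sleep_h)), float(np.mean(usage_h))


def _place_centers(spec: CohortSpec, n_places: int) -> list[tuple[float, float]]:
    # Laid out west-to-east; spacing in degrees longitude at the base latitude.
    deg_per_m_lon = 1.0 / (111_320.0 * math.cos(math.radians(spec.base_lat)))
    return [
        (spec.base_lat, spec.base_lon + i * spec.place_spacing_m * deg_per_m_lon)
        for i in range(n_places)
    ]


def generate_gps_trace(
    params: GroupParams, spec: CohortSpec, pid: str, rng: np.random.Generator
) -> tuple[list[GpsFix], float]:
    """Hourly fixes at jittered place centers; returns (fixes, realized entropy)."""
    centers = _place_centers(spec, len(params.visit_probs))
    probs = np.asarray(params.visit_probs)
    n_fixes = spec.days * spec.fixes_per_day
    choices = rng.choice(len(centers), size=n_fixes, p=probs)
    deg_per_m_lat = 1.0 / 111_320.0
    deg_per_m_lon = 1.0 / (111_320.0 * math.cos(math.radians(spec.base_lat)))
    fixes = []
    for i, place in enumerate(choices):
        d, h = divmod(i, spec.fixes_per_day)
        lat, lon = centers[place]
        if spec.gps_jitter_m > 0:
            lat += rng.normal(0.0, spec.gps_jitter_m) * deg_per_m_lat
            lon += rng.normal(0.0, spec.gps_jitter_m) * deg_per_m_lon
        fixes.append(GpsFix(pid, _day(spec, d, h * 24.0 / spec.fixes_per_day), lat, lon))
    counts = np.bincount(choices, minlength=len(centers)).astype(float)
    p = counts[counts > 0] / counts.sum()
    realized_entropy = float(-np.sum(p * np.log(p)))
    return fixes, realized_entropy


def generate_activity_log(
    params: GroupParams, spec: CohortSpec, pid: str, rng: np.random.Generator
) -> tuple[list[ActivityTransitionEvent], float]:
    """Walking/running episodes realizing the daily activity budget, plus
    vehicle and cycling distractors that the included-class rule must drop."""
    events: list[ActivityTransitionEvent] = []
    totals = np.clip(
        rng.normal(params.activity_mean_h, params.activity_sd_h, spec.days), 0.05, 6.0
    )

    def episode(d: int, cls: ActivityClass, start_h: float, dur_h: float) -> None:
        events.append(
            ActivityTransitionEvent(pid, _day(spec, d, start_h), cls, Transition.ENTER)
        )
        events.append(
            ActivityTransitionEvent(pid, _day(spec, d, start_h + dur_h), cls, Transition.EXIT)
        )

    for d in range(spec.days):
        total = float(totals[d])
        episode(d, ActivityClass.VEHICLE, 8.0, 0.5)
        episode(d, ActivityClass.WALKING, 9.0, 0.8 * total)
        episode(d, ActivityClass.CYCLING, 16.0, 0.5)
        episode(d, ActivityClass.RUNNING, 17.0, 0.2 * total)
    events.sort(key=lambda e: e.timestamp)
    return events, float(np.mean(totals))


def _allocate_items(total: int, n_items: int, item_max: int) -> tuple[int, ...]:
    # Deterministic fill respecting per-item caps; total <= n_items * item_max.
    base, rem = divmod(total, n_items)
    items = [base + 1 if i < rem else base for i in range(n_items)]
    if max(items) > item_max:  # only possible at base == item_max, rem == 0
        raise ValueError(f"total {total} exceeds instrument maximum")
    return tuple(items)


def _draw_total(rng: np.random.Generator, mean: float, sd: float, max_total: int) -> int:
    return int(np.clip(round(rng.normal(mean, sd) if sd > 0 else mean), 0, max_total))


def generate_expression_and_questionnaires(
    params: GroupParams, spec: CohortSpec, pid: str, rng: np.random.Generator
) -> tuple[list[FaceEmbeddingRecord], list[QuestionnaireRecord]]:
    """Weekly embeddings around the group centroid; M1/M2/M3 questionnaire waves."""
    embeddings = []
    mean = np.asarray(params.expression_mean)
    for d in range(0, spec.days, 7):
        noise = (
            rng.normal(0.0, params.expression_sd, EMBEDDING_DIM)
            if params.expression_sd > 0
            else np.zeros(EMBEDDING_DIM)
        )
        embeddings.append(
            FaceEmbeddingRecord(
                pid, _day(spec, d, 12.0), tuple(float(x) for x in mean + noise)
            )
        )
    questionnaires = []
    wave_days = {Wave.M1: 0, Wave.M2: spec.days // 2, Wave.M3: spec.days - 1}
    for wave, d in wave_days.items():
        phq9 = _draw_total(rng, params.phq9_mean, params.phq9_sd, 27)
        cesdr = _draw_total(rng, params.cesdr_mean, params.cesdr_sd, 60)
        questionnaires.append(
            QuestionnaireRecord(pid, Instrument.PHQ9, wave, _allocate_items(phq9, 9, 3))
        )
        questionnaires.append(
            QuestionnaireRecord(pid, Instrument.CESDR, wave, _allocate_items(cesdr, 20, 3))
        )
        questionnaires.append(
            QuestionnaireRecord(
                pid, Instrument.ISI, wave, tuple(int(x) for x in rng.integers(0, 5, 7))
            )
        )
    return embeddings, questionnaires


def generate_participant(
    spec: CohortSpec, pidx: int, group: str
) -> tuple[SensorBundle, ParticipantTruth]:
    params = spec.depressed if group == "depressed" else spec.control
    pid = f"p{pidx:03d}"
    events, window_end, mean_sleep, mean_usage = generate_screen_stream(
        params, spec, pid, _rng(spec, pidx, "screen")
    )
    fixes, entropy = generate_gps_trace(params, spec, pid, _rng(spec, pidx, "gps"))
    activity, mean_activity = generate_activity_log(
        params, spec, pid, _rng(spec, pidx, "activity")
    )
    embeddings, questionnaires = generate_expression_and_questionnaires(
        params, spec, pid, _rng(spec, pidx, "questionnaire")
    )
    drng = _rng(spec, pidx, "diagnosis")
    agree = drng.random() < spec.diagnosis_agreement
    is_dep = group == "depressed"
    diagnosis = (
        Diagnosis.DEPRESSIVE if (is_dep == agree) else Diagnosis.NON_DEPRESSIVE
    )
    bundle = SensorBundle(
        participant_id=pid,
        window_start=spec.window_start,
        window_end=window_end,
        screen_events=events,
        gps_fixes=fixes,
        activity_events=activity,
        face_embeddings=embeddings,
        questionnaires=questionnaires,
        diagnosis=diagnosis,
    )
    m1 = {
        (q.instrument): sum(q.item_scores)
        for q in questionnaires
        if q.wave == Wave.M1 and q.instrument in (Instrument.PHQ9, Instrument.CESDR)
    }
    truth = ParticipantTruth(
        participant_id=pid,
        group=group,
        mean_sleep_h=mean_sleep,
        mean_usage_h=mean_usage,
        entropy=entropy,
        mean_activity_h=mean_activity,
        phq9_total_m1=m1[Instrument.PHQ9],
        cesdr_total_m1=m1[Instrument.CESDR],
        diagnosis=diagnosis,
    )
    return bundle, truth


def generate_cohort(spec: Optional[CohortSpec] = None) -> tuple[list[SensorBundle], pd.DataFrame]:
    """Generate the full cohort; returns (bundles, ground-truth table)."""
    spec = spec or CohortSpec()
    n_dep = int(round(spec.n_participants * spec.depressed_fraction))
    groups = ["depressed"] * n_dep + ["control"] * (spec.n_participants - n_dep)
    bundles, truths = [], []
    for pidx, group in enumerate(groups):
        bundle, truth = generate_participant(spec, pidx, group)
        bundles.append(bundle)
        truths.append(truth)
    truth_frame = pd.DataFrame([vars(t) for t in truths])
    if not truth_frame.empty:
        truth_frame["diagnosis"] = truth_frame["diagnosis"].map(lambda d: d.value)
        truth_frame = truth_frame.set_index("participant_id")
    return bundles, truth_frame
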