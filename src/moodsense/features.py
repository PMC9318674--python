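"""The 33 multimodal derived features.

Four blocks, in a fixed documented order:

* sleep (14): seven summary statistics of the daily sleep estimate (longest
  screen-off interval per noon-to-noon day, with afternoon-only and >24 h
  candidates discarded) and seven of daily screen-on time;
* mobility (2): log location variance, log(sigma_lat^2 + sigma_lon^2), and
  the entropy -sum p_i ln p_i of time spent across significant places found
  by haversine DBSCAN;
* activity (1): mean daily time in the physical-activity motion classes;
* expression (16): element-wise mean of the facial-expression embeddings.

Each block carries a provenance flag (observed / missing / imputed); missing
blocks are emitted as NaN so the downstream policy (drop the participant, or
impute training-set means) can be applied without information loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .types import (
    EMBEDDING_DIM,
    ActivityClass,
    ActivityTransitionEvent,
    FaceEmbeddingRecord,
    GpsFix,
    ScreenEvent,
    ScreenState,
    SensorBundle,
)

EARTH_RADIUS_M = 6_371_000.0

STAT_NAMES = ("max", "min", "mean", "sd", "q1", "q2", "q3")

FEATURE_NAMES: list[str] = (
    [f"sleep_{s}" for s in STAT_NAMES]
    + [f"usage_{s}" for s in STAT_NAMES]
    + ["location_variance", "location_entropy", "activity_hours"]
    + [f"expr_{i:02d}" for i in range(EMBEDDING_DIM)]
)

#: Column blocks of the 33-feature matrix, as used in the ablation.
FEATURE_GROUPS: dict[str, slice] = {
    "sleep": slice(0, 14),
    "activity": slice(14, 17),  # mobility (2) + daily physical activity (1)
    "expression": slice(17, 33),
}

DEFAULT_ACTIVITY_CLASSES = frozenset(
    {ActivityClass.STATIONARY, ActivityClass.RUNNING, ActivityClass.WALKING}
)
LOCOMOTION_ACTIVITY_CLASSES = frozenset(
    {ActivityClass.WALKING, ActivityClass.RUNNING, ActivityClass.WALKING_OR_RUNNING}
)


@dataclass
class FeatureConfig:
    """Tunables for feature extraction; defaults are the package's documented choices."""

    dbscan_eps_m: float = 300.0
    dbscan_min_samples: int = 5
    variance_floor: float = 1e-12  # degrees^2, keeps single-place participants finite
    afternoon_start: time = time(12, 0)
    afternoon_end: time = time(18, 0)
    activity_classes: frozenset = DEFAULT_ACTIVITY_CLASSES


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters between coordinate pairs in degrees."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Sleep block: screen-off intervals -> daily sleep estimate + daily usage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffInterval:
    start: datetime
    end: datetime
    unterminated: bool = False

    @property
    def hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def midpoint(self) -> datetime:
        return self.start + (self.end - self.start) / 2


def screen_off_intervals(
    events: Sequence[ScreenEvent], window_end: Optional[datetime] = None
) -> list[OffInterval]:
    """Maximal screen-off intervals from alternating ON/OFF events.

    A trailing OFF with no subsequent ON is closed at ``window_end`` (when
    given) and flagged unterminated.
    """
    intervals: list[OffInterval] = []
    off_since: Optional[datetime] = None
    for ev in events:
        if ev.state == ScreenState.OFF:
            if off_since is None:
                off_since = ev.timestamp
        else:
            if off_since is not None:
                intervals.append(OffInterval(off_since, ev.timestamp))
                off_since = None
    if off_since is not None and window_end is not None and window_end > off_since:
        intervals.append(OffInterval(off_since, window_end, unterminated=True))
    return intervals


def _sleep_date(midpoint: datetime) -> date:
    # Noon-to-noon windows keyed by the date of the window's *end* noon, so an
    # overnight interval is attributed to the morning it ends on.
    return midpoint.date() if midpoint.time() < time(12, 0) else midpoint.date() + timedelta(days=1)


def estimate_daily_sleep(
    intervals: Iterable[OffInterval],
    config: Optional[FeatureConfig] = None,
    window: Optional[tuple[datetime, datetime]] = None,
) -> dict[date, float]:
    """Daily sleep in hours: the longest surviving off-interval per noon-to-noon day.

    Candidates longer than 24 h, or lying entirely inside the local afternoon
    span (12:00-18:00 by default), are discarded; a day with no surviving
    candidate is absent from the result.  When the collection ``window`` is
    given, days whose noon-to-noon span is truncated by the window boundary
    are dropped: a partial span cannot contain a full night and would
    otherwise report a short daytime gap as that day's sleep.
    """
    config = config or FeatureConfig()
    best: dict[date, float] = {}
    for iv in intervals:
        if iv.hours > 24.0:
            continue
        same_day = iv.start.date() == iv.end.date()
        if (
            same_day
            and iv.start.time() >= config.afternoon_start
            and iv.end.time() <= config.afternoon_end
        ):
            continue
        day = _sleep_date(iv.midpoint)
        if iv.hours > best.get(day, -1.0):
            best[day] = iv.hours
    if window is not None:
        start, end = window
        tz = start.tzinfo
        best = {
            day: hours
            for day, hours in best.items()
            if datetime.combine(day - timedelta(days=1), time(12, 0), tzinfo=tz) >= start
            and datetime.combine(day, time(12, 0), tzinfo=tz) <= end
        }
    return best


def _split_at_midnight(start: datetime, end: datetime) -> Iterable[tuple[date, float]]:
    cur = start
    while cur < end:
        next_midnight = datetime.combine(
            cur.date() + timedelta(days=1), time(0, 0), tzinfo=cur.tzinfo
        )
        seg_end = min(end, next_midnight)
        yield cur.date(), (seg_end - cur).total_seconds() / 3600.0
        cur = seg_end


def daily_usage(
    events: Sequence[ScreenEvent],
    window: Optional[tuple[datetime, datetime]] = None,
) -> dict[date, float]:
    """Screen-on hours per local calendar day; ON spans crossing midnight are split.

    With a window, every day of the window appears (0.0 when no usage); a
    trailing ON without an OFF is closed at the window end.
    """
    usage: dict[date, float] = {}
    if window is not None:
        d = window[0].date()
        while d <= window[1].date():
            usage[d] = 0.0
            d += timedelta(days=1)
    on_since: Optional[datetime] = None
    for ev in events:
        if ev.state == ScreenState.ON:
            if on_since is None:
                on_since = ev.timestamp
        else:
            if on_since is not None:
                for day, hours in _split_at_midnight(on_since, ev.timestamp):
                    usage[day] = usage.get(day, 0.0) + hours
                on_since = None
    if on_since is not None and window is not None and window[1] > on_since:
        for day, hours in _split_at_midnight(on_since, window[1]):
            usage[day] = usage.get(day, 0.0) + hours
    return usage


@dataclass(frozen=True)
class StatSummary:
    """The seven summary statistics: max, min, mean, sd (n-1), and quartiles."""

    maximum: float
    minimum: float
    mean: float
    sd: float
    q1: float
    q2: float
    q3: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.maximum, self.minimum, self.mean, self.sd, self.q1, self.q2, self.q3]
        )


def stat_summary(series: Sequence[float]) -> Optional[StatSummary]:
    """Summarize a series of daily values; ``None`` signals a missing group.

    Quartiles use linear interpolation; sd uses the n-1 denominator (0 for a
    single observation).
    """
    values = np.asarray([v for v in series if v is not None and np.isfinite(v)], float)
    if values.size == 0:
        return None
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return StatSummary(
        maximum=float(values.max()),
        minimum=float(values.min()),
        mean=float(values.mean()),
        sd=sd,
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
    )


def sleep_feature_block(
    bundle: SensorBundle, config: Optional[FeatureConfig] = None
) -> Optional[np.ndarray]:
    """14 sleep features: stats of daily sleep hours then stats of daily usage hours."""
    config = config or FeatureConfig()
    if not bundle.screen_events:
        return None
    intervals = screen_off_intervals(bundle.screen_events, bundle.window_end)
    sleep = estimate_daily_sleep(
        intervals, config, (bundle.window_start, bundle.window_end)
    )
    usage = daily_usage(bundle.screen_events, (bundle.window_start, bundle.window_end))
    sleep_stats = stat_summary(list(sleep.values()))
    usage_stats = stat_summary(list(usage.values()))
    if sleep_stats is None or usage_stats is None:
        return None
    return np.concatenate([sleep_stats.as_array(), usage_stats.as_array()])


# ---------------------------------------------------------------------------
# Mobility block: DBSCAN significant places -> variance + entropy
# ---------------------------------------------------------------------------


def cluster_gps(
    fixes: Sequence[GpsFix], eps_meters: float = 300.0, min_samples: int = 5
) -> np.ndarray:
    """DBSCAN cluster label per fix (-1 = noise) under haversine distance.

    Fixes are clustered in timestamp order and cluster ids are renumbered by
    first appearance in time, so labels are deterministic for a given input.
    """
    if not fixes:
        return np.empty(0, dtype=int)
    order = np.argsort([f.timestamp for f in fixes], kind="stable")
    coords = np.radians([[fixes[i].latitude, fixes[i].longitude] for i in order])
    raw = DBSCAN(
        eps=eps_meters / EARTH_RADIUS_M,
        min_samples=min_samples,
        metric="haversine",
        algorithm="ball_tree",
    ).fit_predict(coords)
    remap: dict[int, int] = {}
    canonical = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab == -1:
            canonical[i] = -1
        else:
            canonical[i] = remap.setdefault(lab, len(remap))
    labels = np.empty(len(fixes), dtype=int)
    labels[order] = canonical
    return labels


def location_variance(
    fixes: Sequence[GpsFix], floor: float = 1e-12
) -> Optional[float]:
    """log(var(lat) + var(lon)) in degrees^2 (population variance), floored at ``floor``."""
    if len(fixes) < 2:
        return None
    lat = np.array([f.latitude for f in fixes])
    lon = np.array([f.longitude for f in fixes])
    total_var = float(np.var(lat) + np.var(lon))
    return math.log(max(total_var, floor))


def location_entropy(labels: Sequence[int]) -> Optional[float]:
    """Shannon entropy (nats) of the fix distribution over clusters; noise excluded."""
    labels = np.asarray(labels, dtype=int)
    clustered = labels[labels >= 0]
    if clustered.size == 0:
        return None
    _, counts = np.unique(clustered, return_counts=True)
    if counts.size <= 1:
        return 0.0
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def mobility_features(
    fixes: Sequence[GpsFix], config: Optional[FeatureConfig] = None
) -> tuple[Optional[float], Optional[float], int]:
    """(location variance, entropy, number of significant places) for one participant."""
    config = config or FeatureConfig()
    variance = location_variance(fixes, config.variance_floor)
    labels = cluster_gps(fixes, config.dbscan_eps_m, config.dbscan_min_samples)
    entropy = location_entropy(labels) if labels.size else None
    n_clusters = int(labels.max() + 1) if labels.size and labels.max() >= 0 else 0
    return variance, entropy, n_clusters


# ---------------------------------------------------------------------------
# Activity block
# ---------------------------------------------------------------------------


def daily_activity_time(
    events: Sequence[ActivityTransitionEvent],
    included_classes: Iterable[ActivityClass] = DEFAULT_ACTIVITY_CLASSES,
    window_end: Optional[datetime] = None,
) -> Optional[float]:
    """Mean hours/day spent in the included motion classes.

    ENTER/EXIT events are paired per class; an unmatched trailing ENTER is
    closed at the window end.  The mean is taken over days touched by any
    activity episode, so days observed only in excluded classes contribute
    0 included hours rather than being dropped.
    """
    if not events:
        return None
    included = set(included_classes)
    per_day_included: dict[date, float] = {}
    observed_days: set[date] = set()
    pending: dict[ActivityClass, datetime] = {}
    episodes: list[tuple[ActivityClass, datetime, datetime]] = []
    for ev in events:
        if ev.transition.value == "ENTER":
            pending.setdefault(ev.activity_class, ev.timestamp)
        else:
            start = pending.pop(ev.activity_class, None)
            if start is not None and ev.timestamp > start:
                episodes.append((ev.activity_class, start, ev.timestamp))
    if window_end is not None:
        for cls, start in pending.items():
            if window_end > start:
                episodes.append((cls, start, window_end))
    if not episodes:
        return None
    for cls, start, end in episodes:
        for day, hours in _split_at_midnight(start, end):
            observed_days.add(day)
            if cls in included:
                per_day_included[day] = per_day_included.get(day, 0.0) + hours
    return float(
        np.mean([per_day_included.get(day, 0.0) for day in sorted(observed_days)])
    )


# ---------------------------------------------------------------------------
# Expression block
# ---------------------------------------------------------------------------


def aggregate_expression(
    records: Sequence[FaceEmbeddingRecord],
) -> Optional[np.ndarray]:
    """Element-wise mean of the (weekly) 16-d expression embeddings."""
    if not records:
        return None
    mat = np.array([r.embedding for r in records], float)
    if mat.shape[1] != EMBEDDING_DIM:
        raise ValueError(f"expected embeddings of dimension {EMBEDDING_DIM}")
    return mat.mean(axis=0)


def stub_embedder(identifier: str) -> np.ndarray:
    """Deterministic stand-in embedder: maps a string to a unit-norm 16-vector.

    Synthetic replacement for the on-device expression network, used in tests
    and simulations; real embeddings plug in through FaceEmbeddingRecord.
    """
    seed = int.from_bytes(
        __import__("hashlib").sha256(identifier.encode()).digest()[:4], "big"
    )
    vec = np.random.default_rng(seed).standard_normal(EMBEDDING_DIM)
    return vec / np.linalg.norm(vec)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

GROUP_NAMES = ("sleep", "mobility", "activity", "expression")

#: Provenance groups mapped onto feature columns (mobility+activity form the
#: ablation "activity" block but carry separate provenance).
_PROVENANCE_SLICES = {
    "sleep": slice(0, 14),
    "mobility": slice(14, 16),
    "activity": slice(16, 17),
    "expression": slice(17, 33),
}


@dataclass
class FeatureVector:
    participant_id: str
    values: np.ndarray  # length 33, NaN where a group is missing
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have length {len(FEATURE_NAMES)}, "
                f"got {self.values.shape}"
            )


def assemble_features(
    bundle: SensorBundle, config: Optional[FeatureConfig] = None
) -> FeatureVector:
    """Extract the full 33-feature vector from one participant bundle."""
    config = config or FeatureConfig()
    values = np.full(len(FEATURE_NAMES), np.nan)
    provenance = {g: "missing" for g in GROUP_NAMES}

    sleep = sleep_feature_block(bundle, config)
    if sleep is not None:
        values[_PROVENANCE_SLICES["sleep"]] = sleep
        provenance["sleep"] = "observed"

    variance, entropy, _ = mobility_features(bundle.gps_fixes, config)
    if variance is not None and entropy is not None:
        values[14], values[15] = variance, entropy
        provenance["mobility"] = "observed"

    activity = daily_activity_time(
        bundle.activity_events, config.activity_classes, bundle.window_end
    )
    if activity is not None:
        values[16] = activity
        provenance["activity"] = "observed"

    expression = aggregate_expression(bundle.face_embeddings)
    if expression is not None:
        values[_PROVENANCE_SLICES["expression"]] = expression
        provenance["expression"] = "observed"

    return FeatureVector(bundle.participant_id, values, provenance)


def feature_matrix(
    bundles: Sequence[SensorBundle],
    config: Optional[FeatureConfig] = None,
    missing_policy: str = "drop",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort feature matrix (participants x 33) plus per-group provenance flags.

    ``missing_policy``: "drop" removes participants with any missing group
    (the study default); "keep" retains NaNs for downstream train-mean
    imputation.
    """
    if missing_policy not in ("drop", "keep"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    vectors = [assemble_features(b, config) for b in bundles]
    matrix = pd.DataFrame(
        [v.values for v in vectors],
        index=[v.participant_id for v in vectors],
        columns=FEATURE_NAMES,
    )
    matrix.index.name = "participant_id"
    prov = pd.DataFrame(
        [v.provenance for v in vectors], index=matrix.index, columns=list(GROUP_NAMES)
    )
    if missing_policy == "drop":
        keep = matrix.notna().all(axis=1)
        dropped = matrix.index[~keep].tolist()
        if dropped:
            import logging

            logging.getLogger(__name__).info(
                "dropped %d participants with missing feature groups: %s",
                len(dropped),
                dropped,
            )
        matrix, prov = matrix.loc[keep], prov.loc[keep]
    return matrix, prov
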