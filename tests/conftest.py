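"""Shared fixtures, time helpers and independent oracles for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from moodsense.features import haversine_m
from moodsense.types import ScreenEvent, ScreenState

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TZ = timezone(timedelta(hours=9))
BASE = datetime(2021, 8, 19, 0, 0, tzinfo=TZ)


def t(day: int, hour: float = 0.0) -> datetime:
    """Timestamp `hour` hours into calendar day `day` of the study window."""
    return BASE + timedelta(days=day, hours=hour)


def screen(pid: str, *events: tuple[int, float, str]) -> list[ScreenEvent]:
    return [ScreenEvent(pid, t(d, h), ScreenState(s)) for d, h, s in events]


# ---------------------------------------------------------------------------
# Independent oracles (never share code with the implementation they check)
# ---------------------------------------------------------------------------


def dbscan_oracle(coords_deg: np.ndarray, eps_m: float, min_samples: int) -> np.ndarray:
    """Brute-force O(n^2) DBSCAN over haversine distances.

    Clusters are numbered in order of their seed point; border points join the
    first cluster whose expansion reaches them, matching the classic
    index-ordered formulation.
    """
    n = len(coords_deg)
    labels = np.full(n, -2)  # -2 unvisited, -1 noise
    if n == 0:
        return labels
    lat = coords_deg[:, 0][:, None]
    lon = coords_deg[:, 1][:, None]
    dist = haversine_m(lat, lon, lat.T, lon.T)
    neighbors = dist <= eps_m
    core = neighbors.sum(axis=1) >= min_samples
    cluster = 0
    for i in range(n):
        if labels[i] != -2 or not core[i]:
            continue
        labels[i] = cluster
        queue = [i]
        while queue:
            j = queue.pop(0)
            if not core[j]:
                continue
            for k in np.flatnonzero(neighbors[j]):
                if labels[k] in (-2, -1):
                    labels[k] = cluster
                    queue.append(k)
        cluster += 1
    labels[labels == -2] = -1
    return labels


def canonical_labels(labels) -> np.ndarray:
    """Renumber cluster ids by first appearance (noise stays -1), so label
    comparisons are insensitive to arbitrary cluster numbering."""
    labels = np.asarray(labels)
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        out[i] = -1 if lab == -1 else remap.setdefault(int(lab), len(remap))
    return out


def metrics_oracle(pred, truth) -> dict:
    """Count-based precision/recall/f1/accuracy for the positive class (percent)."""
    pred, truth = list(pred), list(truth)
    tp = fp = fn = tn = 0
    for p, y in zip(pred, truth):
        if p == 1 and y == 1:
            tp += 1
        elif p == 1 and y == 0:
            fp += 1
        elif p == 0 and y == 1:
            fn += 1
        else:
            tn += 1
    precision = 100 * tp / (tp + fp) if tp + fp else None
    recall = 100 * tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": 100 * (tp + tn) / len(pred) if pred else None,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy synthetic cohort shared by read-only tests."""
    from moodsense.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_participants=10, depressed_fraction=0.5, days=10, seed=11)
    return generate_cohort(spec)
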