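"""Scoring and labeling of self-report depression questionnaires.

Two instruments drive the binary depressed-mood label: the nine-item PHQ-9
(total 0-27, depressed at >= 10) and the 20-item CESD-R scored here on the
study's 0-60 range, with the Korean-calibrated cut-point of 13.  ISI, PHQ-2
and TAM records are stored but never scored semantically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .types import Instrument, LabelSet, MoodLabel, QuestionnaireRecord, Wave

PHQ9_CUTPOINT = 10
CESDR_CUTPOINT = 13

_ITEM_SPECS = {
    Instrument.PHQ9: (9, 0, 3, 27),
    Instrument.CESDR: (20, 0, 3, 60),
}

#: Five-band severity scheme: (band name, inclusive upper edge).
FIVE_BAND_SCHEME = [
    ("normal", 4),
    ("minimum", 9),
    ("mild", 14),
    ("moderate", 19),
    ("severe", 27),
]


def six_band_scheme(minimal_minor_edge: int = 7) -> list[tuple[str, int]]:
    """Six-band variant with a configurable minimal/minor split inside 5-9."""
    if not 5 <= minimal_minor_edge <= 8:
        raise ValueError("minimal/minor edge must lie in [5, 8]")
    return [
        ("normal", 4),
        ("minimal", minimal_minor_edge),
        ("minor", 9),
        ("moderate", 14),
        ("moderately severe", 19),
        ("severe", 27),
    ]


class ScoringError(ValueError):
    """Item count or item value outside the instrument's legal range."""


def score_instrument(record: QuestionnaireRecord) -> int:
    """Validate item responses and return the instrument total (sum of items).

    PHQ-9 and CESD-R item counts and 0-3 ranges are enforced; other stored
    instruments are summed without semantic validation.
    """
    spec = _ITEM_SPECS.get(record.instrument)
    if spec is not None:
        n_items, lo, hi, _ = spec
        if len(record.item_scores) != n_items:
            raise ScoringError(
                f"{record.instrument.value} expects {n_items} items, "
                f"got {len(record.item_scores)}"
            )
        for i, score in enumerate(record.item_scores):
            if not lo <= score <= hi:
                raise ScoringError(
                    f"{record.instrument.value} item {i + 1} score {score} "
                    f"outside [{lo}, {hi}]"
                )
    total = int(sum(record.item_scores))
    record.total = total
    return total


def _check_total(total: int, instrument: Instrument) -> None:
    _, _, _, max_total = _ITEM_SPECS[instrument]
    if not 0 <= total <= max_total:
        raise ScoringError(
            f"{instrument.value} total {total} outside [0, {max_total}]"
        )


def phq9_label(total: int, cutpoint: int = PHQ9_CUTPOINT) -> MoodLabel:
    """Depressed mood iff the PHQ-9 total reaches the cut-point (default 10)."""
    _check_total(total, Instrument.PHQ9)
    return MoodLabel.DEPRESSED if total >= cutpoint else MoodLabel.NON_DEPRESSED


def cesdr_label(total: int, cutpoint: int = CESDR_CUTPOINT) -> MoodLabel:
    """Depressed mood iff the CESD-R total reaches the cut-point (default 13)."""
    _check_total(total, Instrument.CESDR)
    return MoodLabel.DEPRESSED if total >= cutpoint else MoodLabel.NON_DEPRESSED


def phq9_severity_band(
    total: int, scheme: Optional[list[tuple[str, int]]] = None
) -> str:
    """Map a PHQ-9 total to its severity band (five-band scheme by default)."""
    _check_total(total, Instrument.PHQ9)
    for name, upper in scheme or FIVE_BAND_SCHEME:
        if total <= upper:
            return name
    raise ScoringError(f"severity scheme does not cover total {total}")


@dataclass
class LabelConfig:
    label_wave: Wave = Wave.M1
    phq9_cutpoint: int = PHQ9_CUTPOINT
    cesdr_cutpoint: int = CESDR_CUTPOINT
    severity_scheme: Optional[list[tuple[str, int]]] = None


def build_labelset(
    participant_id: str,
    records: list[QuestionnaireRecord],
    diagnosis=None,
    config: Optional[LabelConfig] = None,
) -> LabelSet:
    """Derive the participant's label set from one questionnaire wave.

    The labeling wave is configurable (baseline M1 by default); a missing
    instrument at that wave leaves the corresponding label ``None``.
    """
    config = config or LabelConfig()
    labels = LabelSet(participant_id=participant_id, diagnosis=diagnosis)
    for record in records:
        if record.wave != config.label_wave:
            continue
        total = score_instrument(record)
        if record.instrument == Instrument.PHQ9:
            labels.phq9_label = phq9_label(total, config.phq9_cutpoint)
            labels.phq9_severity = phq9_severity_band(total, config.severity_scheme)
        elif record.instrument == Instrument.CESDR:
            labels.cesdr_label = cesdr_label(total, config.cesdr_cutpoint)
    return labels
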