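"""End-to-end orchestration: simulate/load -> validate -> extract -> train -> report.

A single :class:`RunConfig` (YAML-loadable) drives the whole run.  Every run
directory is self-describing: the manifest records the config hash, seed,
package version and per-stage record counts, so a run can be reproduced
bit-for-bit from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureConfig, feature_matrix
from .model_eval import (
    EvalReport,
    ModelConfig,
    SplitResult,
    ablation_by_group,
    compare_to_diagnosis,
    evaluate,
    impute_train_means,
    split_cohort,
    train_model,
)
from .questionnaires import LabelConfig, build_labelset
from .sensor_io import ExclusionPolicy, apply_exclusion_rules, load_cohort
from .synthetic import CohortSpec, generate_cohort
from .types import MoodLabel, SensorBundle

logger = logging.getLogger(__name__)


class RunConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    input_dir: Optional[str] = None
    simulation: Optional[dict] = None  # CohortSpec overrides
    output_dir: Optional[str] = None
    label_source: str = "CESDR"  # or "PHQ9"
    missing_policy: str = "drop"  # or "impute"
    features: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise RunConfigError(
                "exactly one of input_dir / simulation must be configured"
            )
        if self.label_source not in ("PHQ9", "CESDR"):
            raise RunConfigError(f"unknown label_source {self.label_source!r}")
        if self.missing_policy not in ("drop", "impute"):
            raise RunConfigError(f"unknown missing_policy {self.missing_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise RunConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(**self.features)

    def model_config(self) -> ModelConfig:
        kwargs = dict(self.model)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("label_source", self.label_source)
        return ModelConfig(**kwargs)

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.simulation or {})
        kwargs.setdefault("seed", self.seed)
        return CohortSpec(**kwargs)


@dataclass
class RunArtifacts:
    features: pd.DataFrame
    provenance: pd.DataFrame
    labels: pd.DataFrame
    split: SplitResult
    questionnaire_report: EvalReport
    diagnosis_report: Optional[EvalReport]
    ablation: dict[str, float]
    manifest: dict


def _label_frame(bundles: list[SensorBundle], label_config: LabelConfig) -> pd.DataFrame:
    rows = []
    for b in bundles:
        ls = build_labelset(b.participant_id, b.questionnaires, b.diagnosis, label_config)
        rows.append(
            {
                "participant_id": b.participant_id,
                "PHQ9": ls.phq9_label.value if ls.phq9_label else None,
                "CESDR": ls.cesdr_label.value if ls.cesdr_label else None,
                "phq9_severity": ls.phq9_severity,
                "diagnosis": ls.diagnosis.value if ls.diagnosis else None,
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute every stage and (optionally) persist artifacts to the output dir."""
    logging.basicConfig(level=config.log_level)
    counts: dict[str, int] = {}

    if config.simulation is not None:
        bundles, ground_truth = generate_cohort(config.cohort_spec())
    else:
        bundles, _ = load_cohort(config.input_dir)
        ground_truth = None
    counts["participants_input"] = len(bundles)

    bundles, exclusion = apply_exclusion_rules(bundles, ExclusionPolicy())
    counts["participants_retained"] = exclusion.n_retained

    label_config = LabelConfig(**config.labels)
    labels = _label_frame(bundles, label_config)
    matrix, provenance = feature_matrix(
        bundles,
        config.feature_config(),
        missing_policy="keep" if config.missing_policy == "impute" else "drop",
    )
    labels = labels.loc[matrix.index]
    y_raw = labels[config.label_source]
    usable = y_raw.notna()
    matrix, provenance, labels = matrix[usable], provenance[usable], labels[usable]
    y = (y_raw[usable] == MoodLabel.DEPRESSED.value).astype(int)
    counts["participants_featurized"] = len(matrix)

    split = split_cohort(list(matrix.index), test_fraction=0.25, seed=config.seed)
    X_train = matrix.loc[list(split.train_ids)]
    X_test = matrix.loc[list(split.test_ids)]
    if config.missing_policy == "impute":
        X_train, X_test = impute_train_means(X_train, X_test)
        matrix = pd.concat([X_train, X_test]).loc[matrix.index]
    model_config = config.model_config()
    model = train_model(X_train.to_numpy(), y.loc[X_train.index], model_config)
    predictions = model.predict(X_test.to_numpy())
    questionnaire_report = evaluate(predictions, y.loc[X_test.index])

    diagnosis_report = None
    diag = labels.loc[list(split.test_ids), "diagnosis"]
    if diag.notna().any():
        from .types import Diagnosis

        diagnosis_report, _ = compare_to_diagnosis(
            predictions, [Diagnosis(d) if pd.notna(d) else None for d in diag]
        )

    ablation = ablation_by_group(matrix, y.loc[matrix.index], split, model_config)

    manifest = {
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical()),
        "seed": config.seed,
        "version": __version__,
        "counts": counts,
        "split": {"train": len(split.train_ids), "test": len(split.test_ids)},
        "exclusions": exclusion.reasons,
    }
    artifacts = RunArtifacts(
        features=matrix,
        provenance=provenance,
        labels=labels,
        split=split,
        questionnaire_report=questionnaire_report,
        diagnosis_report=diagnosis_report,
        ablation=ablation,
        manifest=manifest,
    )
    if config.output_dir:
        _write_artifacts(artifacts, Path(config.output_dir), ground_truth)
    return artifacts


def _write_artifacts(
    artifacts: RunArtifacts, outdir: Path, ground_truth: Optional[pd.DataFrame]
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts.features.join(artifacts.provenance.add_suffix("_provenance")).to_csv(
        outdir / "features.csv"
    )
    artifacts.labels.to_csv(outdir / "labels.csv")
    if ground_truth is not None:
        ground_truth.to_csv(outdir / "ground_truth.csv")
    reports = {
        "questionnaire": artifacts.questionnaire_report.to_dict(),
        "diagnosis": artifacts.diagnosis_report.to_dict()
        if artifacts.diagnosis_report
        else None,
        "ablation": artifacts.ablation,
    }
    (outdir / "reports.json").write_text(json.dumps(reports, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(artifacts.manifest, indent=2))
    (outdir / "report.txt").write_text(
        render_report(
            {"questionnaire truth": artifacts.questionnaire_report}
            | (
                {"clinician diagnosis": artifacts.diagnosis_report}
                if artifacts.diagnosis_report
                else {}
            ),
            artifacts.ablation,
        )
    )


def _fmt(value: Optional[float]) -> str:
    return f"{value:6.2f}" if value is not None else "   n/a"


def render_report(reports: dict[str, EvalReport], ablation: Optional[dict[str, float]] = None) -> str:
    """Render accuracy-by-group and precision/recall/F1 tables as text."""
    lines: list[str] = []
    if ablation:
        lines.append("Accuracy by derived feature group (%)")
        for name, acc in ablation.items():
            label = "all features" if name == "all" else name
            lines.append(f"  {label:<14} {acc:6.2f}")
        lines.append("")
    for title, report in reports.items():
        lines.append(f"Classification vs {title} (n={report.n})")
        lines.append(f"  {'class':<16} {'precision':>9} {'recall':>7} {'f1':>7}")
        for cls, m in report.per_class.items():
            lines.append(
                f"  {cls:<16} {_fmt(m.precision):>9} {_fmt(m.recall):>7} {_fmt(m.f1):>7}"
            )
        for mode in ("macro", "weighted"):
            agg = getattr(report, mode)
            lines.append(
                f"  {f'total ({mode})':<16} {_fmt(agg.get('precision')):>9} "
                f"{_fmt(agg.get('recall')):>7} {_fmt(agg.get('f1')):>7}"
            )
        lines.append(f"  accuracy {report.accuracy:.2f}%")
        lines.append("")
    return "\n".join(lines)
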