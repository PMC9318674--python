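"""Full pipeline: simulate a study-shaped cohort, train, evaluate, ablate.

Generates 106 synthetic participants (84:22 depressed/non-depressed, the
CESD-R-like imbalance), extracts the 33-feature matrix, trains the
1000-tree random forest on a random 3:1 split, and prints held-out
precision/recall/F1 against both questionnaire labels and the clinician
diagnosis, plus the per-feature-group ablation.
"""

from moodsense import RunConfig, render_report, run_pipeline

config = RunConfig(
    seed=1,
    simulation={"n_participants": 106, "days": 28},
    label_source="CESDR",
)
artifacts = run_pipeline(config)

reports = {"questionnaire truth": artifacts.questionnaire_report}
if artifacts.diagnosis_report is not None:
    reports["clinician diagnosis"] = artifacts.diagnosis_report
print(render_report(reports, artifacts.ablation))
print("split:", artifacts.manifest["split"])
# Accuracy near or above 90% reflects the generator's well-separated group
# profiles; single-group models trail the all-features model, showing the
# complementary value of fusing sleep, mobility/activity and expression.
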