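"""Score depression questionnaires and map totals to labels and severity bands.

Builds two item-level responses, scores them, and applies the cut-points
(PHQ-9 >= 10, CESD-R >= 13) that define the binary depressed-mood label.
"""

from moodsense import (
    Instrument,
    QuestionnaireRecord,
    Wave,
    cesdr_label,
    phq9_label,
    phq9_severity_band,
    score_instrument,
)

phq9 = QuestionnaireRecord("p001", Instrument.PHQ9, Wave.M1, (2, 1, 2, 1, 1, 2, 1, 1, 1))
cesdr = QuestionnaireRecord("p001", Instrument.CESDR, Wave.M1, (1, 0, 1, 1, 0) * 4)

phq9_total = score_instrument(phq9)
cesdr_total = score_instrument(cesdr)

print(f"PHQ-9 total  : {phq9_total}  (range 0-27)")
print(f"  label      : {phq9_label(phq9_total).value}  (cut-point 10)")
print(f"  severity   : {phq9_severity_band(phq9_total)}")
print(f"CESD-R total : {cesdr_total}  (range 0-60)")
print(f"  label      : {cesdr_label(cesdr_total).value}  (cut-point 13)")
# A PHQ-9 of 12 crosses the cut-point (depressed mood, mild band); the
# CESD-R of 12 sits just below its cut-point, so the two instruments disagree
# for this participant -- exactly the situation dual screening is meant to catch.
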