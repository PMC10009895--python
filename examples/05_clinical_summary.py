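"""Trial summary statistics from the packaged clinical tables.

Computes exposure, time-to-progression, survival, and adverse-event
summaries for the four-subject cohort, plus the qPCR and serology
arithmetic used for individual immune readouts.
"""

import json

from allovax.clinical import (
    QpcrWell,
    SerologySample,
    clinical_summary,
    load_adverse_event_table,
    load_subject_table,
    percent_change_mfi,
    qpcr_relative_expression,
)

subjects = load_subject_table()
aes = load_adverse_event_table()
summary = clinical_summary(subjects, aes, repeat_observations=3)
print(json.dumps(summary, indent=2))

# qPCR: a sample 20 cycles later than its calibrator (ddCt = 20) sits
# below 0.001% of the calibrator's expression
rel = qpcr_relative_expression(
    QpcrWell("SV-BR-1-GM", "HLA-DRB3*01:01", ct_target=45, ct_reference=25),
    QpcrWell("SK-MEL-24", "HLA-DRB3*01:01", ct_target=25, ct_reference=25),
)
print(f"\nqPCR 2^-ddCt percent of calibrator: {rel['percent_of_calibrator']:.2e}%")

# serology: MFI doubling relative to baseline is a +100% change
pc = percent_change_mfi(
    SerologySample("A002", "C5", "1:3", mfi=820.0),
    SerologySample("A002", "baseline", "1:3", mfi=410.0),
)
print(f"anti-cell IgG MFI percent change: {pc:+.0f}%")
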