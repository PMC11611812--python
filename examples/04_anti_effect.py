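"""Quantify task modulation (the ANTI-effect) on a synthetic cohort.

Anti-saccade preparation dilates the pupil more than pro-saccade
preparation.  Per participant the effect is the ANTI-median minus the
PRO-median of each measure; the group null of zero median effect is
tested with the Wilcoxon signed-rank test.
"""

import pandas as pd

from pupilspan import CohortConfig, generate_cohort
from pupilspan import io as pio
from pupilspan.calibration import apply_calibration, fit_calibration
from pupilspan.modulation import anti_effect, anti_effect_table
from pupilspan.pipeline import process_participant

cohort = generate_cohort(CohortConfig(n_participants=40, seed=3,
                                      trials_per_block=20, n_blocks=2))
curve = fit_calibration(cohort.calibration)
rows = []
for pid, sess in cohort.sessions.items():
    trace = apply_calibration(curve, sess.trace)
    _, measures = process_participant(trace, sess.events, pio.RunConfig())
    med = measures.groupby("condition").median(numeric_only=True)
    for cond in med.index:
        rows.append({"id": pid, "condition": cond,
                     **med.loc[cond].to_dict()})
medians = pd.DataFrame(rows).drop(columns=["trial_id"])
effects = anti_effect(medians)
print(anti_effect_table(effects).to_string(index=False))
# Positive median effects with small p-values for the dilation measures
# (and negative for constriction size) reproduce the planted modulation;
# baseline size and onset latency show no task effect.
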