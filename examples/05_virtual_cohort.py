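"""Virtual-patient cohorts and response variability under standard dosing.

Cross-combines the 7 reported 6-MP parameter sets with the 8 synthetic
leukopoiesis sets (56 virtual patients) and the 10 synthetic MCV sets
(70 patients), simulates everyone under 75 mg/day, and summarizes the
spread of the treatment response.
"""

import numpy as np

from sixmp import (
    DoseRegimen,
    cohort_summary,
    load_erythro_fixtures,
    load_leuko_fixtures,
    load_table5,
    make_virtual_cohort,
    simulate_cohort,
)

regimen = DoseRegimen.daily(75, 112)

leuko_cohort = make_virtual_cohort(load_table5(), load_leuko_fixtures())
summary = cohort_summary(simulate_cohort(leuko_cohort, regimen, horizon_days=112.0))
L_mean, L_sd = summary.mean["L"], summary.sd["L"]
print(f"leukocyte cohort: {summary.size} virtual patients (7 PK x 8 marrow)")
print(f"  day 112 leukocytes: {L_mean[-1] / 1e9:.2f} +/- {L_sd[-1] / 1e9:.2f} e9/L "
      "(mean +/- SD across patients)")
print(f"  spread peaks at day {summary.times[np.argmax(L_sd)]:.0f} — the first "
      "treatment transient desynchronizes the cohort before feedback re-equilibrates it")

mcv_cohort = make_virtual_cohort(load_table5(), load_erythro_fixtures())
summary2 = cohort_summary(simulate_cohort(mcv_cohort, regimen, horizon_days=112.0))
m_mean, m_sd = summary2.mean["dmcv"], summary2.sd["dmcv"]
print(f"\nMCV cohort: {summary2.size} virtual patients (7 PK x 10 erythroid)")
print(f"  day 112 MCV shift: {m_mean[-1]:.2f} +/- {m_sd[-1]:.2f} fL")
print("  the spread keeps growing through the 4-month window — MCV is the slow marker")
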