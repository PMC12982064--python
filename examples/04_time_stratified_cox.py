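"""Two-interval (day-7 time-stratified) Cox model for trajectory classes.

Follow-up is episode-split at day 7; one Cox model with an
interval-stratified baseline hazard estimates a separate hazard ratio for
each trajectory class in days 0-7 and after day 7, adjusted for
covariates.  The Schoenfeld test compares the unstratified model (whose
single coefficient misrepresents an effect that emerges only after day 7)
with the two-interval model; at a late hazard ratio near 1.5 that test
has limited power, so the landmark log-rank contrast below is the clearer
signature of the delayed effect.
"""

import numpy as np

import tygdyn as tg

cohort = tg.generate_cohort(tg.SyntheticCohortConfig(n_patients=4000, seed=11))
df = cohort.outcomes.merge(cohort.truth[["patient_id", "true_class"]], on="patient_id")
df["trajectory"] = np.array(["LSI", "MI", "PH"])[df["true_class"]]

res = tg.time_stratified_model(
    df, "trajectory", covariates=["age", "male", "dm", "htn", "sofa", "mv"]
)
print(res.table.round(3).to_string(index=False))
# Early-interval hazard ratios hover around 1 (no class effect before
# day 7 in the generative model); late-interval MI and PH approach their
# generating values of 1.48 and 1.51 versus the LSI reference.

print()
print("PH test, unstratified model (exposure block): p = %.4f"
      % res.unstratified_ph_test.table.loc["BLOCK", "p"])
print("PH test, two-interval model  (exposure block): p = %.4f"
      % res.ph_test.table.loc["BLOCK", "p"])

lr_early = tg.km_logrank(df, "trajectory", window=(0.0, 7.0))
lr_late = tg.km_logrank(df, "trajectory", window=(7.0, None))
print()
print(f"landmark log-rank, days 0-7: chi2={lr_early.chi2:.2f}, p={lr_early.p:.3f}")
print(f"landmark log-rank, >7 days : chi2={lr_late.chi2:.2f}, p={lr_late.p:.2g}")
# The curves barely separate in the first week but diverge afterwards.
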