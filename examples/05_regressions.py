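"""Hierarchical and stepwise regressions predicting MCI status.

MCI status (0/1) is fitted as a linear probability model: demographics
enter in step 1, clinical diagnoses in step 2, so the step-2 increment
shows what the clinical variables add over demographics.  The stepwise
model then selects the strongest joint predictors.
"""

from gwmci import cohort_to_frame, generate_fixture, hierarchical_regression, stepwise_regression

frame = cohort_to_frame(generate_fixture())
frame["mci_status"] = (frame["planted_label"] == "MCI").astype(float)
frame["race_nonwhite"] = (frame["race"] != "caucasian").astype(float)

steps = hierarchical_regression(
    frame["mci_status"],
    [["race_nonwhite", "rank_enlisted"],
     ["ptsd_current", "mdd_current", "etoh_history"]],
    frame,
)
for s in steps:
    print(f"step {s.step_index}: R2 = {s.fit.r2:.3f} (delta = {s.delta_r2:.3f})")
    for term in s.fit.terms:
        print(f"    {term:<16} beta* = {s.fit.std_beta[term]:+.2f}  "
              f"t = {s.fit.t[term]:+.2f}  p = {s.fit.p[term]:.4f}")

final, order = stepwise_regression(
    frame["mci_status"],
    ["race_nonwhite", "rank_enlisted", "ptsd_current", "mdd_current", "etoh_history"],
    frame,
)
print("\nstepwise entry order:", order)

# Current PTSD remains associated with MCI status after race and rank
# are controlled (positive step-2 standardized beta); MDD and alcohol
# history typically add little once PTSD is in the model.
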