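"""Survival analysis of a calibrated synthetic cohort.

Generates a cohort with the study's statistical structure (GARD median
~39, near-uniform EQD2 ~70 Gy, ~94% OS at 36 months), then runs the
analysis sequence: continuous Cox, time-dependent AUC, and the maximally
selected GARD cut-point with a selection-aware permutation p-value.
"""

import numpy as np

import gardkit as gk

cohort = gk.generate_cohort(gk.CohortSpec(n=191, seed=42))
df = gk.annotate_gard(cohort.table)

km = gk.km_estimate(df["time_months"], df["event"])
print(f"n = {len(df)}, events = {km.n_events}, "
      f"OS(36) = {km.survival_at(36):.1%}, OS(60) = {km.survival_at(60):.1%}")
print(f"GARD median = {df['gard'].median():.1f}, "
      f"IQR = {np.subtract(*np.percentile(df['gard'], [75, 25])):.1f}")

cox = gk.fit_cox(df, ["gard"])
print(f"Cox per GARD unit: HR = {cox.hazard_ratios['gard']:.3f} "
      f"({cox.ci_lower['gard']:.3f}, {cox.ci_upper['gard']:.3f}), "
      f"p = {cox.p_values['gard']:.3g}")

auc = gk.td_auc_ipcw(df.assign(risk=-df["gard"]), "risk", horizon=36.0)
print(f"time-dependent AUC of GARD for 36-month OS: {auc:.3f}")

cut = gk.optimal_cutpoint(df, "gard", n_permutations=1000, seed=42)
print(f"maximally selected cut-point: GARD = {cut.cutpoint:.1f} "
      f"(|Z| = {abs(cut.z):.2f}, naive p = {cut.p_naive:.2g}, "
      f"selection-adjusted p = {cut.p_adjusted:.3f})")
# Higher GARD (more predicted treatment effect) is protective: HR < 1.
# The adjusted p accounts for the post hoc choice of the cut.
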