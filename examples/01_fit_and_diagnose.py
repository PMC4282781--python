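"""Fit a standard Cox model and inspect its proportional-hazards diagnostics.

Builds a synthetic HIV-prevention-style cohort (821 subjects, one binary risk
covariate, three censoring reasons), fits the Cox model assuming independent
censoring, and prints the coefficient table plus a summary of the Schoenfeld
residuals. The coefficient is a log hazard ratio: exp(coef) multiplies the
failure hazard for high-risk subjects. Residuals centred near zero with no
time trend support the proportional-hazards form of the fitted model.
"""

import numpy as np

from coxsens import fit_cox, make_hivlike, schoenfeld_residuals

cohort = make_hivlike(seed=0)
print(f"cohort: n={cohort.n}, events={cohort.n_events}, "
      f"censored before horizon={int(cohort.imputable_mask.sum())}")

fit = fit_cox(cohort)
print("\nindependent-censoring Cox fit (log hazard ratios):")
print(fit.summary().round(3).to_string())

res = schoenfeld_residuals(fit, cohort)
early = res[res.time <= 1.5]["highrisk"]
late = res[res.time > 1.5]["highrisk"]
print(f"\nSchoenfeld residuals: mean {res['highrisk'].mean():.4f} "
      f"(early {early.mean():.3f}, late {late.mean():.3f})")
print("a near-zero mean with no early/late drift supports proportional hazards")
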