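"""Sweep the step-change sensitivity parameter gamma over a grid.

gamma is the log hazard ratio comparing a subject's post-censoring to
pre-censoring failure hazard: gamma = 0 is independent censoring, positive
gamma means censored subjects fail faster than the model for the uncensored
implies. For each gamma the censored failure times are multiply imputed
(m = 40 bootstrap refits) and the pooled Cox estimates printed, framed by
the two extreme single-imputation analyses ("censored = never fails" and
"censored = immediate failure").
"""

from coxsens import GammaSpec, export_curves, make_hivlike, run_gamma_grid

cohort = make_hivlike(seed=0)
result = run_gamma_grid(
    cohort,
    GammaSpec.constant(0.0),
    grid=[-3, -2, -1, 0, 1, 2, 3, 4, 5],
    m=40,
    master_seed=2024,
)

curves = export_curves(result)
print(curves.round(3).to_string(index=False))
print(
    "\nreading the table: the 'ic' row is the usual analysis; rows -3..5 show"
    "\nhow the log hazard ratio and its 95% CI move as the independent-"
    "\ncensoring assumption is relaxed; 'never'/'immediate' bound the range."
    "\nShrinking CIs at large gamma reflect the extra (assumed) information"
    "\nthat censoring predicts failure."
)
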