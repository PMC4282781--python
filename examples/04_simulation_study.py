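"""Bias and coverage of IC vs MI analyses under informative censoring.

A fast profile of the simulation study: datasets of 1000 subjects with a
three-level categorical covariate, exponential failure and dropout times and
a 3-year horizon. For each gamma the standard independent-censoring analysis
(IC) and the MI procedure run with the correct gamma (MI) are compared
against the large-sample truth. Expect: both near-unbiased at gamma = 0; at
gamma = 3 the IC estimator is badly biased with degraded coverage while MI
stays near-nominal.
"""

from coxsens import SimConfig, run_study

config = SimConfig(
    reps=100, mi_reps=50, m=10, gamma_grid=(0.0, 3.0),
    truth_n=200_000, seed=7,
)
summary = run_study(config)

print(summary.truth.round(4).to_string(index=False))
print()
print(summary.table.round(3).to_string(index=False))
print(
    "\nbias is mean(estimate) - truth with its Monte Carlo SE; coverage is"
    "\nthe fraction of 95% CIs containing the truth (nominal 0.95)."
)
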