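# Methods

## Model and procedure

`coxsens` relaxes the independent-censoring assumption of the Cox model by
a *pattern-mixture-style* device: the conditional failure hazard of a
censored subject, after their censoring time, is the model hazard
multiplied by exp(γᵢ). γᵢ is a per-subject sensitivity parameter — a log
hazard ratio comparing post- to pre-censoring risk — about which the
observed data carry no information. The analysis therefore never estimates
γ; it reports how the estimates of interest vary as γ is varied.

The estimation engine is multiple imputation of the censored failure
times:

1. **Proper imputation via the bootstrap.** For each of the m imputations
   the full sample is resampled with replacement (optionally within
   user-declared sampling strata, e.g. treatment arms) and the Cox model
   refitted, including its Breslow cumulative baseline hazard Ĥ₀ₛ. This
   propagates the uncertainty of both β and the baseline, which a
   semi-parametric model cannot propagate through a parametric posterior.
   A refit that fails (no events, collinear resample) is redrawn from the
   same stream, capped at 25 attempts.
2. **Inverse-transform draw on a step cumulative hazard.** For a subject
   censored at C with resolved γᵢ, draw U ~ Unif(0,1) and set
   x = −log(U)/exp(Zβ̂ + γᵢ). The imputed gap is
   A = inf{a > 0 : Ĥ₀ₛ(C+a) − Ĥ₀ₛ(C) ≥ x}. Because Ĥ₀ₛ is a step
   function, A lands on an observed event time of the bootstrap refit;
   when the remaining hazard mass on (C, τ] is below x the subject is
   imputed censored at the horizon τ. Jumps at exactly t = C are excluded,
   so imputed times strictly exceed censoring times (this is enforced
   index-wise, which also guards the γ → +∞ regime where x underflows
   below the floating-point resolution of Ĥ₀ₛ(C)).
3. **Analysis and pooling.** The ordinary Cox model is fitted to each
   completed dataset and the estimates combined by Rubin's rules:
   pooled variance W + (1 + 1/m)B, normal-theory 95% intervals
   (±1.96·SE). The Barnard-Rubin-free classical df is exposed on
   `PooledEstimate.df` but not used by default, matching the convention
   that all pooled intervals in the reproduced analyses are ±1.96 SE.

Administratively censored subjects (time ≥ τ) are never imputed: their
censoring is caused by the calendar, so γᵢ = 0 is safe, and any imputed
time would be re-censored at τ anyway. τ is a required user input rather
than inferred, because the appropriate horizon is a design quantity
(typically beyond the maximum observed time).

### Sensitivity curves and anchors

`run_gamma_grid` generates the m bootstrap refits and the (n × m) uniform
matrix **once** per master seed and reuses them at every grid point
(common random numbers), so differences along the curve reflect γ alone
and single grid points rerun identically outside the grid. Both the
bootstrap draws and the uniforms are reused; reusing only the former would
leave residual imputation noise in the curves.

The curves are framed by three anchors: the standard independent-censoring
fit; "censored = never fails" (all in-scope censored times set to τ),
which is the exact γ → −∞ limit of the MI procedure; and "censored =
immediate failure" (all in-scope censoring indicators set to 1), which the
γ → +∞ limit only approaches because finite γ never imputes a zero gap —
the +∞ limit imputes the *first event time after* C. The immediate anchor
is therefore a distinct code path, not a large-γ run. For all-subjects
analyses the anchor scope is every censored record, administrative
included; reason-scoped analyses restrict both anchors to the designated
reason.

## Cox engine

The partial likelihood is maximised by Newton iteration with step-halving,
relative log-likelihood tolerance 1e-9, at most 100 iterations, covariance
from the inverse observed information. Ties are handled with the
**Breslow** approximation in the likelihood, the baseline estimator and
the Schoenfeld residuals. This choice is structural, not incidental:
imputed failure times coincide with observed event times by construction,
so imputed datasets are heavily tied, and the baseline used for inversion
must be the one implied by the fitted likelihood. (The general-purpose
survival packages default to Efron ties and are used in the test suite as
independent cross-checks on untied data, where the two conventions agree.)
Covariates are centred internally for numerical stability; the Breslow
baseline is computed on the uncentred linear predictor, so adding a
constant to every linear predictor rescales all jumps by exp(−c), as it
must. Monotone-likelihood (separation) data yield a large finite
coefficient under the stopping rule, as in standard Cox software;
coefficients beyond ±50 raise an error.

Schoenfeld residuals (observed covariate minus risk-set weighted mean at
each event) are exported as a table for proportional-hazards diagnostics of
both the observed-data model and each imputed-data analysis model; the two
models are formally incompatible, so residual checks on both sides are part
of the intended workflow.

## Synthetic data

No real trial data ship with the package. Two generators stand in:

- **Simulation-study generator** (`coxsens.simulate`): n = 1000 subjects,
  categorical covariate Z with P(Z = 0,1,2) = (0.5, 0.3, 0.2), failure
  T ~ Exp(λ_Z) with λ = (0.03, 0.05, 0.09) per year, dropout C ~ Exp(0.3),
  administrative censoring at τ = 3 years. These rates produce roughly 9%
  events, 57% dropout and 34% administrative censoring — heavy censoring,
  the regime where the independent-censoring assumption matters most. The
  estimand under γ is defined by a large-sample oracle: failure times
  completed after censoring with rate λ_Z·exp(γ), censored at 3 years, and
  a Cox model fitted to one very large dataset (default 10⁶ subjects; the
  tests use 2×10⁵ and fold the oracle's SE into the Monte Carlo SEs). At
  γ = 0 the truth is the closed form (log(5/3), log(3)) with zero oracle
  uncertainty. The marginal survival function of the completed failure
  time has a closed form for exponential components
  (`stepchange_survival`), used to cross-check the augmentation.
- **`hivlike` fixture** (`coxsens.fixtures`): a synthetic 821-subject
  cohort with one binary risk covariate (log HR 0.7) and three censoring
  reasons. Baseline failure rate 0.02050 and dropout rate 0.16254 per year
  were solved analytically (once) so the expected outcome mix is 7%
  events, 56% administrative, 37% dropout (split 20% "pregnancy" / 17%
  "ltfu"), emulating published trial summary proportions.

What these generators do **not** emulate: covariate-dependent censoring,
non-exponential hazards, staggered entry, multiple covariates with
confounding. Passing tests therefore demonstrate the procedure's
correctness under its own model and its frequentist properties in an
idealised heavy-censoring regime, not robustness to misspecification.

## Study design used by the validation runs

The simulation driver analyses each replicate with (a) the standard IC Cox
fit and (b) the MI procedure run with the *correct* γ and m = 10. Observed
data replicates are generated from a per-replicate substream, so they are
bit-identical across γ — only the estimand and the imputation γ change.
Bias is mean(estimate) − truth; its MCSE combines the empirical SD of the
estimates with the truth oracle's SE. Coverage is the fraction of nominal
95% intervals containing the truth. Problem sizes in the shipped runs:
1000 replicates for the IC arm, 250 for the MI arm (the MI arm is the
expensive one; 250 replicates give bias MCSEs around 0.01–0.02, which the
test tolerances account for), truth oracles of 2×10⁵ (tests) or 10⁶
(acceptance script). Per-replicate fit failures are excluded and counted;
more than 1% aborts the run (none occur under the default conditions).

## Numerical and design choices

- **U strictly inside (0,1):** exact zeros from the generator (probability
  2⁻⁵³) are replaced by the smallest positive double; x is computed as
  −log(U)·exp(−lp) to avoid overflow at extreme γ.
- **Seeding:** a single master seed spawns one substream per bootstrap
  index plus one for the uniform matrix; the simulation driver derives
  dataset, truth and MI seeds from disjoint spawn keys. All results are
  bit-reproducible from the seed.
- **Grid failures are non-fatal:** a grid point whose pooled fit fails is
  recorded and skipped; curves render from the surviving points.
- **Stratified baselines:** a stratum with no events gets an empty step
  function — its censored subjects are always imputed as censored at τ —
  and a stratum label missing from a bootstrap refit is treated the same
  way, with a warning.

## Known limitations

Right censoring only; no time-dependent covariates or coefficients; no
time-varying γ(t); γ elicitation is out of scope (the package evaluates
user-supplied γ, it does not help choose them); no parametric
(e.g. Weibull) imputation variant; missing covariates are a hard error.
The normal-theory pooled intervals are slightly anti-conservative at very
small m.
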