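"""Small synthetic datasets for examples, tests and the CLI ``fixture`` command.

Three kinds:

``tiny``
    six hand-checkable rows with one binary covariate; used wherever a result
    must be verified against a pencil-and-paper computation.
``hivlike``
    a synthetic cohort of 821 women emulating an HIV-prevention trial:
    competing exponential failure and dropout hazards with administrative
    censoring at 3 years, calibrated so the expected outcome mix is 7%
    events, 20% censored for pregnancy, 17% lost to follow-up and 56%
    administratively censored, with one binary risk covariate (log hazard
    ratio 0.7). This is a stand-in for trial data that are not public.
``sim5``
    one draw from the simulation study's generator (n = 1000, categorical
    covariate with three levels); see :mod:`coxsens.simulate`.
"""

from __future__ import annotations

import numpy as np

from .data import SurvivalDataset
from .simulate import SimConfig, generate_dataset

__all__ = ["make_tiny", "make_hivlike", "make_sim5", "make_fixture"]

# hivlike generator rates: solved so that with z ~ Bernoulli(0.5), failure
# hazard lam0*exp(0.7 z), dropout hazard mu, horizon 3y, the expected outcome
# proportions are P(event)=0.07 and P(admin)=0.56 exactly
HIVLIKE_LAMBDA0 = 0.02050391
HIVLIKE_MU = 0.16253797
HIVLIKE_BETA = 0.7
HIVLIKE_N = 821
PREGNANCY_SHARE = 0.20 / 0.37  # pregnancy vs ltfu split among dropouts


def make_tiny() -> SurvivalDataset:
    """Six subjects, one binary covariate, fixed times; hand-checkable."""
    return SurvivalDataset(
        time=[0.5, 1.0, 1.5, 2.0, 2.4, 3.0],
        event=[1, 0, 1, 1, 0, 0],
        covariates=np.array([[0.0], [1.0], [1.0], [0.0], [1.0], [0.0]]),
        covariate_names=["z"],
        tau=3.0,
        reason=[None, "ltfu", None, None, "pregnancy", "admin"],
    )


def make_hivlike(seed: int = 0, n: int = HIVLIKE_N) -> SurvivalDataset:
    """Synthetic HIV-prevention-trial-like cohort with three censoring reasons."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    tau = 3.0
    z = rng.integers(0, 2, size=n).astype(float)
    T = rng.exponential(1.0 / (HIVLIKE_LAMBDA0 * np.exp(HIVLIKE_BETA * z)))
    C = rng.exponential(1.0 / HIVLIKE_MU, size=n)
    Y = np.minimum(np.minimum(T, C), tau)
    delta = ((T < C) & (T < tau)).astype(np.int8)
    reason = np.full(n, None, dtype=object)
    dropout = (delta == 0) & (C < T) & (C < tau)
    pregnant = dropout & (rng.random(n) < PREGNANCY_SHARE)
    reason[pregnant] = "pregnancy"
    reason[dropout & ~pregnant] = "ltfu"
    reason[(delta == 0) & ~dropout] = "admin"
    return SurvivalDataset(
        time=Y,
        event=delta,
        covariates=z[:, None],
        covariate_names=["highrisk"],
        tau=tau,
        reason=reason,
    )


def make_sim5(seed: int = 0, n: int = 1000) -> SurvivalDataset:
    """One dataset from the simulation-study generator."""
    config = SimConfig(n=n, seed=seed)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    return generate_dataset(config, rng)


def make_fixture(kind: str, seed: int = 0) -> SurvivalDataset:
    """Dispatch by fixture name: ``tiny``, ``hivlike`` or ``sim5``."""
    if kind == "tiny":
        return make_tiny()
    if kind == "hivlike":
        return make_hivlike(seed)
    if kind == "sim5":
        return make_sim5(seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
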