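"""Bootstrap multiple imputation of censored failure times under a step-change hazard.

For each of the ``m`` imputations the whole sample is resampled with
replacement and the Cox model (coefficients and Breslow baseline) refitted on
the resample — "proper" imputation, propagating the uncertainty in the
imputation model. A censored subject with censoring time ``C`` then has a
failure time drawn from the Cox model whose cumulative baseline hazard is the
refitted baseline shifted to start at ``C`` and whose linear predictor is
``Z beta + gamma``: censoring multiplies the subject's failure hazard by
``exp(gamma)`` from the censoring time onward. Draws use inverse-transform
sampling; because the Breslow baseline is a step function, imputed failure
times always coincide with observed event times of the bootstrap refit, or
are censored at the follow-up horizon ``tau`` when the step function's mass
beyond ``C`` is exhausted first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxFit, CoxFitError, StepCumHaz, fit_cox
from .data import GammaSpec, SurvivalDataset, resolve_gamma

__all__ = [
    "BootstrapDraw",
    "ImputationDraw",
    "ImputedDataset",
    "bootstrap_draw",
    "prepare_draws",
    "invert_step_cumhaz",
    "impute_record",
    "impute_with",
    "create_imputed_datasets",
    "extreme_never",
    "extreme_immediate",
]

logger = logging.getLogger(__name__)

MAX_REDRAWS = 25


@dataclass
class BootstrapDraw:
    """One resampled-and-refitted imputation model."""

    index: int
    beta: np.ndarray
    baseline: dict[object, StepCumHaz]
    sample_idx: np.ndarray
    n_redraws: int = 0

    @classmethod
    def from_fit(cls, index: int, fit: CoxFit, sample_idx: np.ndarray, n_redraws: int = 0):
        return cls(index, fit.beta, fit.baseline, sample_idx, n_redraws)


@dataclass
class ImputationDraw:
    """Per-record imputation intermediates (audit trail for one draw)."""

    record_id: object
    U: float
    target: float
    gap: float | None          # None means beyond-horizon
    imputed_time: float
    imputed_event: int


@dataclass
class ImputedDataset:
    """A completed dataset: observed rows unchanged, censored rows imputed."""

    dataset: SurvivalDataset
    draw_index: int
    imputed: np.ndarray        # boolean mask of rows that were imputed
    source_time: np.ndarray    # pre-imputation follow-up times


def bootstrap_draw(
    dataset: SurvivalDataset,
    rng: np.random.Generator,
    sampling_strata: np.ndarray | None = None,
    index: int = 0,
) -> BootstrapDraw:
    """Resample the dataset with replacement and refit the Cox model.

    Resampling is from the whole sample, or within each level of
    ``sampling_strata`` (per-record labels, e.g. treatment arm) so each
    stratum keeps its original size. A refit failure (for example a covariate
    level absent from the resample) triggers a redraw from the same RNG
    stream, up to 25 attempts.
    """
    n = dataset.n
    for attempt in range(MAX_REDRAWS + 1):
        if sampling_strata is None:
            idx = rng.integers(0, n, size=n)
        else:
            labels = np.asarray(sampling_strata)
            idx = np.empty(n, dtype=np.intp)
            for label in pd.unique(labels):
                rows = np.flatnonzero(labels == label)
                idx[rows] = rows[rng.integers(0, rows.size, size=rows.size)]
        resample = SurvivalDataset(
            time=dataset.time[idx],
            event=dataset.event[idx],
            covariates=dataset.covariates[idx],
            covariate_names=dataset.covariate_names,
            tau=dataset.tau,
            stratum=dataset.stratum[idx],
            reason=dataset.reason[idx],
            ids=dataset.ids[idx],
        )
        try:
            fit = fit_cox(resample)
        except CoxFitError as exc:
            logger.warning("bootstrap refit %d failed (attempt %d): %s", index, attempt + 1, exc)
            continue
        return BootstrapDraw.from_fit(index, fit, idx, n_redraws=attempt)
    raise CoxFitError(f"bootstrap refit failed after {MAX_REDRAWS} redraws")


def prepare_draws(
    dataset: SurvivalDataset,
    m: int,
    master_seed: int,
    sampling_strata: np.ndarray | None = None,
) -> tuple[list[BootstrapDraw], np.ndarray]:
    """Generate the m bootstrap refits and the (n, m) uniform matrix.

    These are the reusable randomness of the procedure: for a sensitivity
    analysis over several gamma values the same draws and the same uniforms
    are used at every grid point (common random numbers), so result curves
    are smooth in gamma and differences across gamma reflect gamma alone.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(m + 1)
    draws = [
        bootstrap_draw(dataset, np.random.Generator(np.random.PCG64(children[j])),
                       sampling_strata=sampling_strata, index=j)
        for j in range(m)
    ]
    u_rng = np.random.Generator(np.random.PCG64(children[m]))
    U = u_rng.random((dataset.n, m))
    # U must lie strictly inside (0, 1): U -> 0+ is harmless (imputes beyond
    # the horizon) but U = 0 exactly would give an infinite target
    tiny = np.finfo(float).tiny
    U[U == 0.0] = tiny
    return draws, U


def invert_step_cumhaz(H: StepCumHaz, C: float, x: float, tau: float) -> float | None:
    """Invert a step cumulative hazard: smallest gap A > 0 with H(C+A) - H(C) >= x.

    Returns ``A = t_k - C`` for the smallest jump time ``t_k > C`` whose
    accumulated increment since ``C`` reaches ``x``, provided ``t_k <= tau``;
    returns None ("beyond-horizon") when the increment over ``(C, tau]``
    never reaches ``x``. Jumps at exactly ``t = C`` do not count towards the
    increment, so the gap is always strictly positive.
    """
    if x <= 0:
        raise ValueError(f"target x must be positive, got {x}")
    if H.n_jumps == 0:
        return None
    base = H.at(C)
    k = int(np.searchsorted(H.values, base + x, side="left"))
    # guard against x underflowing below the float resolution of H(C): the
    # gap must always be strictly positive, so never land on a jump <= C
    k = max(k, int(np.searchsorted(H.times, C, side="right")))
    if k >= H.n_jumps or H.times[k] > tau:
        return None
    return float(H.times[k] - C)


def impute_record(
    dataset: SurvivalDataset,
    index: int,
    draw: BootstrapDraw,
    gamma_i: float,
    rng: np.random.Generator | None = None,
    U: float | None = None,
) -> ImputationDraw:
    """Impute a failure time for one censored record under one bootstrap draw.

    Draws ``U ~ Unif(0,1)`` (or uses the supplied ``U``), forms the target
    ``x = -log(U) / exp(Z beta + gamma_i)`` and inverts the record's stratum
    baseline shifted to its censoring time. Beyond-horizon draws are censored
    at ``tau``.
    """
    if dataset.event[index] != 0 or dataset.time[index] >= dataset.tau:
        raise ValueError(f"record {index} is not imputable (event or administratively censored)")
    if U is None:
        if rng is None:
            raise ValueError("provide either U or rng")
        U = float(rng.random())
        if U == 0.0:
            U = np.finfo(float).tiny
    if not 0.0 < U < 1.0:
        raise ValueError(f"U must lie strictly in (0,1), got {U}")
    C = float(dataset.time[index])
    lp = float(dataset.covariates[index] @ draw.beta) + gamma_i
    x = -np.log(U) * np.exp(-lp)
    label = dataset.stratum[index]
    H = draw.baseline.get(label)
    if H is None:
        logger.warning("stratum %r absent from bootstrap baseline; censoring at tau", label)
        H = StepCumHaz.empty()
    gap = invert_step_cumhaz(H, C, x, dataset.tau)
    if gap is None:
        return ImputationDraw(dataset.ids[index], U, x, None, float(dataset.tau), 0)
    return ImputationDraw(dataset.ids[index], U, x, gap, C + gap, 1)


def _impute_columns(
    dataset: SurvivalDataset,
    draw: BootstrapDraw,
    gammas: np.ndarray,
    U_col: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised imputation of all imputable rows for one bootstrap draw."""
    time = dataset.time.copy()
    event = dataset.event.copy()
    mask = dataset.imputable_mask & np.isfinite(gammas)
    for label in pd.unique(dataset.stratum[mask]):
        rows = np.flatnonzero(mask & (dataset.stratum == label))
        H = draw.baseline.get(label)
        if H is None or H.n_jumps == 0:
            if H is None:
                logger.warning("stratum %r absent from bootstrap baseline; censoring at tau", label)
            time[rows] = dataset.tau
            event[rows] = 0
            continue
        C = dataset.time[rows]
        lp = dataset.covariates[rows] @ draw.beta + gammas[rows]
        x = -np.log(U_col[rows]) * np.exp(-lp)
        target = H.at(C) + x
        k = np.searchsorted(H.values, target, side="left")
        # never land on a jump <= C even when x underflows (gap must be > 0)
        k = np.maximum(k, np.searchsorted(H.times, C, side="right"))
        within = k < H.n_jumps
        kc = np.minimum(k, H.n_jumps - 1)
        within &= H.times[kc] <= dataset.tau
        time[rows] = np.where(within, H.times[kc], dataset.tau)
        event[rows] = within.astype(np.int8)
    return time, event, mask


def impute_with(
    dataset: SurvivalDataset,
    draws: list[BootstrapDraw],
    U: np.ndarray,
    gammas: np.ndarray,
) -> list[ImputedDataset]:
    """Build one imputed dataset per bootstrap draw from prepared randomness.

    ``gammas`` is the resolved per-record gamma array (NaN = skip). Rows that
    are events or administratively censored are carried over unchanged.
    """
    out = []
    for j, draw in enumerate(draws):
        time, event, mask = _impute_columns(dataset, draw, gammas, U[:, j])
        completed = SurvivalDataset(
            time=time,
            event=event,
            covariates=dataset.covariates,
            covariate_names=dataset.covariate_names,
            tau=dataset.tau,
            stratum=dataset.stratum,
            reason=dataset.reason,
            ids=dataset.ids,
        )
        out.append(ImputedDataset(completed, j, mask, dataset.time.copy()))
    return out


def create_imputed_datasets(
    dataset: SurvivalDataset,
    gamma_spec: GammaSpec,
    m: int,
    master_seed: int,
    sampling_strata: np.ndarray | None = None,
) -> tuple[list[ImputedDataset], list[BootstrapDraw]]:
    """Create ``m`` imputed datasets under the given gamma specification.

    One bootstrap refit per imputation; every censored record with
    ``time < tau`` is imputed, events and administratively censored records
    are untouched. Fully reproducible from ``master_seed``.
    """
    if m < 2:
        raise ValueError(f"m must be at least 2, got {m}")
    gammas = resolve_gamma(gamma_spec, dataset)
    draws, U = prepare_draws(dataset, m, master_seed, sampling_strata)
    return impute_with(dataset, draws, U, gammas), draws


# ---------------------------------------------------------------------------
# Extreme single-imputation analyses
# ---------------------------------------------------------------------------

def extreme_never(
    dataset: SurvivalDataset, scope: np.ndarray | None = None
) -> SurvivalDataset:
    """'Censored = never fails': censoring times in scope pushed to the horizon.

    A single-"imputation" analysis: every censored record in scope has its
    time set to ``tau`` (event stays 0). Default scope is all censored
    records.
    """
    out = dataset.copy()
    mask = dataset.censored_mask if scope is None else (dataset.censored_mask & scope)
    out.time[mask] = dataset.tau
    return out


def extreme_immediate(
    dataset: SurvivalDataset, scope: np.ndarray | None = None
) -> SurvivalDataset:
    """'Censored = immediate failure': censoring indicators in scope set to 1.

    The opposite extreme: every censored record in scope becomes an event at
    its censoring time. Default scope is all censored records.
    """
    out = dataset.copy()
    mask = dataset.censored_mask if scope is None else (dataset.censored_mask & scope)
    out.event[mask] = 1
    return out
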