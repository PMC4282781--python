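"""Survival data container, delimited-text I/O and per-subject sensitivity parameters.

The central object is :class:`SurvivalDataset`: one row per subject with
follow-up time ``Y = min(T, C)``, event indicator ``delta``, a fixed-width
covariate matrix ``Z`` (categorical covariates pre-expanded to indicator
columns), an optional stratum label ``S``, an optional censoring-reason label
``W``, and the end-of-follow-up horizon ``tau``.

:class:`GammaSpec` describes the departure from independent censoring: the
per-subject step-change parameter ``gamma_i`` is the log hazard ratio
comparing a subject's post-censoring to pre-censoring hazard of failure.
``gamma_i = 0`` for everyone recovers the usual independent-censoring
analysis; the data carry no information about these parameters, so they are
supplied by the analyst, optionally varying by censoring reason or by an
arbitrary per-record rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "GammaSpec",
    "ValidationError",
    "ConfigError",
    "read_dataset",
    "write_dataset",
    "resolve_gamma",
    "expand_categorical",
]

DEFAULT_STRATUM = ""


class ValidationError(ValueError):
    """Raised when a dataset violates its invariants (bad time/event values)."""


class ConfigError(ValueError):
    """Raised for malformed column mappings or gamma specifications."""


@dataclass
class SurvivalDataset:
    """Right-censored survival data with a fixed follow-up horizon.

    Parameters
    ----------
    time : array of shape (n,)
        Observed follow-up times ``Y_i = min(T_i, C_i)``; nonnegative, in the
        same unit throughout (years in the motivating application) and never
        exceeding ``tau``.
    event : array of shape (n,)
        Event indicators ``delta_i`` in {0, 1}; 1 means the failure time was
        observed, 0 means the subject was censored at ``time``.
    covariates : array of shape (n, p)
        Regression covariate matrix ``Z``; categorical covariates must
        already be expanded to indicator columns.
    covariate_names : sequence of str, length p
    tau : float
        End of the follow-up horizon. Records censored at ``time >= tau`` are
        administratively censored and are never imputed.
    stratum : array of shape (n,), optional
        Baseline-hazard stratum labels; a single default stratum if omitted.
    reason : array of shape (n,), optional
        Censoring-reason labels (ignored for event records).
    ids : array of shape (n,), optional
        Opaque per-record identifiers; defaults to the row index.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]
    tau: float
    stratum: np.ndarray | None = None
    reason: np.ndarray | None = None
    ids: np.ndarray | None = None
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.time.shape[0]:
            self.covariates = self.covariates.T
        n = self.n
        if self.stratum is None:
            self.stratum = np.full(n, DEFAULT_STRATUM, dtype=object)
        else:
            self.stratum = np.asarray(self.stratum, dtype=object)
        if self.reason is None:
            self.reason = np.full(n, None, dtype=object)
        else:
            self.reason = np.asarray(self.reason, dtype=object)
        if self.ids is None:
            self.ids = np.arange(n, dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
        self.covariate_names = list(self.covariate_names)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.tau <= 0:
            raise ValidationError(f"tau must be positive, got {self.tau}")
        bad = np.flatnonzero(~np.isfinite(self.time) | (self.time < 0))
        if bad.size:
            raise ValidationError(f"negative or non-finite time at row {bad[0]}")
        bad = np.flatnonzero(~np.isin(self.event, (0, 1)))
        if bad.size:
            raise ValidationError(
                f"event indicator must be 0 or 1, got {self.event[bad[0]]!r} at row {bad[0]}"
            )
        self.event = self.event.astype(np.int8)
        bad = np.flatnonzero(self.time > self.tau)
        if bad.size:
            raise ValidationError(
                f"time {self.time[bad[0]]} exceeds horizon tau={self.tau} at row {bad[0]}"
            )
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValidationError(
                "covariate_names length does not match covariate matrix width"
            )
        if not np.all(np.isfinite(self.covariates)):
            bad = np.flatnonzero(~np.isfinite(self.covariates).all(axis=1))
            raise ValidationError(f"missing or non-finite covariate at row {bad[0]}")

    # -- conveniences ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def censored_mask(self) -> np.ndarray:
        return self.event == 0

    @property
    def admin_censored_mask(self) -> np.ndarray:
        """Censored at (or beyond) the horizon: safely independent censoring."""
        return (self.event == 0) & (self.time >= self.tau)

    @property
    def imputable_mask(self) -> np.ndarray:
        """Censored strictly before the horizon: candidates for imputation."""
        return (self.event == 0) & (self.time < self.tau)

    def copy(self) -> "SurvivalDataset":
        return replace(
            self,
            time=self.time.copy(),
            event=self.event.copy(),
            covariates=self.covariates.copy(),
            stratum=self.stratum.copy(),
            reason=self.reason.copy(),
            ids=self.ids.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "time": self.time, "event": self.event})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        if not np.all(self.stratum == DEFAULT_STRATUM):
            df["stratum"] = self.stratum
        if any(r is not None for r in self.reason):
            df["reason"] = self.reason
        return df


def expand_categorical(
    column: pd.Series, name: str, reference: object
) -> tuple[np.ndarray, list[str]]:
    """Expand a categorical column to indicator columns with treatment coding.

    The declared ``reference`` level is dropped; remaining levels become
    columns named ``"<name>=<level>"`` in sorted order.
    """
    levels = sorted(set(column.dropna().unique()), key=str)
    if reference not in levels:
        raise ConfigError(f"reference level {reference!r} not found in column {name!r}")
    keep = [lv for lv in levels if lv != reference]
    mat = np.column_stack([(column == lv).to_numpy(dtype=float) for lv in keep])
    names = [f"{name}={lv}" for lv in keep]
    return mat, names


def read_dataset(
    path,
    colmap: Mapping[str, object],
    tau: float,
    categorical: Mapping[str, object] | None = None,
    sep: str = ",",
) -> SurvivalDataset:
    """Read a delimited survival table into a validated :class:`SurvivalDataset`.

    Parameters
    ----------
    path : path-like
    colmap : mapping
        Keys ``"time"`` and ``"event"`` (required column names), ``"covariates"``
        (sequence of column names), and optionally ``"stratum"``, ``"reason"``,
        ``"id"``.
    tau : float
        Follow-up horizon; a required input, never inferred from the data.
    categorical : mapping, optional
        ``{covariate column: reference level}`` for columns in ``colmap["covariates"]``
        to be expanded to indicators with treatment coding. Other covariate
        columns are taken as numeric.
    """
    df = pd.read_csv(path, sep=sep)
    categorical = dict(categorical or {})
    needed = [colmap.get("time"), colmap.get("event")]
    if needed[0] is None or needed[1] is None:
        raise ConfigError("colmap must define 'time' and 'event' columns")
    cov_cols = list(colmap.get("covariates", []))
    for col in needed + cov_cols:
        if col not in df.columns:
            raise ConfigError(f"column {col!r} not present in {path}")
    for key in ("stratum", "reason", "id"):
        col = colmap.get(key)
        if col is not None and col not in df.columns:
            raise ConfigError(f"column {col!r} not present in {path}")

    time = pd.to_numeric(df[colmap["time"]], errors="coerce").to_numpy()
    event = df[colmap["event"]].to_numpy()

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in cov_cols:
        if col in categorical:
            mat, nm = expand_categorical(df[col], col, categorical[col])
            blocks.append(mat)
            names.extend(nm)
        else:
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            blocks.append(vals[:, None])
            names.append(col)
    Z = np.hstack(blocks) if blocks else np.empty((len(df), 0))

    return SurvivalDataset(
        time=time,
        event=event,
        covariates=Z,
        covariate_names=names,
        tau=tau,
        stratum=df[colmap["stratum"]].to_numpy() if colmap.get("stratum") else None,
        reason=df[colmap["reason"]].to_numpy() if colmap.get("reason") else None,
        ids=df[colmap["id"]].to_numpy() if colmap.get("id") else None,
    )


def write_dataset(
    dataset: SurvivalDataset,
    path,
    imputed: np.ndarray | None = None,
    source_time: np.ndarray | None = None,
    sep: str = ",",
) -> None:
    """Write a dataset as delimited text (inverse of :func:`read_dataset`).

    For imputed datasets, pass ``imputed`` (0/1 flags) and ``source_time``
    (the pre-imputation follow-up times) to record provenance columns.
    """
    df = dataset.to_frame()
    if imputed is not None:
        df["imputed"] = np.asarray(imputed, dtype=int)
        df["source_time"] = source_time if source_time is not None else dataset.time
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Sensitivity-parameter specification
# ---------------------------------------------------------------------------

@dataclass
class GammaSpec:
    """Specification of the per-subject step-change parameters ``gamma_i``.

    Three modes:

    ``constant``
        one scalar gamma for every non-administratively censored subject;
    ``by_reason``
        a ``{reason: gamma}`` table, with an optional ``"default"`` entry for
        reasons not listed;
    ``by_rule``
        an arbitrary callable ``rule(record_dict) -> float`` evaluated per
        censored record (receives time, reason, stratum, covariates and any
        extra columns).
    """

    mode: str = "constant"
    value: float = 0.0
    table: Mapping[object, float] | None = None
    rule: Callable[[dict], float] | None = None

    @classmethod
    def constant(cls, value: float) -> "GammaSpec":
        return cls(mode="constant", value=float(value))

    @classmethod
    def by_reason(cls, table: Mapping[object, float]) -> "GammaSpec":
        return cls(mode="by_reason", table=dict(table))

    @classmethod
    def by_rule(cls, rule: Callable[[dict], float]) -> "GammaSpec":
        return cls(mode="by_rule", rule=rule)

    def with_value(self, gamma: float, reason: object | None = None) -> "GammaSpec":
        """Return a copy with the free scalar replaced (grid-driver hook).

        In ``constant`` mode the scalar is the constant itself; in
        ``by_reason`` mode it rebinds the entry for ``reason``.
        """
        if self.mode == "constant":
            return GammaSpec.constant(gamma)
        if self.mode == "by_reason":
            if reason is None:
                raise ConfigError("by_reason template needs the reason to rebind")
            table = dict(self.table or {})
            table[reason] = float(gamma)
            return GammaSpec.by_reason(table)
        raise ConfigError(f"cannot rebind scalar in mode {self.mode!r}")


def resolve_gamma(spec: GammaSpec, dataset: SurvivalDataset) -> np.ndarray:
    """Resolve the gamma specification to one value per record.

    Returns a float array of length ``n``: a finite ``gamma_i`` for every
    censored record with ``time < tau``, and NaN ("skip") for event records
    and administratively censored records (``time >= tau``), for which no
    imputation is ever performed.
    """
    n = dataset.n
    out = np.full(n, np.nan)
    mask = dataset.imputable_mask
    if spec.mode == "constant":
        out[mask] = spec.value
    elif spec.mode == "by_reason":
        table = dict(spec.table or {})
        for i in np.flatnonzero(mask):
            reason = dataset.reason[i]
            if reason in table:
                out[i] = table[reason]
            elif "default" in table:
                out[i] = table["default"]
            else:
                raise ConfigError(
                    f"no gamma for censoring reason {reason!r} and no default"
                )
    elif spec.mode == "by_rule":
        if spec.rule is None:
            raise ConfigError("by_rule mode requires a rule callable")
        for i in np.flatnonzero(mask):
            record = {
                "id": dataset.ids[i],
                "time": dataset.time[i],
                "event": int(dataset.event[i]),
                "stratum": dataset.stratum[i],
                "reason": dataset.reason[i],
                "covariates": dict(
                    zip(dataset.covariate_names, dataset.covariates[i])
                ),
            }
            if dataset.extra is not None:
                record.update(dataset.extra.iloc[i].to_dict())
            out[i] = float(spec.rule(record))
    else:
        raise ConfigError(f"unknown gamma mode {spec.mode!r}")
    resolved = out[mask]
    if not np.all(np.isfinite(resolved)):
        raise ConfigError("gamma resolution produced non-finite values")
    return out
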