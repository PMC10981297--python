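"""Preprocessing: attention filtering, missing-data handling, lagged design,
within-person centering, stationarity testing, and daily reliability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from esmnet.dataset import EsmDataset

#: Level-stationarity KPSS critical values (10% / 5% / 1%).
KPSS_CRITICAL_VALUES = {0.10: 0.347, 0.05: 0.463, 0.01: 0.739}

DEFAULT_IMPUTE_WINDOW = 2


@dataclass
class LaggedDesign:
    """Model-ready lag-1 rows: one row per (person, outcome day).

    ``frame`` columns: ``person_id``, ``day`` (the outcome day; day-1 was
    observed), lagged predictors ``x_<var>``, outcomes ``y_<var>``, and — once
    :func:`within_person_center` has run — centered predictors ``xc_<var>``.
    """

    frame: pd.DataFrame
    variable_names: list[str]
    mode: str
    person_means: pd.DataFrame | None = None

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_persons(self) -> int:
        return self.frame["person_id"].nunique()

    @property
    def is_centered(self) -> bool:
        return all(f"xc_{v}" in self.frame.columns for v in self.variable_names)

    def predictor_columns(self, centered: bool = True) -> list[str]:
        prefix = "xc_" if centered else "x_"
        return [f"{prefix}{v}" for v in self.variable_names]

    def audit_lag_validity(self, dataset: EsmDataset) -> bool:
        """Every retained row's predictor day must be outcome day - 1."""
        observed = set(zip(dataset.data["person_id"], dataset.data["day"]))
        for pid, day in zip(self.frame["person_id"], self.frame["day"]):
            if (pid, day - 1) not in observed or (pid, day) not in observed:
                return False
        return True


def filter_attention_checks(dataset: EsmDataset) -> EsmDataset:
    """Drop records that failed (or lack) the attention check.

    The dropped day simply becomes missing for that person; absent
    attention-check values are treated as failing (conservative).
    """
    passed = dataset.data["attention_pass"].notna() & dataset.data["attention_pass"].astype(
        object
    ).eq(True)
    kept = dataset.data[passed].reset_index(drop=True)
    return EsmDataset(kept, list(dataset.variable_names), dataset.likert_bounds)


def moving_average_impute(series: np.ndarray, window: int = DEFAULT_IMPUTE_WINDOW) -> np.ndarray:
    """Replace each missing entry by the mean of observed neighbours.

    The unweighted mean over observed values within ``window`` positions on
    each side; if that window holds no observed value it is expanded
    symmetrically until one is found.  Observed entries are never altered.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    arr = np.asarray(series, dtype=float)
    observed = ~np.isnan(arr)
    if not observed.any():
        raise ValueError("cannot impute an all-missing series")
    out = arr.copy()
    n = arr.size
    for idx in np.flatnonzero(~observed):
        half = window
        while True:
            lo, hi = max(0, idx - half), min(n, idx + half + 1)
            neighbours = arr[lo:hi]
            obs = neighbours[~np.isnan(neighbours)]
            if obs.size:
                out[idx] = obs.mean()
                break
            half += 1
    return out


def impute_dataset(dataset: EsmDataset, window: int = DEFAULT_IMPUTE_WINDOW) -> EsmDataset:
    """Apply moving-average imputation per person, per variable.

    Persons with an all-missing series for some variable are left untouched
    for that variable (those rows fall out at the lagged-design stage).
    """
    out = dataset.copy()
    out.likert_bounds = None  # imputed means need not be integers
    for _, idx in out.data.groupby("person_id", sort=False).groups.items():
        for v in out.variable_names:
            col = out.data.loc[idx, v].to_numpy(dtype=float)
            if np.isnan(col).all() or not np.isnan(col).any():
                continue
            out.data.loc[idx, v] = moving_average_impute(col, window)
    return out


def build_lagged_rows(dataset: EsmDataset, mode: str = "listwise") -> LaggedDesign:
    """Pair each day t with day t-1 into lag-1 rows.

    A candidate row exists only when day t-1 is present in the person's
    calendar (the consecutive-assessment lag requirement); in ``listwise``
    mode the row is retained only when the full predictor and outcome vectors
    are observed, so every node-wise regression sees the same rows.  In
    ``imputed`` mode imputation is expected to have removed all missingness
    beforehand; rows still containing missing cells (e.g. a person with an
    all-missing variable) are dropped.
    """
    if mode not in ("listwise", "imputed"):
        raise ValueError(f"unknown mode {mode!r}")
    names = dataset.variable_names
    pieces = []
    for pid, grp in dataset.data.groupby("person_id", sort=False):
        days = grp["day"].to_numpy()
        values = grp[names].to_numpy(dtype=float)
        day_pos = {d: k for k, d in enumerate(days)}
        for d in days:
            if (d - 1) not in day_pos:
                continue
            pred = values[day_pos[d - 1]]
            outc = values[day_pos[d]]
            if np.isnan(pred).any() or np.isnan(outc).any():
                continue
            pieces.append((pid, d, *pred, *outc))
    cols = ["person_id", "day", *[f"x_{v}" for v in names], *[f"y_{v}" for v in names]]
    frame = pd.DataFrame(pieces, columns=cols)
    return LaggedDesign(frame, list(names), mode)


def within_person_center(design: LaggedDesign) -> LaggedDesign:
    """Center lagged predictors on each person's mean over retained rows.

    Means are computed from retained predictor values (post-deletion), so the
    per-person centered mean is exactly zero on the design actually fit.
    """
    frame = design.frame.copy()
    x_cols = [f"x_{v}" for v in design.variable_names]
    means = frame.groupby("person_id", sort=False)[x_cols].transform("mean")
    for v in design.variable_names:
        frame[f"xc_{v}"] = frame[f"x_{v}"] - means[f"x_{v}"]
    person_means = (
        frame.groupby("person_id", sort=False)[x_cols]
        .mean()
        .rename(columns={f"x_{v}": v for v in design.variable_names})
    )
    return LaggedDesign(frame, list(design.variable_names), design.mode, person_means)


@dataclass(frozen=True)
class KpssResult:
    """Level-stationarity KPSS statistic for one series."""

    statistic: float
    lag_truncation: int
    n_obs: int

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("KPSS statistic must be nonnegative")


def default_kpss_lags(n_obs: int) -> int:
    """Common Bartlett-window truncation rule: floor(4 (T/100)^{1/4})."""
    return int(np.floor(4.0 * (n_obs / 100.0) ** 0.25))


def kpss_statistic(series: np.ndarray, lag_truncation: int | None = None) -> KpssResult:
    """Level-stationarity KPSS statistic.

    Demean the series, take partial sums S_t, estimate the long-run variance
    with a Bartlett-kernel (Newey-West) estimator at the given truncation,
    and return eta = T^{-2} sum_t S_t^2 / lrv.  A constant series (zero
    long-run variance) yields statistic 0.
    """
    y = np.asarray(series, dtype=float)
    if np.isnan(y).any():
        raise ValueError("series must be fully observed")
    T = y.size
    if T < 8:
        raise ValueError("series too short for KPSS (need T >= 8)")
    if lag_truncation is None:
        lag_truncation = default_kpss_lags(T)
    if lag_truncation < 0:
        raise ValueError("lag_truncation must be >= 0")
    e = y - y.mean()
    S = np.cumsum(e)
    lrv = float(e @ e) / T
    for lag in range(1, lag_truncation + 1):
        weight = 1.0 - lag / (lag_truncation + 1.0)
        lrv += 2.0 * weight * float(e[lag:] @ e[:-lag]) / T
    if lrv <= 0:
        return KpssResult(0.0, lag_truncation, T)
    eta = float(S @ S) / (T**2 * lrv)
    return KpssResult(eta, lag_truncation, T)


def kpss_decision(result: KpssResult, level: float = 0.05) -> bool:
    """True when the series is accepted as level-stationary.

    Stationary iff statistic < critical value; a tie rejects stationarity.
    """
    if level not in KPSS_CRITICAL_VALUES:
        raise ValueError(f"unsupported level {level}; choose from {sorted(KPSS_CRITICAL_VALUES)}")
    return result.statistic < KPSS_CRITICAL_VALUES[level]


def kpss_report(
    dataset: EsmDataset,
    level: float = 0.05,
    lag_truncation: int | None = None,
    min_length: int = 8,
    pass_fraction: float = 0.95,
) -> pd.DataFrame:
    """Per-person, per-variable KPSS table with a variable-level verdict.

    Each person's observed (or imputed) series is tested separately; a
    variable passes when at least ``pass_fraction`` of testable person-series
    are stationary at ``level``.  Columns: variable, person_id, n_obs,
    statistic, stationary, variable_pass.
    """
    rows = []
    for v in dataset.variable_names:
        for pid, grp in dataset.data.groupby("person_id", sort=False):
            series = grp[v].to_numpy(dtype=float)
            series = series[~np.isnan(series)]
            if series.size < min_length:
                continue
            res = kpss_statistic(series, lag_truncation)
            rows.append(
                {
                    "variable": v,
                    "person_id": pid,
                    "n_obs": res.n_obs,
                    "statistic": res.statistic,
                    "stationary": kpss_decision(res, level),
                }
            )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    verdict = report.groupby("variable")["stationary"].mean() >= pass_fraction
    report["variable_pass"] = report["variable"].map(verdict)
    return report


def cronbach_alpha_daily(dataset: EsmDataset) -> pd.Series:
    """Cronbach's alpha per day over persons with complete item responses.

    alpha = (k/(k-1)) * (1 - sum of item variances / variance of item sum),
    sample variances (ddof=1).  Days with fewer than two complete responders
    get NaN.
    """
    names = dataset.variable_names
    k = len(names)
    alphas = {}
    for day, grp in dataset.data.groupby("day", sort=True):
        items = grp[names].to_numpy(dtype=float)
        complete = items[~np.isnan(items).any(axis=1)]
        if complete.shape[0] < 2:
            alphas[day] = np.nan
            continue
        item_vars = complete.var(axis=0, ddof=1)
        total_var = complete.sum(axis=1).var(ddof=1)
        if total_var == 0:
            alphas[day] = np.nan
            continue
        alphas[day] = (k / (k - 1)) * (1.0 - item_vars.sum() / total_var)
    return pd.Series(alphas, name="alpha").rename_axis("day")
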