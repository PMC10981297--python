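"""Node-wise multilevel lag-1 VAR estimation.

Each symptom is regressed on the p within-person-centered lagged predictors
with a person-level random intercept and mutually uncorrelated ("orthogonal")
random slopes.  The linear mixed models are fit with statsmodels MixedLM
(variance components encode the diagonal random-slope covariance); the
node-wise orchestration, inference conventions, residual pipeline, and the
contemporaneous partial-correlation stage live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

RANDOM_STRUCTURES = ("orthogonal", "intercept_only")
PVALUE_METHODS = ("wald_normal", "satterthwaite")
ESTIMATORS = ("reml", "ml")

#: Optimizer cascade: each entry is tried until one converges.
_FIT_METHODS = ("lbfgs", "powell", "cg")


class EstimationError(RuntimeError):
    """Raised when a node-wise mixed model cannot be estimated."""


class ConvergenceError(EstimationError):
    """Raised when no optimizer converges; carries per-attempt diagnostics."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class FitConfig:
    """Settings for node-wise estimation and edge selection."""

    alpha: float = 0.05
    random_structure: str = "orthogonal"
    pvalue_method: str = "wald_normal"
    min_rows_per_person: int = 10
    estimator: str = "reml"
    contemporaneous_multilevel: bool = False
    max_restarts: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(f"random_structure must be one of {RANDOM_STRUCTURES}")
        if self.pvalue_method not in PVALUE_METHODS:
            raise ValueError(f"pvalue_method must be one of {PVALUE_METHODS}")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")


@dataclass
class NodewiseFit:
    """One symptom's multilevel regression result."""

    target: int
    target_name: str
    intercept: float
    intercept_se: float
    intercept_p: float
    fixed_coefs: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    random_variances: np.ndarray  # intercept first, then one slope per predictor
    residuals: np.ndarray
    row_index: pd.DataFrame  # person_id, day of each retained row
    n_rows: int
    n_persons: int
    converged: bool
    method: str

    def __post_init__(self) -> None:
        if (self.random_variances < -1e-12).any():
            raise ValueError("random variances must be nonnegative")
        if ((self.p_values < 0) | (self.p_values > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if len(self.residuals) != self.n_rows:
            raise ValueError("residual count must equal n_rows")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "target_name": self.target_name,
            "intercept": {"estimate": self.intercept, "se": self.intercept_se, "p": self.intercept_p},
            "coefficients": self.fixed_coefs.tolist(),
            "std_errors": self.std_errors.tolist(),
            "p_values": self.p_values.tolist(),
            "random_effect_sd": np.sqrt(self.random_variances).tolist(),
            "n_rows": self.n_rows,
            "n_persons": self.n_persons,
            "converged": self.converged,
            "method": self.method,
        }


def _prepare_frame(design, config: FitConfig) -> tuple[pd.DataFrame, list[str]]:
    """Model frame with sanitized predictor names, small persons excluded."""
    if not design.is_centered:
        raise EstimationError("design must be within-person centered before fitting")
    p = len(design.variable_names)
    frame = design.frame.copy()
    counts = frame.groupby("person_id")["day"].transform("count")
    dropped = frame.loc[counts < config.min_rows_per_person, "person_id"].unique()
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} person(s) with < {config.min_rows_per_person} rows",
            stacklevel=3,
        )
        frame = frame[counts >= config.min_rows_per_person]
    if frame["person_id"].nunique() < 2:
        raise EstimationError("multilevel model needs >= 2 persons with enough rows")
    xcols = [f"__x{i}" for i in range(p)]
    for i, v in enumerate(design.variable_names):
        frame[xcols[i]] = frame[f"xc_{v}"]
    return frame.reset_index(drop=True), xcols


def _fit_mixedlm(formula, data, groups, vc_formula, config: FitConfig):
    """Fit with an optimizer cascade and jittered restarts; raise on failure."""
    diagnostics: list[str] = []
    methods = _FIT_METHODS[: config.max_restarts + 1] or _FIT_METHODS[:1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in methods:
            model = smf.mixedlm(formula, data, groups=groups, re_formula="1", vc_formula=vc_formula)
            try:
                result = model.fit(
                    reml=config.estimator == "reml", method=method, maxiter=2000
                )
            except Exception as exc:  # noqa: BLE001 — collect and try next optimizer
                diagnostics.append(f"{method}: {exc!r}")
                continue
            if result.converged:
                return result, method
            diagnostics.append(f"{method}: did not converge")
    raise ConvergenceError("mixed model did not converge", diagnostics)


def _pvalues(est: np.ndarray, se: np.ndarray, config: FitConfig) -> np.ndarray:
    if config.pvalue_method == "wald_normal":
        z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
        return 2.0 * stats.norm.sf(np.abs(z))
    raise NotImplementedError(
        "satterthwaite degrees of freedom are not implemented; use wald_normal"
    )


def fit_node(design, target: int, config: FitConfig | None = None) -> NodewiseFit:
    """Fit one node-wise multilevel regression.

    The outcome is variable ``target`` at day t; predictors are all p
    centered lagged variables.  Random structure: person intercept plus,
    under ``orthogonal``, one variance component per slope (diagonal
    random-effect covariance).  Residuals are taken at the conditional level
    (fixed effects plus empirical-Bayes person effects).
    """
    config = config or FitConfig()
    names = design.variable_names
    p = len(names)
    if not 0 <= target < p:
        raise IndexError(f"target {target} out of range for p={p}")
    frame, xcols = _prepare_frame(design, config)
    frame = frame.assign(__y=frame[f"y_{names[target]}"])

    formula = "__y ~ " + " + ".join(xcols)
    vc = {c: f"0 + {c}" for c in xcols} if config.random_structure == "orthogonal" else None
    result, method = _fit_mixedlm(formula, frame, frame["person_id"], vc, config)

    fe = result.fe_params
    se = result.bse_fe
    coef = fe[xcols].to_numpy()
    coef_se = se[xcols].to_numpy()
    pvals = _pvalues(coef, coef_se, config)
    intercept_p = float(_pvalues(np.array([fe["Intercept"]]), np.array([se["Intercept"]]), config)[0])

    var_intercept = float(np.asarray(result.cov_re)[0, 0])
    if vc is not None:
        vc_names = list(result.model.exog_vc.names)
        vcomp = dict(zip(vc_names, np.asarray(result.vcomp, dtype=float)))
        slope_vars = np.array([max(vcomp[c], 0.0) for c in xcols])
    else:
        slope_vars = np.zeros(p)
    random_variances = np.concatenate([[max(var_intercept, 0.0)], slope_vars])

    residuals = np.asarray(result.resid, dtype=float)
    return NodewiseFit(
        target=target,
        target_name=names[target],
        intercept=float(fe["Intercept"]),
        intercept_se=float(se["Intercept"]),
        intercept_p=intercept_p,
        fixed_coefs=coef,
        std_errors=coef_se,
        p_values=pvals,
        random_variances=random_variances,
        residuals=residuals,
        row_index=frame[["person_id", "day"]].reset_index(drop=True),
        n_rows=len(frame),
        n_persons=frame["person_id"].nunique(),
        converged=bool(result.converged),
        method=method,
    )


def fit_all_nodes(design, config: FitConfig | None = None, raise_on_error: bool = True):
    """Fit every node-wise regression, in variable order.

    With ``raise_on_error=False``, failures are isolated: the returned list
    holds the exception object in the failing node's slot so successful nodes
    survive a partial failure.
    """
    config = config or FitConfig()
    fits: list = []
    for j in range(len(design.variable_names)):
        try:
            fits.append(fit_node(design, j, config))
        except Exception as exc:  # noqa: BLE001
            if raise_on_error:
                raise
            fits.append(exc)
    return fits


def residual_matrix(fits: list[NodewiseFit]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack per-node residuals column-wise, verifying row alignment."""
    ref = fits[0].row_index
    for fit in fits[1:]:
        if len(fit.row_index) != len(ref) or not (
            fit.row_index["person_id"].to_numpy() == ref["person_id"].to_numpy()
        ).all() or not (fit.row_index["day"].to_numpy() == ref["day"].to_numpy()).all():
            raise EstimationError("residuals are not aligned on the same retained rows")
    return np.column_stack([f.residuals for f in fits]), ref


def sign_consistent_pcor(b_jk: float, b_kj: float) -> float:
    """Combine the two residual-regression coefficients of one pair.

    sign(b_jk) * sqrt(b_jk * b_kj) when the coefficients share a sign,
    otherwise 0; the result is clipped into [-1, 1].
    """
    if b_jk * b_kj > 0:
        return float(np.clip(np.sign(b_jk) * np.sqrt(b_jk * b_kj), -1.0, 1.0))
    return 0.0


def fit_contemporaneous(fits: list[NodewiseFit], config: FitConfig | None = None):
    """Partial-correlation network among same-day residuals.

    Each residual series is regressed on all the others (pooled OLS by
    default; person random intercept behind a flag).  The edge weight for a
    pair combines the two regression coefficients, sign-consistently:
    sign(b_jk) * sqrt(b_jk * b_kj) when they agree in sign, else 0.  An edge
    is retained only when both coefficients are significant ("and" rule).
    """
    from esmnet.networks import ContemporaneousNetwork  # local import: avoid cycle

    config = config or FitConfig()
    R, row_index = residual_matrix(fits)
    p = R.shape[1]
    B = np.zeros((p, p))
    P = np.ones((p, p))
    for j in range(p):
        others = [k for k in range(p) if k != j]
        b, se = _regress_residuals(R[:, j], R[:, others], row_index, config)
        pv = _pvalues(b, se, config)
        B[others, j] = b
        P[others, j] = pv

    weights = np.zeros((p, p))
    significant = np.zeros((p, p), dtype=bool)
    for j in range(p):
        for k in range(j + 1, p):
            bjk, bkj = B[k, j], B[j, k]  # b_jk: coef of k in regression of j
            w = sign_consistent_pcor(bjk, bkj)
            weights[j, k] = weights[k, j] = w
            sig = bool(P[k, j] < config.alpha and P[j, k] < config.alpha and w != 0.0)
            significant[j, k] = significant[k, j] = sig

    names = [f.target_name for f in fits]
    return ContemporaneousNetwork(
        weights=weights,
        significant=significant,
        alpha=config.alpha,
        variable_names=names,
        coef_matrix=B,
        p_value_matrix=P,
    )


def _regress_residuals(y, X, row_index, config: FitConfig):
    """One residual-on-residuals regression; returns (coefs, std errors)."""
    if config.contemporaneous_multilevel:
        data = pd.DataFrame(X, columns=[f"__r{i}" for i in range(X.shape[1])])
        data["__y"] = y
        data["__g"] = row_index["person_id"].to_numpy()
        formula = "__y ~ " + " + ".join(data.columns[: X.shape[1]])
        result, _ = _fit_mixedlm(formula, data, data["__g"], None, config)
        cols = [c for c in result.fe_params.index if c != "Intercept"]
        return result.fe_params[cols].to_numpy(), result.bse_fe[cols].to_numpy()
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    dof = len(y) - Xd.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    return beta[1:], se[1:]


def random_effects_sd_network(fits: list[NodewiseFit]) -> np.ndarray:
    """Inter-individual-difference network: SD of each random slope.

    Entry [i, j] is the standard deviation of the person-specific deviation
    of predictor i's coefficient in the node-j regression.
    """
    p = len(fits)
    out = np.zeros((p, p))
    for j, fit in enumerate(fits):
        out[:, j] = np.sqrt(fit.random_variances[1:])
    return out
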