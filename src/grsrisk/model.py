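"""Combined risk model: logistic regression of case status on the wGRS
decile rank and ordinal smoking, plus per-category odds-ratio tables."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import two_by_two_or
from .grs import ScoreSet
from .types import Cohort, GrsError


@dataclass
class ModelFit:
    """A fitted logistic model on named ordinal covariates."""

    names: list[str]  # ("const", <covariates...>)
    coefficients: np.ndarray
    bse: np.ndarray
    ci95: np.ndarray  # (k, 2)
    pvalues: np.ndarray
    fitted_probabilities: np.ndarray
    converged: bool

    @property
    def or_per_unit(self) -> np.ndarray:
        return np.exp(self.coefficients)

    def to_series(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.names)


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str]) -> ModelFit:
    """Maximum-likelihood logistic fit with explicit convergence checking."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-10)
    except Exception as exc:  # separation raises PerfectSeparationError
        raise GrsError(f"logistic fit failed: {exc}") from exc
    grad_norm = float(np.abs(res.model.score(res.params)).max())
    if not res.mle_retvals.get("converged", False) or grad_norm > 1e-6:
        raise GrsError(
            f"logistic fit did not converge (max |gradient| = {grad_norm:.3g}); "
            "check for separation or collinearity"
        )
    return ModelFit(
        names=names,
        coefficients=np.asarray(res.params),
        bse=np.asarray(res.bse),
        ci95=np.asarray(res.conf_int()),
        pvalues=np.asarray(res.pvalues),
        fitted_probabilities=np.asarray(res.predict(X)),
        converged=True,
    )


def fit_risk_model(
    cohort: Cohort, scores: ScoreSet, wgrs_covariate: str = "decile"
) -> ModelFit:
    """Fit status ~ wGRS + smoking.

    The wGRS covariate is the decile rank 0-9 by default
    (``wgrs_covariate="raw"`` uses the raw multiplicative score instead);
    smoking enters as ordinal 0/1/2.
    """
    if wgrs_covariate == "decile":
        g = np.asarray(scores.wgrs_decile, dtype=float)
    elif wgrs_covariate == "raw":
        g = np.asarray(scores.wgrs, dtype=float)
    else:
        raise GrsError(f"unknown wGRS covariate mode {wgrs_covariate!r}")
    smoking = np.asarray(cohort.smoking, dtype=float)
    X = np.column_stack([np.ones(len(cohort)), g, smoking])
    return fit_logistic(cohort.status, X, names=["const", "wgrs", "smoking"])


def relative_risk(
    coefficients: np.ndarray, wgrs_decile: int, smoking: int
) -> float:
    """Relative odds exp(b0 + b1*decile + b2*smoking) for given covariates."""
    b = np.asarray(coefficients, dtype=float)
    if b.shape != (3,):
        raise GrsError("coefficients must be (intercept, wgrs, smoking)")
    if not 0 <= wgrs_decile <= 9:
        raise GrsError(f"wGRS decile must be 0-9, got {wgrs_decile}")
    if smoking not in (0, 1, 2):
        raise GrsError(f"smoking level must be 0/1/2, got {smoking}")
    return math.exp(b[0] + b[1] * wgrs_decile + b[2] * smoking)


def logistic_procedure() -> "FitProcedure":
    """Fit-procedure adapter for the resampling validators: maximum-
    likelihood logistic on the given covariate matrix (intercept added)."""

    def fit(X: np.ndarray, y: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        design = np.column_stack([np.ones(len(y)), X])
        names = ["const"] + [f"x{i}" for i in range(X.shape[1])]
        mf = fit_logistic(y, design, names=names)
        coef = mf.coefficients

        def predict(X_new: np.ndarray) -> np.ndarray:
            X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
            if X_new.shape[1] != X.shape[1]:
                X_new = X_new.T
            lin = np.column_stack([np.ones(len(X_new)), X_new]) @ coef
            return 1.0 / (1.0 + np.exp(-lin))

        return predict

    return fit


def regularized_logistic_procedure(C: float = 1e6):
    """Ridge-stabilized logistic fit procedure (scikit-learn backend).

    Robust to separation and wide designs; used where exact ML would fail,
    e.g. many-noise-covariate over-fitting demonstrations.
    """
    from sklearn.linear_model import LogisticRegression

    def fit(X: np.ndarray, y: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        clf = LogisticRegression(C=C, max_iter=5000)
        clf.fit(X, y)

        def predict(X_new: np.ndarray) -> np.ndarray:
            X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
            if X_new.shape[1] != X.shape[1]:
                X_new = X_new.T
            return clf.predict_proba(X_new)[:, 1]

        return predict

    return fit


def category_or_table(
    status: np.ndarray,
    categories: np.ndarray,
    reference: str | int,
    order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-category odds ratios vs a reference category, with trend test.

    Categories are compared to ``reference`` by 2x2 cross-product ORs with
    Woolf CIs; the trend p-value comes from a logistic fit on the ordinal
    category rank.  Rank order is ``order`` if given, else categories sorted
    ascending (numeric-aware).  Categories empty of cases or controls are
    flagged with NaN OR.  The trend p is attached to every row (column
    ``p_trend``).
    """
    status = np.asarray(status)
    categories = np.asarray(categories)
    ref = str(reference)
    if order is not None:
        cats = [str(c) for c in order]
        extra = set(map(str, categories)) - set(cats)
        if extra:
            raise GrsError(f"categories not covered by order: {sorted(extra)}")
    else:
        cats = sorted(set(map(str, categories)), key=_category_key)
    if ref not in cats:
        raise GrsError(f"reference category {reference!r} absent")
    cat_str = categories.astype(str)
    ref_cases = int(((cat_str == ref) & (status == 1)).sum())
    ref_ctrls = int(((cat_str == ref) & (status == 0)).sum())
    if ref_cases == 0 or ref_ctrls == 0:
        raise GrsError(f"reference category {reference!r} empty in cases or controls")

    rank = {c: i for i, c in enumerate(cats)}
    x = np.array([rank[c] for c in cat_str], dtype=float)
    trend = fit_logistic(
        status, np.column_stack([np.ones_like(x), x]), names=["const", "rank"]
    )
    p_trend = float(trend.pvalues[1])

    rows = []
    for cat in cats:
        n_case = int(((cat_str == cat) & (status == 1)).sum())
        n_ctrl = int(((cat_str == cat) & (status == 0)).sum())
        if cat == ref:
            orr, lo, hi, p = 1.0, np.nan, np.nan, np.nan
        elif n_case == 0 and n_ctrl == 0:
            orr, lo, hi, p = np.nan, np.nan, np.nan, np.nan
        else:
            res = two_by_two_or(n_case, n_ctrl, ref_cases, ref_ctrls)
            orr, (lo, hi), p = res.oratio, res.ci95, res.p
        rows.append((cat, n_case, n_ctrl, orr, lo, hi, p, p_trend))
    return pd.DataFrame(
        rows,
        columns=["category", "n_cases", "n_controls", "oratio", "ci_low", "ci_high", "p", "p_trend"],
    )


def _category_key(c: str):
    try:
        return (0, float(c), c)
    except ValueError:
        return (1, 0.0, c)
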