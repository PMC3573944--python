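"""Discrimination, calibration and internal validation.

AUC is the rank-based concordance statistic: the probability a random case
outscores a random control, ties counted half.  Confidence intervals and
AUC comparisons use seeded bootstrap resampling (DeLong available as an
option); over-fitting is quantified by Harrell's bootstrap optimism and by
a 75/25 split refit; calibration by the Hosmer-Lemeshow decile chi-square;
operating points by the Youden criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .types import GrsError

# fit procedure contract: fit_fn(X, y) -> predict(X) -> scores
FitProcedure = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float] | None
    curve: pd.DataFrame  # columns fpr, tpr, threshold


@dataclass
class OptimismResult:
    auc_apparent: float
    optimism: float
    auc_corrected: float
    n_replicates: int
    n_failed: int
    replicate_optimism: np.ndarray = field(repr=False, default=None)


@dataclass
class CutoffMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    tp: int
    fn: int
    tn: int
    fp: int


def _check_classes(status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    status = np.asarray(status)
    if not ((status == 1).any() and (status == 0).any()):
        raise GrsError("both cases and controls are required")
    return status == 1, status == 0


def auc_mann_whitney(scores: np.ndarray, status: np.ndarray) -> float:
    """Concordance: P(case score > control score) + 0.5 P(tie), via ranks."""
    scores = np.asarray(scores, dtype=float)
    is_case, is_ctrl = _check_classes(status)
    n1, n0 = int(is_case.sum()), int(is_ctrl.sum())
    ranks = stats.rankdata(scores)
    return float((ranks[is_case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    """ROC curve points: (fpr, tpr, threshold), threshold rule score >= t."""
    scores = np.asarray(scores, dtype=float)
    is_case, is_ctrl = _check_classes(status)
    n1, n0 = is_case.sum(), is_ctrl.sum()
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tp = np.cumsum(is_case[order])
    fp = np.cumsum(is_ctrl[order])
    last = np.r_[np.flatnonzero(np.diff(sorted_scores) != 0), len(scores) - 1]
    tpr = np.r_[0.0, tp[last] / n1]
    fpr = np.r_[0.0, fp[last] / n0]
    thr = np.r_[np.inf, sorted_scores[last]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def auc_rank(
    scores: np.ndarray,
    status: np.ndarray,
    ci: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> RocResult:
    """AUC with bootstrap-percentile 95% CI and the ROC curve."""
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status)
    auc = auc_mann_whitney(scores, status)
    curve = roc_points(scores, status)
    interval = None
    if ci:
        rng = np.random.default_rng(seed)
        n = len(scores)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            while not (status[idx] == 1).any() or not (status[idx] == 0).any():
                idx = rng.integers(0, n, n)
            reps[b] = auc_mann_whitney(scores[idx], status[idx])
        interval = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return RocResult(auc=auc, ci95=interval, curve=curve)


def compare_auc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    status: np.ndarray,
    method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired AUC comparison; returns (delta = AUC_a - AUC_b, two-sided p).

    Default is a paired subject-level bootstrap; ``method="delong"`` uses
    the DeLong covariance test.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    status = np.asarray(status)
    if a.shape != b.shape or a.shape[0] != status.shape[0]:
        raise GrsError("compare_auc requires paired scores on the same subjects")
    delta = auc_mann_whitney(a, status) - auc_mann_whitney(b, status)
    if method == "delong":
        return delta, _delong_p(a, b, status)
    if method != "bootstrap":
        raise GrsError(f"unknown AUC comparison method {method!r}")
    rng = np.random.default_rng(seed)
    n = len(status)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        while not (status[idx] == 1).any() or not (status[idx] == 0).any():
            idx = rng.integers(0, n, n)
        reps[i] = auc_mann_whitney(a[idx], status[idx]) - auc_mann_whitney(b[idx], status[idx])
    p_low = float(np.mean(reps <= 0.0))
    p_high = float(np.mean(reps >= 0.0))
    return delta, min(1.0, 2.0 * min(p_low, p_high))


def _delong_p(a: np.ndarray, b: np.ndarray, status: np.ndarray) -> float:
    is_case, is_ctrl = _check_classes(status)
    m, n = int(is_case.sum()), int(is_ctrl.sum())

    def structural(scores):
        cases, ctrls = scores[is_case], scores[is_ctrl]
        # placement values via midranks
        v10 = np.array([(np.sum(c > ctrls) + 0.5 * np.sum(c == ctrls)) / n for c in cases])
        v01 = np.array([(np.sum(cases > c) + 0.5 * np.sum(cases == c)) / m for c in ctrls])
        return v10, v01

    v10a, v01a = structural(a)
    v10b, v01b = structural(b)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def hosmer_lemeshow(
    fitted_probabilities: np.ndarray, status: np.ndarray, n_groups: int = 10
) -> tuple[float, float]:
    """Hosmer-Lemeshow calibration test; returns (statistic, p-value).

    Subjects are binned by fitted-probability deciles (degenerate bins are
    merged); statistic is sum (O-E)^2 / (E (1 - E/n_g)) with df = g - 2.
    """
    p = np.asarray(fitted_probabilities, dtype=float)
    y = np.asarray(status, dtype=float)
    if n_groups < 2:
        raise GrsError("n_groups must be >= 2")
    groups = pd.qcut(p, n_groups, labels=False, duplicates="drop")
    groups = np.asarray(groups, dtype=float)
    if np.isnan(groups).all():
        raise GrsError("fitted probabilities are degenerate; cannot form groups")
    groups = groups.astype(int)
    g = int(groups.max()) + 1
    if g < 2:
        raise GrsError("fitted probabilities are degenerate; cannot form groups")
    statistic = 0.0
    for k in range(g):
        sel = groups == k
        n_g = int(sel.sum())
        obs = float(y[sel].sum())
        exp = float(p[sel].sum())
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            continue
        statistic += (obs - exp) ** 2 / denom
    df = g - 2
    return float(statistic), float(stats.chi2.sf(statistic, df))


def bootstrap_optimism(
    X: np.ndarray,
    y: np.ndarray,
    fit_procedure: FitProcedure,
    n_boot: int = 1000,
    seed: int = 0,
) -> OptimismResult:
    """Harrell's bootstrap optimism correction of the c-statistic.

    For each resample: refit, score AUC on the resample and on the original
    data; optimism is the mean difference, and the corrected AUC is the
    apparent AUC minus the optimism.  Replicates whose refit fails are
    dropped; more than 10% failures is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_boot < 1:
        raise GrsError("n_boot must be >= 1")
    predict = fit_procedure(X, y)
    apparent = auc_mann_whitney(predict(X), y)
    rng = np.random.default_rng(seed)
    n = len(y)
    opts, failed = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if not (y[idx] == 1).any() or not (y[idx] == 0).any():
            failed += 1
            continue
        try:
            pred_b = fit_procedure(X[idx], y[idx])
            auc_boot = auc_mann_whitney(pred_b(X[idx]), y[idx])
            auc_orig = auc_mann_whitney(pred_b(X), y)
        except Exception:
            failed += 1
            continue
        opts.append(auc_boot - auc_orig)
    if failed > 0.1 * n_boot:
        raise GrsError(f"bootstrap optimism: {failed}/{n_boot} replicates failed to refit")
    optimism = float(np.mean(opts))
    return OptimismResult(
        auc_apparent=apparent,
        optimism=optimism,
        auc_corrected=apparent - optimism,
        n_replicates=len(opts),
        n_failed=failed,
        replicate_optimism=np.asarray(opts),
    )


def split_validate(
    X: np.ndarray,
    y: np.ndarray,
    fit_procedure: FitProcedure,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[float, float]:
    """Random train/test split refit; returns (c_train, c_test)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not 0.0 < train_fraction < 1.0:
        raise GrsError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round(train_fraction * n))
    for attempt in range(2):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        ok = all((y[part] == 1).any() and (y[part] == 0).any() for part in (tr, te))
        if ok:
            break
    else:
        raise GrsError("could not obtain a split with both classes in both parts")
    predict = fit_procedure(X[tr], y[tr])
    return (
        auc_mann_whitney(predict(X[tr]), y[tr]),
        auc_mann_whitney(predict(X[te]), y[te]),
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> CutoffMetrics:
    """Sensitivity/specificity/accuracy/PPV/NPV from a confusion matrix."""
    total = tp + fn + tn + fp
    return CutoffMetrics(
        cutoff=float("nan"),
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / total if total else float("nan"),
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def metrics_at_cutoff(scores: np.ndarray, status: np.ndarray, cutoff: float) -> CutoffMetrics:
    """Confusion metrics with positives called at score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    is_case, is_ctrl = _check_classes(status)
    pos = scores >= cutoff
    m = confusion_metrics(
        tp=int((pos & is_case).sum()),
        fn=int((~pos & is_case).sum()),
        tn=int((~pos & is_ctrl).sum()),
        fp=int((pos & is_ctrl).sum()),
    )
    m.cutoff = float(cutoff)
    return m


def youden_cutoff_metrics(scores: np.ndarray, status: np.ndarray) -> CutoffMetrics:
    """Operating point maximizing sensitivity + specificity.

    Candidate cutoffs are the observed score values (rule: score >= cutoff);
    ties on the Youden criterion are broken toward higher specificity
    (higher cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    is_case, is_ctrl = _check_classes(status)
    n1, n0 = is_case.sum(), is_ctrl.sum()
    candidates = np.unique(scores)
    # vectorized sens/spec at each candidate via sorted cumulative counts
    order = np.argsort(scores, kind="mergesort")
    sorted_scores = scores[order]
    case_sorted = is_case[order].astype(int)
    left = np.searchsorted(sorted_scores, candidates, side="left")
    cum_cases = np.r_[0, np.cumsum(case_sorted)]
    cases_below = cum_cases[left]
    ctrls_below = left - cases_below
    sens = (n1 - cases_below) / n1
    spec = ctrls_below / n0
    j = sens + spec
    best = np.flatnonzero(j == j.max())[-1]  # highest cutoff -> higher specificity
    return metrics_at_cutoff(scores, status, float(candidates[best]))
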