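"""Diagnostic evaluation: empirical ROC, Youden cutoff, logistic combination.

Conventions:

* For Ct features, *lower* values indicate disease (more methylated
  template amplifies earlier); pass ``direction="lower_positive"`` rather
  than negating scores by hand.
* The empirical AUC equals the Mann-Whitney U statistic scaled to [0, 1]
  with ties counted 1/2; its 95% CI uses the DeLong variance estimate.
* The Youden-optimal cutoff maximizes J = sensitivity + specificity - 1;
  ties are broken toward higher specificity, then the higher threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RocResult",
    "LogisticModel",
    "SensSpecResult",
    "roc_curve",
    "youden_cutoff",
    "delong_auc_ci",
    "fit_logistic",
    "sens_spec",
    "group_comparison",
]


@dataclass
class RocResult:
    """Empirical ROC curve.

    ``thresholds`` are on the *original* score scale; a sample is called
    positive at threshold t when its score is >= t (``higher_positive``) or
    <= t (``lower_positive``).
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    direction: str
    youden_cutoff: float = np.nan
    youden_j: float = np.nan


@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    converged: bool
    separation_detected: bool

    def decision_score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_score(X)))


@dataclass
class SensSpecResult:
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    tp: int
    fn: int
    tn: int
    fp: int


def _as_binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        raise ValueError("labels must be binary 0/1 (encode classes first)")
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return y


def roc_curve(scores, labels, direction: str = "higher_positive") -> RocResult:
    """Empirical ROC over thresholds at midpoints between distinct scores.

    AUC is computed by the rank (Mann-Whitney) formula, counting ties 1/2,
    and so equals the exhaustive pair-counting probability
    P(score_pos beats score_neg) + P(tie)/2.
    """
    if direction not in ("higher_positive", "lower_positive"):
        raise ValueError("direction must be 'higher_positive' or 'lower_positive'")
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present; AUC undefined")

    internal = s if direction == "higher_positive" else -s

    # thresholds: +inf sentinel, midpoints between consecutive distinct
    # scores (descending), -inf sentinel; positive call iff internal >= t.
    distinct = np.unique(internal)[::-1]
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if distinct.size > 1 else np.array([])
    t_internal = np.concatenate(([np.inf], distinct[:1], mids, [-np.inf]))
    pos = internal[y == 1]
    neg = internal[y == 0]
    sens = np.array([(pos >= t).mean() for t in t_internal])
    spec = np.array([(neg < t).mean() for t in t_internal])

    ranks = stats.rankdata(internal)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    ci = delong_auc_ci(internal, y)

    thresholds = t_internal if direction == "higher_positive" else -t_internal
    roc = RocResult(thresholds, sens, spec, float(auc), ci, direction)
    cutoff, j, sens_at, spec_at = _youden(roc)
    roc.youden_cutoff, roc.youden_j = cutoff, j
    return roc


def _youden(roc: RocResult) -> tuple[float, float, float, float]:
    j = roc.sensitivities + roc.specificities - 1.0
    jmax = j.max()
    tied = np.flatnonzero(np.isclose(j, jmax))
    # higher specificity first, then higher threshold on the internal scale
    internal_t = roc.thresholds if roc.direction == "higher_positive" else -roc.thresholds
    best = max(tied, key=lambda i: (roc.specificities[i], internal_t[i]))
    return (float(roc.thresholds[best]), float(jmax),
            float(roc.sensitivities[best]), float(roc.specificities[best]))


def youden_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Return (cutoff, sensitivity, specificity) at the Youden-optimal point."""
    cutoff, _, sens_at, spec_at = _youden(roc)
    return cutoff, sens_at, spec_at


def delong_auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong 95% CI for the empirical AUC (higher score = positive)."""
    y = _as_binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    # structural components: V10_i = P-hat(pos_i beats a negative), etc.
    cmp_matrix = (pos[:, None] > neg[None, :]).astype(float)
    cmp_matrix += 0.5 * (pos[:, None] == neg[None, :])
    auc = cmp_matrix.mean()
    v10 = cmp_matrix.mean(axis=1)
    v01 = cmp_matrix.mean(axis=0)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def fit_logistic(
    features,
    labels,
    l2: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-10,
    separation_bound: float = 50.0,
) -> LogisticModel:
    """Penalized maximum-likelihood logistic regression (Newton iterations).

    A small L2 penalty (default 1e-6, not applied to the intercept)
    stabilizes the perfectly- or quasi-separated regimes that strong
    biomarkers produce; ``separation_detected`` flags any coefficient whose
    magnitude exceeds ``separation_bound``. Zero-variance features get a
    warning and a zero coefficient.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary_labels(labels).astype(float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    n, p = X.shape

    active = np.std(X, axis=0) > 0
    if not active.all():
        warnings.warn(
            f"{int((~active).sum())} zero-variance feature(s); coefficients set to 0",
            stacklevel=2,
        )
    Xa = X[:, active]
    pa = Xa.shape[1]

    beta = np.zeros(pa + 1)  # [intercept, coefs]
    design = np.column_stack([np.ones(n), Xa])
    penalty = np.full(pa + 1, l2)
    penalty[0] = 0.0

    def negloglik(b):
        eta = design @ b
        # log(1 + exp(eta)) - y*eta, numerically stable
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta)
                     + 0.5 * np.sum(penalty * b * b))

    prev = negloglik(beta)
    converged = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = design.T @ (mu - y) + penalty * beta
        hess = (design * w[:, None]).T @ design + np.diag(penalty + 1e-12)
        step = np.linalg.solve(hess, grad)
        # damped Newton: halve until the penalized deviance does not increase
        lam = 1.0
        for _ in range(30):
            cand = beta - lam * step
            cur = negloglik(cand)
            if cur <= prev + 1e-12:
                break
            lam *= 0.5
        beta = beta - lam * step
        cur = negloglik(beta)
        if abs(prev - cur) < tol:
            converged = True
            prev = cur
            break
        prev = cur

    coefs = np.zeros(p)
    coefs[active] = beta[1:]
    separation = bool(np.any(np.abs(beta) > separation_bound))
    return LogisticModel(float(beta[0]), coefs, converged, separation)


def sens_spec(calls, labels, level: float = 0.95) -> SensSpecResult:
    """Sensitivity and specificity with exact (Clopper-Pearson) CIs."""
    y = _as_binary_labels(labels)
    c = _as_binary_labels(calls)
    if c.shape != y.shape:
        raise ValueError("calls and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    tp = int(((c == 1) & (y == 1)).sum())
    fn = int(((c == 0) & (y == 1)).sum())
    tn = int(((c == 0) & (y == 0)).sum())
    fp = int(((c == 1) & (y == 0)).sum())
    return SensSpecResult(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        sensitivity_ci=_clopper_pearson(tp, tp + fn, level),
        specificity_ci=_clopper_pearson(tn, tn + fp, level),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def group_comparison(*groups, test: str = "kruskal"):
    """Thin convenience wrapper over standard group-comparison tests
    (``kruskal`` for >2 groups, ``ttest`` for a two-sided two-sample t test).
    Returns (statistic, p_value)."""
    if test == "kruskal":
        res = stats.kruskal(*groups)
    elif test == "ttest":
        if len(groups) != 2:
            raise ValueError("ttest requires exactly two groups")
        res = stats.ttest_ind(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
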