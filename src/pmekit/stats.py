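"""Self-contained statistical kernel used by every downstream analysis stage.

Implements the estimators the peritumor-microenvironment pipeline relies on:
ROC/AUC with Youden threshold selection, the Kaplan-Meier product-limit
estimator, the two-group log-rank test, Cox proportional-hazards regression
(Breslow tie handling), logistic regression via IRLS, Fisher's exact and
Pearson chi-square contingency tests, and Pearson/Spearman correlation.

Only scipy distribution functions are used for tail probabilities; the
statistics themselves are computed here so that every quantity reported by
the pipeline has a single, inspectable definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SurvivalData",
    "RocResult",
    "KaplanMeierResult",
    "LogrankResult",
    "CoxResult",
    "LogisticResult",
    "roc_auc",
    "auc_many",
    "km_estimate",
    "logrank_test",
    "logrank_test_permutation",
    "cox_fit",
    "logistic_fit",
    "fisher_exact",
    "chi_square_test",
    "correlation",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival outcomes.

    time : follow-up in days, strictly positive.
    event : 1 if death observed at ``time``, 0 if censored there.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.ndim != 1 or event.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if time.size == 0:
            raise ValueError("empty survival data")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be finite and strictly positive")
        if not np.all(np.isin(event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    def __len__(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, mask) -> "SurvivalData":
        mask = np.asarray(mask, dtype=bool)
        return SurvivalData(self.time[mask], self.event[mask])


@dataclass(frozen=True)
class RocResult:
    """ROC curve summary: AUC, the Youden-optimal operating point, and the curve."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    curve_points: np.ndarray  # ordered (FPR, TPR) pairs, (0,0) ... (1,1)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class KaplanMeierResult:
    """Product-limit survival estimate over the distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None    # earliest time with S(t) <= 0.5; None if never reached

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    #: observed minus expected events in group A; > 0 means group A dies more
    o_minus_e_a: float = 0.0


@dataclass(frozen=True)
class CoxResult:
    coef: np.ndarray
    se: np.ndarray
    linear_predictor: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    flagged: bool = False           # non-convergence or monotone likelihood
    flag_reason: str = ""


@dataclass(frozen=True)
class LogisticResult:
    intercept: float
    coef: np.ndarray
    fitted: np.ndarray              # predicted probabilities, in (0,1)
    n_iter: int
    converged: bool
    flagged: bool = False
    flag_reason: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.intercept + X @ self.coef
        return np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> RocResult:
    """ROC analysis of a score against a binary label.

    The AUC is the Mann-Whitney probability that a positive outranks a
    negative, ties counted 1/2.  The reported operating point maximizes
    Youden's J = sensitivity + specificity - 1; ties are broken toward
    higher specificity.  A subject is called positive when score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("degenerate labels: both classes must be present")

    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # Curve: sweep thresholds from high to low over the distinct scores.
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_labels.size - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    tpr = tps / n1
    fpr = fps / n0
    curve = np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])

    j = tpr - fpr
    best = int(np.argmax(j))  # first maximum = highest threshold = highest specificity
    return RocResult(
        auc=float(auc),
        threshold=float(sorted_scores[distinct][best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        curve_points=curve,
    )


def auc_many(matrix: np.ndarray, labels) -> np.ndarray:
    """Row-wise Mann-Whitney AUC of a (features x subjects) matrix vs a binary label."""
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("degenerate labels: both classes must be present")
    ranks = sps.rankdata(matrix, axis=1)
    return (ranks[:, labels == 1].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def km_estimate(surv: SurvivalData) -> KaplanMeierResult:
    """Kaplan-Meier product-limit estimator.

    The median is the earliest event time where S(t) drops to 0.5 or below;
    if the curve never reaches 0.5 the median is reported as not reached
    (``None``).
    """
    event_times = np.unique(surv.time[surv.event == 1])
    surv_prob = []
    at_risk = []
    n_ev = []
    s = 1.0
    for t in event_times:
        n = int(np.sum(surv.time >= t))
        d = int(np.sum((surv.time == t) & (surv.event == 1)))
        s *= 1.0 - d / n
        surv_prob.append(s)
        at_risk.append(n)
        n_ev.append(d)
    surv_prob = np.asarray(surv_prob)
    median = None
    reached = np.nonzero(surv_prob <= 0.5 + 1e-12)[0]
    if reached.size:
        median = float(event_times[reached[0]])
    return KaplanMeierResult(
        times=event_times,
        survival=surv_prob,
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        median=median,
    )


def _logrank_parts(time, event, group) -> tuple[float, float]:
    """O-E for the ``group`` arm and its hypergeometric variance."""
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d1 = int((dying & group).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var


def _logrank_statistic(time, event, group) -> float:
    """O-E log-rank chi-square with hypergeometric variance at each event time."""
    o_minus_e, var = _logrank_parts(time, event, group)
    if var == 0.0:
        return 0.0
    return o_minus_e**2 / var


def logrank_test(group_a: SurvivalData, group_b: SurvivalData) -> LogrankResult:
    """Two-group log-rank test; p from a 1-df chi-square approximation."""
    if group_a.n_events + group_b.n_events == 0:
        raise ValueError("no events: log-rank test undefined")
    time = np.r_[group_a.time, group_b.time]
    event = np.r_[group_a.event, group_b.event]
    group = np.r_[np.ones(len(group_a), bool), np.zeros(len(group_b), bool)]
    o_minus_e, var = _logrank_parts(time, event, group)
    stat = o_minus_e**2 / var if var > 0 else 0.0
    p = float(sps.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return LogrankResult(statistic=float(stat), p_value=p, o_minus_e_a=float(o_minus_e))


def logrank_test_permutation(
    group_a: SurvivalData, group_b: SurvivalData, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation-null p-value for the log-rank statistic (group labels shuffled)."""
    time = np.r_[group_a.time, group_b.time]
    event = np.r_[group_a.event, group_b.event]
    group = np.r_[np.ones(len(group_a), bool), np.zeros(len(group_b), bool)]
    observed = _logrank_statistic(time, event, group)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(group)
        if _logrank_statistic(time, event, perm) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def cox_fit(
    covariates: np.ndarray,
    surv: SurvivalData,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Cox partial-likelihood fit, Breslow handling of tied event times.

    Newton-Raphson from beta = 0 with step halving, stopping when the
    gradient norm falls below ``tol``.  Monotone likelihood (perfect
    separation of risk) and non-convergence are flagged on the result
    rather than raised, so callers can report them.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(surv):
        X = X.T
    n, p = X.shape
    if n != len(surv):
        raise ValueError("covariate rows must match number of subjects")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate column")
    if surv.n_events < p:
        raise ValueError("fewer events than covariates")

    time, event = surv.time, surv.event
    event_times = np.unique(time[event == 1])
    # Precompute risk-set and death-set masks per distinct event time.
    risk_masks = [time >= t for t in event_times]
    death_masks = [(time == t) & (event == 1) for t in event_times]

    def loglik_grad_hess(beta):
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
        w = np.exp(eta)
        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for risk, death in zip(risk_masks, death_masks):
            d = int(death.sum())
            wr = w[risk]
            xr = X[risk]
            s0 = wr.sum()
            s1 = xr.T @ wr
            s2 = (xr * wr[:, None]).T @ xr
            xbar = s1 / s0
            ll += eta[death].sum() - d * np.log(s0)
            grad += X[death].sum(axis=0) - d * xbar
            hess -= d * (s2 / s0 - np.outer(xbar, xbar))
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            new_ll, new_grad, new_hess = loglik_grad_hess(candidate)
            if new_ll >= ll - 1e-12:
                beta, ll, grad, hess = candidate, new_ll, new_grad, new_hess
                break
            factor /= 2.0
        else:
            break
    else:
        n_iter = max_iter
    if not converged and np.linalg.norm(grad) < tol:
        converged = True

    flagged = False
    reason = ""
    if not converged:
        flagged = True
        reason = "non-convergence"

    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            flagged = True
            reason = reason or "singular information matrix"

    # A flat partial likelihood (monotone / perfect risk separation) shows up
    # as runaway coefficients or standard errors far larger than the estimate.
    if np.any(np.abs(beta) > 15) or np.any(~np.isfinite(se)) or np.any(se > 50 * (1 + np.abs(beta))):
        flagged = True
        reason = reason or "monotone likelihood (possible perfect separation)"

    return CoxResult(
        coef=beta,
        se=se,
        linear_predictor=X @ beta,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        flagged=flagged,
        flag_reason=reason,
    )


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

def _sigmoid(eta):
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logistic_fit(
    covariates: np.ndarray,
    labels,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> LogisticResult:
    """Maximum-likelihood logistic regression by IRLS (with intercept).

    Perfect separation manifests as diverging coefficients; the fit is then
    returned with ``flagged=True`` instead of raising.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    y = np.asarray(labels, dtype=float)
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n != y.size:
        raise ValueError("covariate rows must match number of labels")
    if y.min() == y.max():
        raise ValueError("degenerate labels: both classes must be present")

    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        grad = Xd.T @ (y - mu)
        hess = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            # singular information (e.g. a degenerate covariate): least-squares step
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    flagged = (not converged) or bool(np.max(np.abs(beta)) > 1e2)
    reason = ""
    if not converged:
        reason = "non-convergence"
    elif flagged:
        reason = "possible perfect separation"

    fitted = np.clip(_sigmoid(Xd @ beta), 1e-12, 1 - 1e-12)
    return LogisticResult(
        intercept=float(beta[0]),
        coef=beta[1:],
        fitted=fitted,
        n_iter=n_iter,
        converged=converged,
        flagged=flagged,
        flag_reason=reason,
    )


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, minimum-likelihood convention.

    p = sum of hypergeometric probabilities (margins fixed) of all tables no
    more probable than the observed one.  Degenerate margins give p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    a = t[0, 0]
    r1, r2 = t.sum(axis=1)
    c1, _c2 = t.sum(axis=0)
    n = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or _c2 == 0:
        return 1.0
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = sps.hypergeom.pmf(a, n, c1, r1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence for an R x C count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D non-negative count matrix")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df=df)) if df > 0 else 1.0
    return stat, df, p


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a t-approximation p-value.

    Spearman is Pearson on midranks.  Raises on fewer than 3 points or a
    zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("values must be finite")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    r = float(np.clip(((x - x.mean()) * (y - y.mean())).sum() / ((n - 1) * sx * sy), -1, 1))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * sps.t.sf(abs(tstat), df=n - 2))
    return r, p
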