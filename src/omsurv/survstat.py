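"""Survival-statistics kernel.

Everything downstream (feature screens, risk scoring, subtype survival
comparison) is built on the estimators in this module:

* Kaplan-Meier product-limit estimator,
* k-group log-rank test,
* Cox proportional-hazards fitting by Newton-Raphson on the Efron partial
  likelihood, with an optional L1 penalty solved by proximal-Newton
  coordinate descent (glmnet-style soft thresholding),
* Breslow baseline cumulative hazard,
* Harrell's concordance index,
* cumulative/dynamic time-dependent ROC with inverse-probability-of-censoring
  (censoring-KM) weights,
* equal-frequency calibration curve against within-bin Kaplan-Meier.

All functions take plain numpy arrays: ``time`` (non-negative), ``event``
(1 = event observed, 0 = censored) and, where relevant, a covariate matrix
``X`` of shape (n_samples, n_covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    CollinearityError,
    ConvergenceError,
    ParameterError,
    UndefinedResultError,
    UnfitError,
    ValidationError,
)

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxFit",
    "BaselineHazard",
    "TdRocResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "lasso_path",
    "lambda_max",
    "breslow_baseline",
    "concordance_index",
    "td_roc",
    "calibration_curve",
]


def _as_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValidationError("time and event must be 1-d arrays of equal length")
    if time.size == 0:
        raise ValidationError("at least one sample required")
    if np.any(time < 0) or np.any(~np.isfinite(time)):
        raise ValidationError("survival times must be finite and non-negative")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValidationError("event indicator must be 0 or 1")
    return time, ev.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """S(t): right-continuous step evaluation, S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Censored-only data yields an empty event-time grid (S identically 1).
    """
    time, event = _as_surv(time, event)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted, e_sorted = time[order], event[order]
    uniq, start = np.unique(t_sorted, return_index=True)
    ev_times, surv, at_risk, d_events = [], [], [], []
    s = 1.0
    counts = np.append(start, n)
    for i, t in enumerate(uniq):
        d = int(e_sorted[counts[i] : counts[i + 1]].sum())
        if d == 0:
            continue
        n_risk = n - counts[i]
        s *= 1.0 - d / n_risk
        ev_times.append(t)
        surv.append(s)
        at_risk.append(n_risk)
        d_events.append(d)
    return KMCurve(
        np.array(ev_times), np.array(surv), np.array(at_risk, dtype=int), np.array(d_events, dtype=int)
    )


def nelson_aalen(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Nelson-Aalen cumulative hazard: H(t) = sum_{t_i <= t} d_i / n_i."""
    curve = km_estimate(time, event)
    inc = curve.events / curve.at_risk
    return curve.event_times, np.cumsum(inc)


# ---------------------------------------------------------------------------
# Log-rank


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(time, event, groups) -> LogrankResult:
    """k-group log-rank chi-square test with df = k - 1.

    Zero observed events across all groups gives statistic 0, p = 1.
    """
    time, event = _as_surv(time, event)
    groups = np.asarray(groups)
    if groups.shape != time.shape:
        raise ValidationError("groups must align with samples")
    levels, codes = np.unique(groups, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValidationError("log-rank test requires at least two non-empty groups")

    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], codes[order]
    n = t_s.size
    uniq, start = np.unique(t_s, return_index=True)
    bounds = np.append(start, n)

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    # at-risk counts per group, decremented as samples leave the risk set
    n_g = np.bincount(g_s, minlength=k).astype(float)
    for i in range(uniq.size):
        sl = slice(bounds[i], bounds[i + 1])
        d_g = np.bincount(g_s[sl][e_s[sl] == 1], minlength=k).astype(float)
        d = d_g.sum()
        n_tot = n_g.sum()
        if d > 0:
            O += d_g
            E += n_g * d / n_tot
            if n_tot > 1:
                f = d * (n_tot - d) / (n_tot**2 * (n_tot - 1))
                V += f * (n_tot * np.diag(n_g) - np.outer(n_g, n_g))
        n_g -= np.bincount(g_s[sl], minlength=k)
    if O.sum() == 0:
        return LogrankResult(0.0, k - 1, 1.0)
    z = (O - E)[:-1]
    Vs = V[:-1, :-1]
    stat = float(z @ np.linalg.pinv(Vs) @ z)
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, k - 1))
    return LogrankResult(stat, k - 1, p)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    l1_penalty: float = 0.0
    ties: str = "efron"
    n_iter: int = 0
    converged: bool = True
    # columns held at zero because they carry no information (zero variance)
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)


def _efron_ll(X, time, event, beta, order=2):
    """Efron-approximation log partial likelihood with gradient and Hessian.

    Returns (ll, grad, hess); grad/hess are None when not requested via
    ``order``. Hessian is the actual second derivative (negative semidefinite).
    """
    n, p = X.shape
    eta = X @ beta
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)

    srt = np.argsort(time, kind="stable")  # ascending time
    ts, es = time[srt], event[srt]
    Xs, ws, etas = X[srt], w[srt], eta[srt]
    # suffix sums over the risk set {j : t_j >= t_i}
    S0s = np.cumsum(ws[::-1])[::-1]
    WX = ws[:, None] * Xs
    S1s = np.cumsum(WX[::-1], axis=0)[::-1] if order >= 1 else None
    S2s = (
        np.cumsum(np.einsum("ij,ik->ijk", WX, Xs)[::-1], axis=0)[::-1]
        if order >= 2
        else None
    )
    uniq, start = np.unique(ts, return_index=True)
    bounds = np.append(start, n)

    ll = 0.0
    grad = np.zeros(p) if order >= 1 else None
    hess = np.zeros((p, p)) if order >= 2 else None
    for i in range(uniq.size):
        sl = slice(bounds[i], bounds[i + 1])
        ev = np.flatnonzero(es[sl] == 1) + bounds[i]
        d = ev.size
        if d == 0:
            continue
        S0 = S0s[bounds[i]]
        Xd = Xs[ev]
        wd = ws[ev]
        s0d = wd.sum()
        ll += etas[ev].sum() - shift * d
        if order >= 1:
            S1 = S1s[bounds[i]]
            s1d = wd @ Xd
            grad += Xd.sum(axis=0)
        if order >= 2:
            S2 = S2s[bounds[i]]
            s2d = Xd.T @ (wd[:, None] * Xd)
        for l in range(d):
            f = l / d
            phi = S0 - f * s0d
            ll -= np.log(phi)
            if order >= 1:
                z1 = S1 - f * s1d
                grad -= z1 / phi
                if order >= 2:
                    hess -= (S2 - f * s2d) / phi - np.outer(z1, z1) / phi**2
    return ll, grad, hess


def cox_fit(
    X,
    time,
    event,
    l1_penalty: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    init: np.ndarray | None = None,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by maximizing the Efron partial
    likelihood.

    With ``l1_penalty`` = 0 the fit is Newton-Raphson with step halving, to a
    gradient max-norm below ``tol``. With ``l1_penalty`` > 0 the objective is
    ll(beta)/n - l1_penalty * sum|beta| (glmnet scaling), solved by
    proximal-Newton coordinate descent; standard errors and p-values are only
    reported for the unpenalized fit.

    Zero-variance covariates are held at coefficient 0 with p = 1 so that
    genome-wide univariate screens never abort on a flat feature.
    """
    time, event = _as_surv(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n != time.size:
        raise ValidationError("X rows must align with samples")
    if np.isnan(X).any():
        raise ValidationError("covariate matrix contains missing values")
    if n < 2:
        raise UnfitError("need at least two samples")
    if event.sum() == 0:
        raise UnfitError("no observed events: partial likelihood is uninformative")
    if l1_penalty < 0:
        raise ParameterError("l1_penalty must be >= 0")

    degenerate = X.std(axis=0) == 0.0
    active = ~degenerate
    Xa = X[:, active]
    pa = Xa.shape[1]
    beta_a = np.zeros(pa)
    if init is not None:
        beta_a = np.asarray(init, dtype=float)[active].copy()

    if pa == 0:
        ll0, _, _ = _efron_ll(np.zeros((n, 0)), time, event, np.zeros(0))
        return CoxFit(
            coef=np.zeros(p), se=np.full(p, np.inf), z=np.zeros(p),
            p_values=np.ones(p), log_likelihood=ll0, l1_penalty=l1_penalty,
            degenerate=degenerate,
        )

    if l1_penalty == 0.0:
        beta_a, ll, hess, n_iter = _newton(Xa, time, event, beta_a, max_iter, tol)
        se_a, z_a, p_a = _wald(hess, beta_a)
    else:
        beta_a, ll, n_iter = _l1_coordinate_descent(
            Xa, time, event, beta_a, n * l1_penalty, max_iter
        )
        se_a = np.full(pa, np.nan)
        z_a = np.full(pa, np.nan)
        p_a = np.full(pa, np.nan)

    coef = np.zeros(p)
    coef[active] = beta_a
    se = np.full(p, np.inf)
    z = np.zeros(p)
    pv = np.ones(p)
    se[active], z[active], pv[active] = se_a, z_a, p_a
    return CoxFit(
        coef=coef, se=se, z=z, p_values=pv, log_likelihood=float(ll),
        l1_penalty=l1_penalty, n_iter=n_iter, degenerate=degenerate,
    )


def _newton(X, time, event, beta, max_iter, tol):
    ll, grad, hess = _efron_ll(X, time, event, beta)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            return beta, ll, hess, it - 1
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise CollinearityError(
                "singular information matrix: collinear covariates", _collinear_cols(X)
            )
        # step halving on likelihood decrease; tolerance relative to |ll|
        # so float-level plateau noise near the optimum is accepted
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _efron_ll(X, time, event, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * (1.0 + abs(ll)):
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step halving failed to improve likelihood", beta)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    if np.max(np.abs(grad)) < np.sqrt(tol):
        # close enough for screening purposes; flag via iteration count
        return beta, ll, hess, max_iter
    raise ConvergenceError(
        f"Newton iteration did not converge in {max_iter} steps", beta
    )


def _wald(hess, beta):
    try:
        cov = np.linalg.inv(-hess)
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        var = np.full(beta.size, np.inf)
    var[var <= 0] = np.inf
    se = np.sqrt(var)
    with np.errstate(invalid="ignore"):
        z = np.where(np.isfinite(se), beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return se, z, p


def _collinear_cols(X):
    # name columns whose removal restores full rank
    r = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        keep = [c for c in range(X.shape[1]) if c != j]
        if np.linalg.matrix_rank(X[:, keep]) == r:
            bad.append(j)
    return bad


def _soft(x, t):
    return np.sign(x) * max(abs(x) - t, 0.0)


def _l1_coordinate_descent(X, time, event, beta, penalty, max_outer):
    """Proximal Newton: quadratic expansion of the Efron log-likelihood at the
    current iterate, inner coordinate descent with soft thresholding."""
    n, p = X.shape
    beta = beta.copy()
    for outer in range(1, max_outer + 1):
        ll, grad, hess = _efron_ll(X, time, event, beta)
        A = -hess  # positive semidefinite curvature
        diag = np.clip(np.diag(A).copy(), 1e-10, None)
        b = beta.copy()
        for _ in range(200):
            delta = 0.0
            for j in range(p):
                # partial derivative of the smooth quadratic model wrt b_j
                gj = -grad[j] + A[j] @ (b - beta)
                aj = gj - diag[j] * b[j]
                new = _soft(-aj, penalty) / diag[j]
                delta = max(delta, abs(new - b[j]))
                b[j] = new
            if delta < 1e-10:
                break
        if np.max(np.abs(b - beta)) < 1e-9:
            beta = b
            break
        beta = b
    ll, _, _ = _efron_ll(X, time, event, beta, order=0)
    return beta, ll, outer


def lambda_max(X, time, event) -> float:
    """Smallest penalty (glmnet scale) for which the L1-Cox solution is all-zero."""
    time, event = _as_surv(time, event)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    _, grad, _ = _efron_ll(X, time, event, np.zeros(X.shape[1]), order=1)
    return float(np.max(np.abs(grad)) / n)


def lasso_path(
    X,
    time,
    event,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 50,
    eps: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-Cox regularization path, warm-started along a decreasing lambda grid.

    Returns (lambdas, coefs) with coefs of shape (len(lambdas), n_features).
    When ``lambdas`` is None a log-spaced grid from lambda_max down to
    eps * lambda_max is generated.
    """
    X = np.asarray(X, dtype=float)
    if lambdas is None:
        lmax = lambda_max(X, time, event)
        if lmax <= 0:
            lmax = 1e-3
        lambdas = np.geomspace(lmax, eps * lmax, n_lambdas)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) > 0):
            raise ParameterError("lambda sequence must be decreasing")
    coefs = np.zeros((lambdas.size, X.shape[1]))
    beta = None
    for i, lam in enumerate(lambdas):
        fit = cox_fit(X, time, event, l1_penalty=float(lam), init=beta)
        beta = fit.coef
        coefs[i] = beta
    return lambdas, coefs


# ---------------------------------------------------------------------------
# Breslow baseline hazard


@dataclass
class BaselineHazard:
    """Step-function cumulative baseline hazard H0(t), H0(0) = 0."""

    times: np.ndarray
    cumhaz: np.ndarray

    def at(self, t: float | np.ndarray) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        h = np.concatenate([[0.0], self.cumhaz])
        return h[idx]

    @property
    def max_time(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0


def breslow_baseline(beta, X, time, event) -> BaselineHazard:
    """Breslow estimator H0(t) = sum_{t_i <= t} d_i / sum_{j in R(t_i)} exp(eta_j).

    With beta = 0 this reduces to the Nelson-Aalen cumulative hazard.
    """
    time, event = _as_surv(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = X @ np.asarray(beta, dtype=float)
    w = np.exp(eta - eta.max())
    scale = np.exp(eta.max())

    order = np.argsort(time, kind="stable")
    t_s, e_s, w_s = time[order], event[order], w[order]
    n = t_s.size
    uniq, start = np.unique(t_s, return_index=True)
    bounds = np.append(start, n)
    # suffix sums of weights = risk-set weight at each distinct time
    suffix = np.concatenate([np.cumsum(w_s[::-1])[::-1], [0.0]])
    times, cumhaz = [], []
    h = 0.0
    for i, t in enumerate(uniq):
        d = e_s[bounds[i] : bounds[i + 1]].sum()
        if d == 0:
            continue
        h += d / (suffix[bounds[i]] * scale)
        times.append(t)
        cumhaz.append(h)
    return BaselineHazard(np.array(times), np.array(cumhaz))


# ---------------------------------------------------------------------------
# Concordance


def concordance_index(scores, time, event) -> float:
    """Harrell's c-index: fraction of comparable pairs ordered concordantly.

    A pair is comparable when the sample with the shorter observed time had
    the event (ties in time: event vs censored is comparable, event vs event
    is not). Higher score is taken to mean higher risk (earlier event). Tied
    scores count 1/2.
    """
    time, event = _as_surv(time, event)
    s = np.asarray(scores, dtype=float)
    if s.shape != time.shape:
        raise ValidationError("one score per sample required")
    ti = time[:, None]
    tj = time[None, :]
    ei = event[:, None].astype(bool)
    ej = event[None, :].astype(bool)
    comparable = ei & ((ti < tj) | ((ti == tj) & ~ej))
    n_comp = comparable.sum()
    if n_comp == 0:
        raise UndefinedResultError("no comparable pairs")
    si = s[:, None]
    sj = s[None, :]
    conc = (comparable & (si > sj)).sum() + 0.5 * (comparable & (si == sj)).sum()
    return float(conc / n_comp)


# ---------------------------------------------------------------------------
# Time-dependent ROC


@dataclass
class TdRocResult:
    horizon: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def td_roc(scores, time, event, horizon: float) -> TdRocResult:
    """Cumulative/dynamic time-dependent ROC at ``horizon``.

    Cases are samples with an observed event by the horizon, controls are
    samples still event-free past it. Censoring is handled with inverse
    probability-of-censoring weights from the Kaplan-Meier estimate of the
    censoring distribution; with no censoring this is exactly the binary ROC
    for the label "event by horizon".
    """
    time, event = _as_surv(time, event)
    s = np.asarray(scores, dtype=float)
    if s.shape != time.shape:
        raise ValidationError("one score per sample required")
    g_curve = km_estimate(time, 1 - event)  # censoring survival G(t)

    is_case = (time <= horizon) & (event == 1)
    is_control = time > horizon
    if not is_case.any() or not is_control.any():
        raise UndefinedResultError("tdROC needs at least one case and one control at the horizon")

    w = np.zeros(time.size)
    # G evaluated just before the case's event time (left limit)
    g_case = np.asarray(g_curve.survival_at(np.nextafter(time[is_case], -np.inf)))
    g_case = np.clip(g_case, 1e-12, None)
    w[is_case] = 1.0 / g_case
    g_h = max(float(g_curve.survival_at(horizon)), 1e-12)
    w[is_control] = 1.0 / g_h

    thresholds = np.unique(s)[::-1]
    case_w = w * is_case
    ctrl_w = w * is_control
    tot_case = case_w.sum()
    tot_ctrl = ctrl_w.sum()
    tpr = [0.0]
    fpr = [0.0]
    for c in thresholds:
        above = s >= c
        tpr.append(case_w[above].sum() / tot_case)
        fpr.append(ctrl_w[above].sum() / tot_ctrl)
    tpr.append(1.0)
    fpr.append(1.0)
    fpr_a = np.array(fpr)
    tpr_a = np.array(tpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return TdRocResult(horizon=float(horizon), fpr=fpr_a, tpr=tpr_a, auc=auc)


# ---------------------------------------------------------------------------
# Calibration


def calibration_curve(pred_surv, time, event, horizon: float, n_bins: int = 5):
    """Equal-frequency calibration pairs (mean predicted, KM-observed survival
    at the horizon).

    Bins where the within-bin KM curve does not reach the horizon report the
    observed value as NaN (flagged missing). Identical predictions collapse to
    a single bin.
    """
    time, event = _as_surv(time, event)
    p = np.asarray(pred_surv, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("predicted survival probabilities must lie in [0, 1]")
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    order = np.argsort(p, kind="stable")
    if np.unique(p).size == 1:
        chunks = [order]
    else:
        chunks = np.array_split(order, n_bins)
    pairs = []
    for idx in chunks:
        if idx.size == 0:
            continue
        mean_pred = float(p[idx].mean())
        if horizon > time[idx].max():
            pairs.append((mean_pred, np.nan))
            continue
        km = km_estimate(time[idx], event[idx])
        pairs.append((mean_pred, float(km.survival_at(horizon))))
    return pairs
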