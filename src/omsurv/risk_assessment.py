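"""Cox risk scoring: radscore, horizon survival prediction, nomogram, CV metrics.

The risk score ("radscore") of a sample is the linear combination
``sum_j beta_j x_ij`` from a multivariate Cox fit on the selected features.
Survival at a horizon t is predicted via the Breslow baseline:
``S_i(t) = exp(-H0(t)) ** exp(eta_i)`` with covariates mean-centered as
during fitting, so H0 refers to the average sample. The nomogram converts
feature values to points on a 0-100 scale — the feature with the largest
|beta| x range spans the full scale — and maps total points back to
predicted survival probability per horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survstat
from .errors import ParameterError, ValidationError
from .feature_selection import _stratified_folds
from .tabular_io import OmicsClinicalTable

DEFAULT_HORIZONS = (6.0, 12.0)  # in the table's time unit; primary default 6


@dataclass
class RiskModel:
    feature_ids: list[str]
    beta: np.ndarray
    center: np.ndarray  # feature means used for centering
    baseline: survstat.BaselineHazard
    horizons: tuple[float, ...]
    radscore: pd.Series
    surv_probs: pd.DataFrame  # samples x horizons
    cox: survstat.CoxFit

    def to_risk_table(self) -> pd.DataFrame:
        out = pd.DataFrame({"radscore": self.radscore})
        for h in self.horizons:
            out[f"S({h:g})"] = self.surv_probs[h]
        return out


def compute_radscore(beta, X) -> np.ndarray:
    """radscore_i = sum_j beta_j x_ij."""
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != beta.size:
        raise ValidationError(
            f"dimension mismatch: {X.shape[1]} features vs {beta.size} coefficients"
        )
    return X @ beta


def fit_risk_model(
    table: OmicsClinicalTable,
    feature_ids: list[str] | None = None,
    horizons: tuple[float, ...] = DEFAULT_HORIZONS,
) -> RiskModel:
    """Multivariate Cox fit on the given features plus Breslow baseline and
    per-sample radscore / horizon survival probabilities."""
    feats = list(feature_ids) if feature_ids is not None else table.feature_ids
    sub = table.subset_features(feats)
    X = sub.features.to_numpy(dtype=float)
    time = sub.time.to_numpy(dtype=float)
    event = sub.event.to_numpy()
    fit = survstat.cox_fit(X, time, event)
    center = X.mean(axis=0)
    baseline = survstat.breslow_baseline(fit.coef, X - center, time, event)
    rad = compute_radscore(fit.coef, X)
    model = RiskModel(
        feature_ids=feats,
        beta=fit.coef,
        center=center,
        baseline=baseline,
        horizons=tuple(float(h) for h in horizons),
        radscore=pd.Series(rad, index=sub.features.index, name="radscore"),
        surv_probs=pd.DataFrame(index=sub.features.index),
        cox=fit,
    )
    for h in model.horizons:
        model.surv_probs[h] = predict_survival(model, X, h)
    return model


def predict_survival(model: RiskModel, X, horizon: float) -> np.ndarray:
    """S_i(t) = exp(-H0(t) * exp(beta . (x_i - center))).

    Horizons beyond the last baseline step return the value at the last step
    with an extrapolation warning.
    """
    if horizon < 0:
        raise ParameterError("horizon must be >= 0")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if horizon > model.baseline.max_time:
        warnings.warn(
            f"horizon {horizon:g} beyond last baseline step {model.baseline.max_time:g}; "
            "using the last step value",
            stacklevel=2,
        )
        horizon = model.baseline.max_time
    h0 = float(model.baseline.at(horizon))
    eta = (X - model.center) @ model.beta
    return np.exp(-h0 * np.exp(eta))


@dataclass
class NomogramTable:
    """Per-feature point scales plus the total-points -> survival mapping."""

    feature_points: pd.DataFrame  # feature, value, points
    total_to_prob: pd.DataFrame  # total_points, plus one S(h) column per horizon
    max_points_per_feature: pd.Series


def build_nomogram(
    model: RiskModel,
    table: OmicsClinicalTable | None = None,
    horizons: tuple[float, ...] | None = None,
    n_grid: int = 11,
) -> NomogramTable:
    """Point system: points_j(x) = 100 |beta_j| |x - x0_j| / max_k(|beta_k| range_k),
    with x0_j the lowest-risk end of feature j's observed range. Total points
    map to survival probability through the radscore axis."""
    if np.all(model.beta == 0):
        raise ValidationError("all coefficients are zero: nothing to chart")
    horizons = tuple(horizons) if horizons is not None else model.horizons
    if table is not None:
        sub = table.subset_features(model.feature_ids)
        lo = sub.features.min().to_numpy(dtype=float)
        hi = sub.features.max().to_numpy(dtype=float)
    else:
        # fall back to the centering statistics' implied spread
        raise ValidationError("observed feature ranges (a table) are required")
    rng_span = hi - lo
    if np.any(rng_span <= 0):
        bad = [f for f, s in zip(model.feature_ids, rng_span) if s <= 0]
        raise ValidationError(f"degenerate feature ranges: {bad}")
    weight = np.abs(model.beta) * rng_span
    M = weight.max()
    # lowest-risk endpoint: min for beta > 0, max for beta < 0
    x0 = np.where(model.beta >= 0, lo, hi)

    rows = []
    for j, feat in enumerate(model.feature_ids):
        grid = np.linspace(lo[j], hi[j], n_grid)
        pts = 100.0 * np.abs(model.beta[j]) * np.abs(grid - x0[j]) / M
        for v, p in zip(grid, pts):
            rows.append({"feature": feat, "value": v, "points": p})
    feature_points = pd.DataFrame(rows)
    max_pts = pd.Series(100.0 * weight / M, index=model.feature_ids)

    # total points are affine in radscore: rad = rad0 + T * M / 100
    rad0 = float(model.beta @ x0)
    totals = np.linspace(0.0, max_pts.sum(), 50)
    mapping = {"total_points": totals}
    for h in horizons:
        h_eff = min(h, model.baseline.max_time)
        h0 = float(model.baseline.at(h_eff))
        eta = rad0 + totals * M / 100.0 - float(model.beta @ model.center)
        mapping[f"S({h:g})"] = np.exp(-h0 * np.exp(eta))
    return NomogramTable(
        feature_points=feature_points,
        total_to_prob=pd.DataFrame(mapping),
        max_points_per_feature=max_pts,
    )


@dataclass
class CVResult:
    fold_cindex: list[float]
    fold_auc: list[float]
    pooled_cindex: float
    pooled_auc: float
    horizon: float
    n_folds: int
    seed: int
    oof_radscore: pd.Series = field(repr=False, default=None)


def cross_validate(
    table: OmicsClinicalTable,
    feature_ids: list[str] | None = None,
    n_folds: int = 5,
    horizon: float = 6.0,
    seed: int = 0,
) -> CVResult:
    """Event-stratified k-fold CV of the risk model.

    Out-of-fold radscores are pooled; the concordance index and tdROC AUC at
    the horizon are computed on the pooled predictions, plus per-fold values
    where defined. Deterministic per seed.
    """
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    feats = list(feature_ids) if feature_ids is not None else table.feature_ids
    sub = table.subset_features(feats)
    X = sub.features.to_numpy(dtype=float)
    time = sub.time.to_numpy(dtype=float)
    event = sub.event.to_numpy()
    folds = _stratified_folds(event, n_folds, seed)
    oof = np.full(len(time), np.nan)
    fold_c, fold_a = [], []
    for k in range(n_folds):
        tr = folds != k
        te = ~tr
        if event[tr].sum() == 0:
            raise ValidationError("a training fold has no events")
        fit = survstat.cox_fit(X[tr], time[tr], event[tr])
        oof[te] = X[te] @ fit.coef
        try:
            fold_c.append(survstat.concordance_index(oof[te], time[te], event[te]))
        except survstat.UndefinedResultError:
            fold_c.append(np.nan)
        try:
            fold_a.append(survstat.td_roc(oof[te], time[te], event[te], horizon).auc)
        except survstat.UndefinedResultError:
            fold_a.append(np.nan)
    pooled_c = survstat.concordance_index(oof, time, event)
    pooled_a = survstat.td_roc(oof, time, event, horizon).auc
    return CVResult(
        fold_cindex=fold_c,
        fold_auc=fold_a,
        pooled_cindex=float(pooled_c),
        pooled_auc=float(pooled_a),
        horizon=float(horizon),
        n_folds=n_folds,
        seed=seed,
        oof_radscore=pd.Series(oof, index=sub.features.index, name="oof_radscore"),
    )
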