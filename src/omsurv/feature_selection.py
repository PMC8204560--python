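"""Survival-based feature screening and the sequential chaining engine.

Five screening operators are provided — three single-factor (pairwise
correlation redundancy filter, univariate Cox, median-split log-rank) and
two multi-factor (joint multivariate Cox, cross-validated Lasso-Cox) — and a
chain runner that applies each screen to the survivors of the previous one,
recording a full trace.

The correlation screen is a redundancy filter between features (not a
correlation-with-outcome test): among each pair with |Pearson r| above the
threshold the lower-variance member is dropped, greedily in descending-|r|
order, so no surviving pair exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survstat
from .errors import OmsurvError, ParameterError, ValidationError
from .tabular_io import OmicsClinicalTable

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "correlation_filter",
    "univariate_cox_screen",
    "logrank_screen",
    "multivariate_cox_screen",
    "lasso_screen",
    "run_selection_chain",
]


@dataclass
class SelectionStep:
    method: str
    params: dict
    input_features: list[str]
    survivors: list[str]
    statistics: pd.DataFrame  # one row per input feature
    warnings: list[str] = field(default_factory=list)

    @property
    def n_in(self) -> int:
        return len(self.input_features)

    @property
    def n_out(self) -> int:
        return len(self.survivors)


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    status: str = "complete"  # "complete" | "empty_result"

    @property
    def final_features(self) -> list[str]:
        return self.steps[-1].survivors if self.steps else []

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, st in enumerate(self.steps):
            stats = st.statistics
            for feat in st.input_features:
                row = {
                    "step": i,
                    "method": st.method,
                    "feature": feat,
                    "kept": feat in st.survivors,
                }
                if feat in stats.index:
                    for c in stats.columns:
                        row[c] = stats.loc[feat, c]
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> list[dict]:
        return [
            {
                "step": i,
                "method": st.method,
                "params": st.params,
                "n_in": st.n_in,
                "n_out": st.n_out,
                "warnings": st.warnings,
            }
            for i, st in enumerate(self.steps)
        ]


def correlation_filter(table: OmicsClinicalTable, r_threshold: float = 0.7) -> SelectionStep:
    """Pairwise-redundancy filter: drop the lower-variance member of every
    feature pair with |Pearson r| > r_threshold, processed in descending-|r|
    order. Survivors contain no remaining pair above the threshold."""
    if not (0.0 < r_threshold <= 1.0):
        raise ParameterError("r_threshold must lie in (0, 1]")
    feats = table.feature_ids
    if len(feats) < 2:
        raise ValidationError("correlation filter needs at least two features")
    X = table.features
    var = X.var(ddof=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns give NaN r
        R = np.corrcoef(X.to_numpy(), rowvar=False)
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    iu = np.triu_indices(len(feats), k=1)
    order = np.argsort(-np.abs(R[iu]), kind="stable")
    removed: dict[str, str] = {}
    for k in order:
        i, j = iu[0][k], iu[1][k]
        r = abs(R[i, j])
        if r <= r_threshold:
            break
        fi, fj = feats[i], feats[j]
        if fi in removed or fj in removed:
            continue
        # drop the lower-variance member; tie -> keep the first-listed feature
        loser, winner = (fi, fj) if var.iloc[i] < var.iloc[j] else (fj, fi)
        removed[loser] = winner
    survivors = [f for f in feats if f not in removed]
    stats = pd.DataFrame(
        {
            "variance": var,
            "removed_for": [removed.get(f, "") for f in feats],
        },
        index=feats,
    )
    return SelectionStep(
        method="correlation",
        params={"r_threshold": r_threshold},
        input_features=list(feats),
        survivors=survivors,
        statistics=stats,
    )


def univariate_cox_screen(table: OmicsClinicalTable, alpha: float = 0.05) -> SelectionStep:
    """Single-feature Cox fits; survivors have Wald p < alpha."""
    _check_alpha(alpha)
    time = table.time.to_numpy(dtype=float)
    event = table.event.to_numpy()
    rows, survivors, warns = {}, [], []
    for feat in table.feature_ids:
        x = table.features[feat].to_numpy(dtype=float)
        try:
            fit = survstat.cox_fit(x[:, None], time, event)
            beta, p = float(fit.coef[0]), float(fit.p_values[0])
            rows[feat] = {"beta": beta, "p": p}
            if p < alpha:
                survivors.append(feat)
        except OmsurvError as exc:
            warns.append(f"{feat}: {exc}")
            rows[feat] = {"beta": np.nan, "p": np.nan}
    return SelectionStep(
        method="uni_cox",
        params={"alpha": alpha},
        input_features=list(table.feature_ids),
        survivors=survivors,
        statistics=pd.DataFrame.from_dict(rows, orient="index"),
        warnings=warns,
    )


def logrank_screen(table: OmicsClinicalTable, alpha: float = 0.05) -> SelectionStep:
    """Dichotomize each feature at its median, 2-group log-rank; p < alpha survives.

    Features whose median split leaves a group empty are dropped with a warning.
    """
    _check_alpha(alpha)
    time = table.time.to_numpy(dtype=float)
    event = table.event.to_numpy()
    rows, survivors, warns = {}, [], []
    for feat in table.feature_ids:
        x = table.features[feat].to_numpy(dtype=float)
        hi = x > np.median(x)
        if hi.all() or (~hi).all():
            warns.append(f"{feat}: degenerate median split")
            rows[feat] = {"chi2": np.nan, "p": np.nan}
            continue
        res = survstat.logrank_test(time, event, hi.astype(int))
        rows[feat] = {"chi2": res.statistic, "p": res.p_value}
        if res.p_value < alpha:
            survivors.append(feat)
    return SelectionStep(
        method="logrank",
        params={"alpha": alpha},
        input_features=list(table.feature_ids),
        survivors=survivors,
        statistics=pd.DataFrame.from_dict(rows, orient="index"),
        warnings=warns,
    )


def multivariate_cox_screen(table: OmicsClinicalTable, alpha: float = 0.05) -> SelectionStep:
    """One joint Cox fit over all current features; joint Wald p < alpha survives."""
    _check_alpha(alpha)
    n_events = int(table.event.sum())
    feats = table.feature_ids
    if len(feats) >= n_events:
        raise ValidationError(
            f"{len(feats)} features vs {n_events} events: run a single-factor screen first"
        )
    X = table.features.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        bad = survstat._collinear_cols(X - X.mean(axis=0))
        raise survstat.CollinearityError(
            "rank-deficient design", [feats[j] for j in bad]
        )
    fit = survstat.cox_fit(X, table.time.to_numpy(dtype=float), table.event.to_numpy())
    stats = pd.DataFrame({"beta": fit.coef, "se": fit.se, "p": fit.p_values}, index=feats)
    survivors = [f for f, p in zip(feats, fit.p_values) if p < alpha]
    return SelectionStep(
        method="multi_cox",
        params={"alpha": alpha},
        input_features=list(feats),
        survivors=survivors,
        statistics=stats,
    )


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Event-stratified fold assignment so every fold sees events."""
    rng = np.random.default_rng(seed)
    assign = np.empty(event.size, dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(event == val)
        idx = rng.permutation(idx)
        assign[idx] = np.arange(idx.size) % n_folds
    return assign


def lasso_screen(
    table: OmicsClinicalTable,
    lambda_rule: str = "cv_min",
    fixed_lambda: float | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 50,
) -> SelectionStep:
    """Lasso-Cox screen: features with nonzero coefficient at the chosen penalty.

    ``lambda_rule``: "cv_min" (penalty maximizing the cross-validated partial
    likelihood), "cv_1se" (largest penalty within one standard error of the
    maximum), or "fixed" with ``fixed_lambda``. Cross-validation folds are
    event-stratified and seeded.
    """
    if lambda_rule not in ("cv_min", "cv_1se", "fixed"):
        raise ParameterError(f"unknown lambda rule {lambda_rule!r}")
    time = table.time.to_numpy(dtype=float)
    event = table.event.to_numpy()
    if int(event.sum()) < 2:
        raise ValidationError("lasso screen needs at least two events")
    X = table.features.to_numpy(dtype=float)
    feats = table.feature_ids

    if lambda_rule == "fixed":
        if fixed_lambda is None:
            raise ParameterError("fixed rule requires fixed_lambda")
        lam = float(fixed_lambda)
        cv_frame = None
    else:
        lmax = survstat.lambda_max(X, time, event)
        if lmax <= 0:
            lmax = 1e-3
        lambdas = np.geomspace(lmax, 1e-2 * lmax, n_lambdas)
        folds = _stratified_folds(event, n_folds, seed)
        # Verweij & Van Houwelingen cross-validated partial likelihood:
        # cv_k(lambda) = ll_full(beta_k) - ll_train(beta_k)
        cv = np.zeros((n_folds, lambdas.size))
        for k in range(n_folds):
            tr = folds != k
            if event[tr].sum() == 0:
                raise ValidationError("a CV fold has no events even after stratification")
            _, coefs = survstat.lasso_path(X[tr], time[tr], event[tr], lambdas=lambdas)
            for i, beta in enumerate(coefs):
                ll_full, _, _ = survstat._efron_ll(X, time, event, beta, order=0)
                ll_tr, _, _ = survstat._efron_ll(X[tr], time[tr], event[tr], beta, order=0)
                cv[k, i] = ll_full - ll_tr
        mean_cv = cv.mean(axis=0)
        se_cv = cv.std(axis=0, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmax(mean_cv))
        if lambda_rule == "cv_min":
            lam = float(lambdas[best])
        else:
            ok = np.flatnonzero(mean_cv >= mean_cv[best] - se_cv[best])
            lam = float(lambdas[ok.min()])  # grid is decreasing: min index = largest lambda
        cv_frame = pd.DataFrame({"lambda": lambdas, "cv_loglik": mean_cv, "cv_se": se_cv})

    fit = survstat.cox_fit(X, time, event, l1_penalty=lam)
    survivors = [f for f, b in zip(feats, fit.coef) if b != 0.0]
    stats = pd.DataFrame({"beta": fit.coef, "abs_beta": np.abs(fit.coef)}, index=feats)
    step = SelectionStep(
        method="lasso",
        params={"lambda_rule": lambda_rule, "lambda": lam, "n_folds": n_folds, "seed": seed},
        input_features=list(feats),
        survivors=survivors,
        statistics=stats,
    )
    step.cv_curve = cv_frame  # attached for reporting/plots
    return step


_METHODS = {
    "correlation": correlation_filter,
    "uni_cox": univariate_cox_screen,
    "logrank": logrank_screen,
    "multi_cox": multivariate_cox_screen,
    "lasso": lasso_screen,
}


def run_selection_chain(table: OmicsClinicalTable, steps: list[dict]) -> SelectionTrace:
    """Run screens sequentially, each on the survivors of the previous one.

    ``steps`` is an ordered list of {"method": name, **params} mappings. A
    step that leaves zero features stops the chain with status
    "empty_result" and a partial trace.
    """
    if not steps:
        raise ParameterError("selection chain needs at least one step")
    trace: list[SelectionStep] = []
    current = table
    for spec in steps:
        spec = dict(spec)
        method = spec.pop("method")
        if method not in _METHODS:
            raise ParameterError(f"unknown selection method {method!r}")
        step = _METHODS[method](current, **spec)
        trace.append(step)
        if not step.survivors:
            return SelectionTrace(steps=trace, status="empty_result")
        current = current.subset_features(step.survivors)
    return SelectionTrace(steps=trace)


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must lie in (0, 1)")
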