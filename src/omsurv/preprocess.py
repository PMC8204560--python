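"""Preprocessing: outlier elimination, missing-value imputation, feature scaling.

All statistics (means, medians, standard deviations, ranges) are fitted on
the training partition and re-applied unchanged to test data, so that
downstream evaluation never leaks test information. Outliers are flagged at
the value level (set to missing) rather than dropping whole samples, which
composes cleanly with the imputation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .tabular_io import OmicsClinicalTable


@dataclass
class PreprocessParams:
    """Fitted per-feature statistics plus the choices that produced them."""

    outlier_rule: str = "zscore"  # {"none", "zscore"}
    z_threshold: float = 4.0
    impute_strategy: str = "median"  # {"mean", "median"}
    scale_method: str = "standard"  # {"standard", "minmax", "none"}
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_outliers_flagged: int = 0
    n_imputed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return self.stats.copy()


def eliminate_outliers(
    table: OmicsClinicalTable, z_threshold: float = 4.0
) -> tuple[OmicsClinicalTable, int]:
    """Replace values whose leave-one-out z-score exceeds the threshold by missing.

    Each value is compared against the mean and (population) sd of the
    *remaining* observed values of its feature, so a single gross outlier
    cannot mask itself by inflating the scale it is judged against (with the
    plain all-sample z-score, |z| is bounded by ~sqrt(n-1) and small samples
    could never flag anything). Constant features (sd = 0) are never flagged.
    Returns the table and the count of values flagged.
    """
    if not (z_threshold > 0):
        raise ParameterError("z_threshold must be positive")
    X = table.features
    n = X.notna().sum()
    s1 = X.sum()
    s2 = (X**2).sum()
    m = n - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_loo = (s1 - X) / m
        var_loo = ((s2 - X**2) - m * mean_loo**2) / m
        var_loo = var_loo.clip(lower=0.0)
        flag = (X.sub(mean_loo).abs() > z_threshold * np.sqrt(var_loo)) & (var_loo > 0) & (m >= 2)
    out = X.mask(flag.fillna(False))
    return table.with_features(out), int(flag.to_numpy().sum())


def fit_impute(table: OmicsClinicalTable, strategy: str = "median") -> pd.Series:
    """Per-feature fill values (training mean or median of observed entries)."""
    if strategy not in ("mean", "median"):
        raise ParameterError(f"unknown imputation strategy {strategy!r}")
    X = table.features
    all_missing = X.columns[X.isna().all()].tolist()
    if all_missing:
        raise ValidationError(f"features with no observed values: {all_missing}")
    return X.mean() if strategy == "mean" else X.median()


def apply_impute(table: OmicsClinicalTable, fill: pd.Series) -> tuple[OmicsClinicalTable, int]:
    n_missing = int(table.features.isna().to_numpy().sum())
    return table.with_features(table.features.fillna(fill)), n_missing


def impute_missing(
    table: OmicsClinicalTable, strategy: str = "median"
) -> tuple[OmicsClinicalTable, pd.Series]:
    """Fit-and-apply imputation on a single table."""
    fill = fit_impute(table, strategy)
    out, _ = apply_impute(table, fill)
    return out, fill


def fit_scale(table: OmicsClinicalTable, method: str = "standard") -> pd.DataFrame:
    """Training statistics for scaling: mean, population sd, min, max, median."""
    if method not in ("standard", "minmax", "none"):
        raise ParameterError(f"unknown scaling method {method!r}")
    X = table.features
    if X.isna().to_numpy().any():
        raise ValidationError("scaling requires imputed (complete) data")
    return pd.DataFrame(
        {
            "mean": X.mean(),
            "sd": X.std(ddof=0),
            "min": X.min(),
            "max": X.max(),
            "median": X.median(),
        }
    )


def apply_scale(
    table: OmicsClinicalTable, stats: pd.DataFrame, method: str = "standard"
) -> OmicsClinicalTable:
    """Scale with the fitted training statistics; constant features map to 0."""
    X = table.features
    if method == "none":
        return table
    if method == "standard":
        sd = stats["sd"].replace(0.0, np.nan)
        out = X.sub(stats["mean"]).div(sd).fillna(0.0)
    elif method == "minmax":
        rng = (stats["max"] - stats["min"]).replace(0.0, np.nan)
        out = X.sub(stats["min"]).div(rng).fillna(0.0)
    else:
        raise ParameterError(f"unknown scaling method {method!r}")
    return table.with_features(out)


def scale_features(
    table: OmicsClinicalTable, method: str = "standard"
) -> tuple[OmicsClinicalTable, pd.DataFrame]:
    stats = fit_scale(table, method)
    return apply_scale(table, stats, method), stats


def fit_transform(
    train: OmicsClinicalTable,
    test: OmicsClinicalTable | None = None,
    outlier_rule: str = "zscore",
    z_threshold: float = 4.0,
    impute_strategy: str = "median",
    scale_method: str = "standard",
) -> tuple[OmicsClinicalTable, OmicsClinicalTable | None, PreprocessParams]:
    """Full preprocessing pass: outlier flagging -> imputation -> scaling.

    Outlier flagging, fill values and scaling statistics are all computed on
    ``train``; ``test`` is transformed with the same fitted parameters.
    """
    if outlier_rule not in ("none", "zscore"):
        raise ParameterError(f"unknown outlier rule {outlier_rule!r}")
    n_flagged = 0
    if outlier_rule == "zscore":
        train, n_flagged = eliminate_outliers(train, z_threshold)
        if test is not None:
            test, _ = eliminate_outliers(test, z_threshold)
    n_imputed = int(train.features.isna().to_numpy().sum())
    fill = fit_impute(train, impute_strategy)
    train, _ = apply_impute(train, fill)
    if test is not None:
        test, _ = apply_impute(test, fill)
    stats = fit_scale(train, scale_method)
    stats["fill"] = fill
    train = apply_scale(train, stats, scale_method)
    if test is not None:
        test = apply_scale(test, stats, scale_method)
    params = PreprocessParams(
        outlier_rule=outlier_rule,
        z_threshold=z_threshold,
        impute_strategy=impute_strategy,
        scale_method=scale_method,
        stats=stats,
        n_outliers_flagged=n_flagged,
        n_imputed=n_imputed,
    )
    return train, test, params
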