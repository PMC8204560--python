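"""Survival comparison across subtypes or levels of a discrete clinical feature.

For each grouping: per-group Kaplan-Meier curves, the overall k-group
log-rank test, pairwise hazard ratios from 2-group Cox fits on a group
indicator with 95% Wald confidence intervals, and an at-risk timeline
(number of samples still under observation at each grid time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import subtyping, survstat
from .errors import UnfitError, ValidationError
from .tabular_io import OmicsClinicalTable


@dataclass
class PairwiseHR:
    group: str
    reference: str
    hr: float  # NaN when undefined (a group without events)
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass
class GroupSurvivalResult:
    group_names: list[str]
    km_curves: dict[str, survstat.KMCurve]
    logrank: survstat.LogrankResult
    pairwise_hr: list[PairwiseHR]
    at_risk: pd.DataFrame  # groups x time grid
    time_grid: np.ndarray

    def hr_matrix(self) -> pd.DataFrame:
        m = pd.DataFrame(np.nan, index=self.group_names, columns=self.group_names)
        for p in self.pairwise_hr:
            m.loc[p.group, p.reference] = p.hr
        np.fill_diagonal(m.values, 1.0)
        return m

    def km_frame(self) -> pd.DataFrame:
        rows = []
        for g, c in self.km_curves.items():
            for t, s, n, d in zip(c.event_times, c.survival, c.at_risk, c.events):
                rows.append({"group": g, "time": t, "survival": s, "at_risk": n, "events": d})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "groups": self.group_names,
            "logrank_chi2": self.logrank.statistic,
            "logrank_df": self.logrank.df,
            "logrank_p": self.logrank.p_value,
            "pairwise_hr": [
                {
                    "group": p.group,
                    "reference": p.reference,
                    "hr": p.hr,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                    "defined": p.defined,
                }
                for p in self.pairwise_hr
            ],
        }


def _at_risk_counts(time, groups, names, grid) -> pd.DataFrame:
    rows = {}
    for g in names:
        t = time[groups == g]
        rows[g] = [(t >= x).sum() for x in grid]
    return pd.DataFrame(rows, index=[f"t={x:g}" for x in grid]).T


def compare_groups(time, event, groups, time_grid=None) -> GroupSurvivalResult:
    """KM + log-rank + pairwise hazard ratios for >= 2 non-empty groups.

    Pairs involving a group with zero events get an undefined HR (NaN,
    flagged) rather than an error. The default at-risk grid is 10 equally
    spaced points from 0 to the maximum observed time.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    names = [str(g) for g in pd.unique(groups)]
    groups = groups.astype(str)
    if len(names) < 2:
        raise ValidationError("need at least two groups")

    km = {g: survstat.km_estimate(time[groups == g], event[groups == g]) for g in names}
    lr = survstat.logrank_test(time, event, groups)

    pairs: list[PairwiseHR] = []
    for i, gi in enumerate(names):
        for gj in names:
            if gi == gj:
                continue
            mask = (groups == gi) | (groups == gj)
            x = (groups[mask] == gi).astype(float)
            if event[mask & (groups == gi)].sum() == 0 or event[mask & (groups == gj)].sum() == 0:
                pairs.append(PairwiseHR(gi, gj, np.nan, np.nan, np.nan, defined=False))
                continue
            try:
                fit = survstat.cox_fit(x[:, None], time[mask], event[mask])
            except UnfitError:
                pairs.append(PairwiseHR(gi, gj, np.nan, np.nan, np.nan, defined=False))
                continue
            b, se = float(fit.coef[0]), float(fit.se[0])
            pairs.append(
                PairwiseHR(
                    gi, gj, float(np.exp(b)),
                    float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)),
                )
            )

    if time_grid is None:
        time_grid = np.linspace(0.0, float(time.max()), 10)
    time_grid = np.asarray(time_grid, dtype=float)
    at_risk = _at_risk_counts(time, groups, names, time_grid)
    return GroupSurvivalResult(names, km, lr, pairs, at_risk, time_grid)


def survival_by_category(table: OmicsClinicalTable, column: str, time_grid=None) -> GroupSurvivalResult:
    """Survival comparison across the observed levels of a discrete column.

    ``column`` may name a categorical covariate, the label column, or a
    (discrete) feature column.
    """
    if table.categorical is not None and column in table.categorical.columns:
        values = table.categorical[column]
    elif table.labels is not None and (column == table.labels.name or column == "label"):
        values = table.labels
    elif column in table.features.columns:
        values = table.features[column]
    else:
        raise ValidationError(f"no such column: {column!r}")
    obs = values.notna()
    levels = pd.unique(values[obs])
    if len(levels) < 2:
        raise ValidationError(f"column {column!r} has fewer than two observed levels")
    return compare_groups(
        table.time[obs].to_numpy(dtype=float),
        table.event[obs].to_numpy(),
        values[obs].to_numpy(),
        time_grid=time_grid,
    )


@dataclass
class UserVsSystemComparison:
    system: GroupSurvivalResult
    user: GroupSurvivalResult
    system_k: int
    user_k: int
    ami_between: float
    system_assignment: subtyping.SubtypeAssignment
    user_assignment: subtyping.SubtypeAssignment

    def summary(self) -> dict:
        return {
            "system_k": self.system_k,
            "user_k": self.user_k,
            "ami_between": self.ami_between,
            "system_logrank_p": self.system.logrank.p_value,
            "user_logrank_p": self.user.logrank.p_value,
        }


def compare_user_vs_system_k(
    X,
    time,
    event,
    user_k: int,
    mode: str = "silhouette",
    labels=None,
    seed: int = 0,
) -> UserVsSystemComparison:
    """Subtype twice — system-selected k vs the user's k — and compare the
    two survival stratifications (log-rank p each, AMI between labelings)."""
    system = subtyping.select_k(X, mode=mode, labels=labels, seed=seed)
    user = subtyping.select_k(X, mode="user", k=user_k, seed=seed)
    res_sys = compare_groups(time, event, system.labels)
    res_usr = compare_groups(time, event, user.labels)
    return UserVsSystemComparison(
        system=res_sys,
        user=res_usr,
        system_k=system.k,
        user_k=user.k,
        ami_between=subtyping.ami(system.labels, user.labels),
        system_assignment=system,
        user_assignment=user,
    )
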