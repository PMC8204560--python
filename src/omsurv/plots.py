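"""Basic file-exported plots for the pipeline stages (no interactive display)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def _step_xy(curve):
    # prepend t=0, S=1 so curves start at the origin of the survival axis
    x = np.concatenate([[0.0], curve.event_times])
    y = np.concatenate([[1.0], curve.survival])
    return x, y


def km_plot(result, path, title="Kaplan-Meier by group"):
    """Per-group KM step curves with the at-risk timeline underneath."""
    fig, (ax, ax2) = plt.subplots(
        2, 1, figsize=(7, 6), height_ratios=[4, 1], sharex=True
    )
    for g in result.group_names:
        x, y = _step_xy(result.km_curves[g])
        ax.step(x, y, where="post", label=str(g))
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.set_title(f"{title}  (log-rank p = {result.logrank.p_value:.3g})")
    for i, g in enumerate(result.group_names):
        ax2.plot(result.time_grid, [0] * len(result.time_grid), alpha=0)  # fix x-extent
        for t, n in zip(result.time_grid, result.at_risk.loc[g]):
            ax2.text(t, len(result.group_names) - i, str(int(n)), ha="center", fontsize=7)
    ax2.set_ylim(0, len(result.group_names) + 1)
    ax2.set_yticks([])
    ax2.set_xlabel("Time")
    ax2.set_title("Number at risk", fontsize=8, loc="left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def tdroc_plot(roc, path):
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f} @ t = {roc.horizon:g}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("Time-dependent ROC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def calibration_plot(pairs, path, horizon):
    pairs = [p for p in pairs if np.isfinite(p[1])]
    fig, ax = plt.subplots(figsize=(5, 5))
    if pairs:
        pred, obs = zip(*pairs)
        ax.plot(pred, obs, "o-")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel(f"Predicted S({horizon:g})")
    ax.set_ylabel(f"Observed (KM) S({horizon:g})")
    ax.set_title("Calibration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def lasso_path_plot(lambdas, coefs, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for j in range(coefs.shape[1]):
        ax.plot(np.log(lambdas), coefs[:, j], lw=0.8)
    ax.set_xlabel("log(lambda)")
    ax.set_ylabel("Coefficient")
    ax.set_title("Lasso-Cox path")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def score_vs_k_plot(curve, path, criterion):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve["k"], curve["score"], "o-")
    ax.set_xlabel("k")
    ax.set_ylabel(f"{criterion} score")
    ax.set_title(f"Model-order selection ({criterion})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def nomogram_plot(nomo, path):
    """Point scales per feature plus the total-points axis, as aligned rows."""
    feats = nomo.max_points_per_feature.index.tolist()
    fig, ax = plt.subplots(figsize=(7, 1 + 0.5 * (len(feats) + 2)))
    y = len(feats) + 1
    ax.plot([0, 100], [y, y], "k-", lw=1)
    for p in range(0, 101, 10):
        ax.text(p, y + 0.15, str(p), ha="center", fontsize=7)
    ax.text(-2, y, "Points", ha="right", fontsize=8)
    for i, f in enumerate(feats):
        yy = len(feats) - i
        sub = nomo.feature_points[nomo.feature_points["feature"] == f]
        ax.plot(sub["points"], [yy] * len(sub), "k-", lw=1)
        for _, r in sub.iloc[:: max(1, len(sub) // 5)].iterrows():
            ax.text(r["points"], yy + 0.15, f"{r['value']:.2g}", ha="center", fontsize=6)
        ax.text(-2, yy, f, ha="right", fontsize=8)
    ax.set_ylim(-0.5, len(feats) + 2)
    ax.set_xlim(-30, 105)
    ax.axis("off")
    ax.set_title("Nomogram point scales")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
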