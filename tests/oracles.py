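"""Independent definition-level oracles used to validate the implementation.

Everything here is deliberately naive (loops over pairs, dense grids,
direct textbook summations) and shares no code with the package.
"""

import itertools
import math

import numpy as np


def logrank_2group_oracle(time, event, group):
    """Direct observed-minus-expected / variance summation for two groups."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def cox_partial_loglik_oracle(beta, x, time, event):
    """Log partial likelihood for a single covariate, no tied event times."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = time >= time[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_search_oracle(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Dense grid maximization of the single-covariate partial likelihood."""
    grid = np.arange(lo, hi + step, step)
    vals = [cox_partial_loglik_oracle(b, x, time, event) for b in grid]
    return grid[int(np.argmax(vals))]


def cindex_oracle(scores, time, event):
    """All-pairs Harrell's c: loop over ordered pairs."""
    n = len(time)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j or event[i] != 1:
                continue
            if not (time[i] < time[j] or (time[i] == time[j] and event[j] == 0)):
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def silhouette_oracle(X, labels):
    """Mean of (b - a)/max(a, b); singleton clusters contribute 0."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(labels)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            vals.append(0.0)
            continue
        a = D[i, same].mean()
        b = min(
            D[i, labels == other].mean() for other in set(labels) if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def ami_oracle(a, b):
    """Adjusted mutual information under the permutation model, from the
    textbook formulas (contingency table, hypergeometric expected MI)."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    ua, ub = sorted(set(a)), sorted(set(b))
    cont = np.array([[np.sum((a == x) & (b == y)) for y in ub] for x in ua], float)
    pa = cont.sum(1) / n
    pb = cont.sum(0) / n
    mi = 0.0
    for i in range(len(ua)):
        for j in range(len(ub)):
            if cont[i, j] > 0:
                mi += cont[i, j] / n * math.log(cont[i, j] / n / (pa[i] * pb[j]))
    ha = -sum(p * math.log(p) for p in pa if p > 0)
    hb = -sum(p * math.log(p) for p in pb if p > 0)
    # expected MI under random permutation (hypergeometric model)
    emi = 0.0
    ai = cont.sum(1).astype(int)
    bj = cont.sum(0).astype(int)
    for i in range(len(ua)):
        for j in range(len(ub)):
            lo = max(ai[i] + bj[j] - n, 1)
            hi = min(ai[i], bj[j])
            for nij in range(lo, hi + 1):
                term = nij / n * math.log(n * nij / (ai[i] * bj[j]))
                lp = (
                    math.lgamma(ai[i] + 1)
                    + math.lgamma(bj[j] + 1)
                    + math.lgamma(n - ai[i] + 1)
                    + math.lgamma(n - bj[j] + 1)
                    - math.lgamma(n + 1)
                    - math.lgamma(nij + 1)
                    - math.lgamma(ai[i] - nij + 1)
                    - math.lgamma(bj[j] - nij + 1)
                    - math.lgamma(n - ai[i] - bj[j] + nij + 1)
                )
                emi += term * math.exp(lp)
    denom = (ha + hb) / 2 - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom


def binary_auc_oracle(scores, labels):
    """Rank-based AUC (probability a positive outscores a negative, ties 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    num = 0.0
    for p in pos:
        for q in neg:
            num += 1.0 if p > q else (0.5 if p == q else 0.0)
    return num / (len(pos) * len(neg))


def breslow_oracle(beta, X, time, event):
    """Hand summation of the Breslow cumulative baseline hazard."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ np.asarray(beta, float)
    out = {}
    h = 0.0
    for t in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        risk = np.asarray(time) >= t
        d = np.sum((np.asarray(time) == t) & (np.asarray(event) == 1))
        h += d / np.sum(np.exp(eta[risk]))
        out[t] = h
    return out
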