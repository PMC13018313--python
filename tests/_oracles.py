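"""Independent reference implementations used to cross-check the package.

Everything here is written the slow, obvious way (explicit loops,
enumeration, closed forms) and shares no code with trialmr.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def wls_zero_intercept_slope(x, y, w):
    """Closed-form weighted least squares through the origin."""
    num = sum(wi * xi * yi for xi, yi, wi in zip(x, y, w))
    den = sum(wi * xi * xi for xi, wi in zip(x, w))
    return num / den


def wls_with_intercept(x, y, w):
    """2x2 normal equations for weighted y = a + b*x."""
    sw = sum(w)
    sx = sum(wi * xi for xi, wi in zip(x, w))
    sy = sum(wi * yi for yi, wi in zip(y, w))
    sxx = sum(wi * xi * xi for xi, wi in zip(x, w))
    sxy = sum(wi * xi * yi for xi, yi, wi in zip(x, y, w))
    det = sw * sxx - sx * sx
    a = (sxx * sy - sx * sxy) / det
    b = (sw * sxy - sx * sy) / det
    return a, b


def weighted_median_oracle(theta, w):
    """Step-by-step centred-cumulative-weight interpolation rule."""
    order = sorted(range(len(theta)), key=lambda i: theta[i])
    th = [theta[i] for i in order]
    wt = [w[i] for i in order]
    total = sum(wt)
    cum = []
    running = 0.0
    for wi in wt:
        cum.append((running + wi / 2.0) / total)
        running += wi
    if cum[0] >= 0.5:
        return th[0]
    if cum[-1] <= 0.5:
        return th[-1]
    for k in range(1, len(th)):
        if cum[k] >= 0.5:
            frac = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
            return th[k - 1] + frac * (th[k] - th[k - 1])
    raise AssertionError("unreachable")


def bh_oracle(pvals):
    """Textbook step-up: q_i = min over k >= rank(i) of m * p_(k) / k."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, m * pvals[i] / (pos + 1))
        q[i] = min(1.0, running_min)
    return q


def hwe_enum_p(n_aa, n_ab, n_bb):
    """Exact HWE test by full enumeration with rational arithmetic."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def table_weight(het):
        hom_a = (n_a - het) // 2
        hom_b = (n_b - het) // 2
        return Fraction(
            2**het * math.factorial(n),
            math.factorial(hom_a) * math.factorial(het) * math.factorial(hom_b))

    hets = [h for h in range(min(n_a, n_b) + 1)
            if (n_a - h) % 2 == 0 and h % 2 == min(n_a, n_b) % 2]
    weights = {h: table_weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(wt for wt in weights.values() if wt <= obs) / total)


def greedy_clump_oracle(records, r2_lookup, p_threshold, r2_threshold, window_bp):
    """Greedy clumping, written from the definition.

    ``records``: list of dicts with variant_id, chrom, pos, p.
    ``r2_lookup(id_a, id_b)``: pairwise dosage r-squared.
    """
    passing = [r for r in records if r["p"] < p_threshold]
    passing.sort(key=lambda r: (r["p"], r["pos"]))
    kept = []
    removed = set()
    for r in passing:
        if r["variant_id"] in removed:
            continue
        kept.append(r["variant_id"])
        for s in passing:
            if s["variant_id"] in removed or s["variant_id"] == r["variant_id"]:
                continue
            if s["chrom"] != r["chrom"] or abs(s["pos"] - r["pos"]) > window_bp:
                continue
            if r2_lookup(r["variant_id"], s["variant_id"]) > r2_threshold:
                removed.add(s["variant_id"])
        removed.add(r["variant_id"])
    return kept


def auc_pairwise(labels, scores):
    """Mann-Whitney AUC by explicit pair counting (ties count one half)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def enet_logistic_objective(X, y, b0, beta, lam, alpha):
    """-(1/n) loglik + lam*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)."""
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    eta = b0 + X @ beta
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    pen = alpha * np.abs(beta).sum() + (1 - alpha) / 2 * (beta**2).sum()
    return -loglik / len(y) + lam * pen


def grid_search_enet(X, y, lam, alpha, span=3.0, passes=4, n_grid=41):
    """Dense grid search over (intercept, 1-2 coefficients), refined.

    Only valid for designs with at most two predictor columns; returns the
    (b0, beta) minimizing the penalized logistic objective to ~1e-5.
    """
    X = np.asarray(X, float)
    p = X.shape[1]
    assert p in (1, 2)
    center = np.zeros(p + 1)
    width = span
    best = None
    for _ in range(passes):
        axes = [np.linspace(c - width, c + width, n_grid) for c in center]
        if p == 1:
            for b0 in axes[0]:
                for b1 in axes[1]:
                    val = enet_logistic_objective(X, y, b0, [b1], lam, alpha)
                    if best is None or val < best[0]:
                        best = (val, np.array([b0, b1]))
        else:
            for b0 in axes[0]:
                for b1 in axes[1]:
                    for b2 in axes[2]:
                        val = enet_logistic_objective(X, y, b0, [b1, b2], lam, alpha)
                        if best is None or val < best[0]:
                            best = (val, np.array([b0, b1, b2]))
        center = best[1]
        width = width * 2.0 / (n_grid - 1) * 2.0  # shrink around the best point
    return best[1][0], best[1][1:]


def irls_logistic(X, y, n_iter=50):
    """Plain IRLS Newton fit of a logistic model; returns (coef, se)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, X.T @ (y - mu))
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se
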