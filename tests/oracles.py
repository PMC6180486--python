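"""Independent reference implementations used only to check the package.

``proximal_fit`` solves the weighted elastic-net logistic problem by
accelerated full-gradient proximal descent (FISTA) — a completely
different algorithm from the package's IRLS coordinate descent — run to a
tight KKT tolerance.  ``pairwise_auc`` is the brute-force average over all
positive-negative pairs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def proximal_fit(X, y, wpen, alpha, lam, tol=1e-10, max_iter=500_000):
    """FISTA on the objective -l/n + lam * sum_j w_j[(1-a)/2 b_j^2 + a|b_j|].

    The intercept is unpenalized.  Returns (b0, beta).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    wpen = np.asarray(wpen, dtype=float).ravel()
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    # Lipschitz bound for the smooth part (logistic curvature <= 1/4)
    lip = np.linalg.norm(Xa, 2) ** 2 / (4.0 * n) + lam * (1.0 - alpha) * wpen.max(initial=0.0)
    step = 1.0 / lip

    z = np.zeros(p + 1)       # (b0, beta)
    zy = z.copy()             # extrapolation point
    t_mom = 1.0
    l1 = lam * alpha * wpen

    def smooth_grad(v):
        eta = Xa @ v
        g = Xa.T @ (expit(eta) - y) / n
        g[1:] += lam * (1.0 - alpha) * wpen * v[1:]
        return g

    for _ in range(max_iter):
        g = smooth_grad(zy)
        v = zy - step * g
        v[1:] = np.sign(v[1:]) * np.maximum(np.abs(v[1:]) - step * l1, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        zy = v + ((t_mom - 1.0) / t_new) * (v - z)
        z, t_mom = v, t_new
        if kkt_residual(X, y, wpen, alpha, lam, z[0], z[1:]) <= tol:
            break
    return z[0], z[1:]


def kkt_residual(X, y, wpen, alpha, lam, b0, beta):
    """Max first-order optimality violation of the penalized problem."""
    n = len(y)
    prob = expit(b0 + X @ beta)
    grad = X.T @ (prob - y) / n
    l1 = lam * alpha * wpen
    nz = beta != 0.0
    res = np.where(
        nz,
        np.abs(grad + lam * (1.0 - alpha) * wpen * beta + l1 * np.sign(beta)),
        np.maximum(np.abs(grad) - l1, 0.0),
    )
    return max(float(res.max(initial=0.0)), abs(float(np.mean(prob - y))))


def pairwise_auc(scores, labels):
    """AUC as the brute-force mean over all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
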