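"""Independent reference implementations used only as test oracles.

Each function here is deliberately written from first principles — basic
formulas, enumeration, or permutation — and never shares code with the
package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def irls_logistic(y: np.ndarray, X: np.ndarray, tol: float = 1e-12, max_iter: int = 200):
    """Plain iteratively-reweighted least squares for logistic regression.

    Each iteration solves the weighted least-squares normal equations for
    the working response z = eta + (y - mu) / w.  Returns (beta, se).
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, np.sqrt(np.diag(cov))


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment straight from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def hypergeom_upper_tail(n11: int, n10: int, n01: int, n00: int) -> float:
    """Pr(X >= n11) over all 2x2 tables with the observed margins,
    by explicit enumeration with binomial coefficients."""
    total = n11 + n10 + n01 + n00
    row1 = n11 + n10  # significant in study a
    col1 = n11 + n01  # significant in study b
    denom = math.comb(total, col1)
    acc = 0
    for k in range(n11, min(row1, col1) + 1):
        if col1 - k > total - row1:
            continue
        acc += math.comb(row1, k) * math.comb(total - row1, col1 - k)
    return acc / denom


def permutation_set_test(x: np.ndarray, member_idx: np.ndarray, n_draws: int, rng) -> tuple[float, float]:
    """Random-sets permutation test of the mean covariate in a gene set.

    Draws random same-size sets and compares their mean x with the observed
    set mean; returns (two-sided p with add-one correction, observed minus
    background mean difference).
    """
    size = len(member_idx)
    obs = x[member_idx].mean()
    draws = np.empty(n_draws)
    for b in range(n_draws):
        draws[b] = x[rng.choice(len(x), size, replace=False)].mean()
    hi = np.sum(draws >= obs)
    lo = np.sum(draws <= obs)
    p = 2.0 * (min(hi, lo) + 1) / (n_draws + 1)
    out_mean = np.delete(x, member_idx).mean()
    return min(p, 1.0), obs - out_mean


def pairwise_uncentered_distances(data: np.ndarray) -> np.ndarray:
    """Brute-force double loop over rows; pairwise-complete positions."""
    n = data.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = data[i], data[j]
            ok = ~(np.isnan(a) | np.isnan(b))
            a, b = a[ok], b[ok]
            num = float(np.sum(a * b))
            den = math.sqrt(float(np.sum(a * a))) * math.sqrt(float(np.sum(b * b)))
            d[i, j] = 1.0 if den == 0.0 else 1.0 - num / den
    return d
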