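"""Independent oracles used to check the package's numerics.

Everything here is deliberately naive — hand-rolled elimination, exhaustive
dynamic programming, brute-force enumeration — and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def solve_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares via the normal equations and hand-coded Gaussian
    elimination with partial pivoting (no numpy solvers)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    A = (X.T @ X).tolist()
    b = (X.T @ y).tolist()
    n = len(b)
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(A[r][col]))
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        for r in range(col + 1, n):
            f = A[r][col] / A[col][col]
            for c in range(col, n):
                A[r][c] -= f * A[col][c]
            b[r] -= f * b[col]
    beta = [0.0] * n
    for r in range(n - 1, -1, -1):
        s = b[r] - sum(A[r][c] * beta[c] for c in range(r + 1, n))
        beta[r] = s / A[r][r]
    return np.asarray(beta)


def sse_cost_table(x: np.ndarray):
    """cost(i, j) for the raw-SSE segment cost, via cumulative sums."""
    x = np.asarray(x, dtype=float)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):
        m = j - i
        return (s2[j] - s2[i]) - (s1[j] - s1[i]) ** 2 / m

    return cost


def exhaustive_dp_changepoints(x: np.ndarray, penalty: float) -> list[int]:
    """Optimal partition by the full O(n^2) dynamic program (no pruning)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    cost = sse_cost_table(x)
    F = [0.0] * (n + 1)
    F[0] = -penalty
    last = [0] * (n + 1)
    for t in range(1, n + 1):
        best, arg = math.inf, 0
        for s in range(t):
            v = F[s] + cost(s, t) + penalty
            if v < best:
                best, arg = v, s
        F[t] = best
        last[t] = arg
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def segmentation_cost(x: np.ndarray, bounds: list[int], penalty: float) -> float:
    """Total penalized cost of an arbitrary segmentation given by interior
    boundaries."""
    cost = sse_cost_table(x)
    pts = [0, *bounds, len(x)]
    return sum(cost(a, b) for a, b in zip(pts[:-1], pts[1:])) + penalty * (
        len(pts) - 2
    )


def gaussian_aicc(n: int, rss: float, n_coefficients: int) -> float:
    """AICc from first principles for a Gaussian OLS fit
    (k = coefficients + residual variance)."""
    k = n_coefficients + 1
    ll = -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)
    aic = -2.0 * ll + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def exhaustive_best_terms(
    frame, y, pool: list[str], max_terms: int, include_intercept: bool = True
):
    """Brute-force AICc minimisation over all term subsets of size <= max_terms.

    Terms are covariate names or "a:b" products; returns (terms, aicc).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)

    def column(t):
        if ":" in t:
            a, b = t.split(":", 1)
            return frame[a].to_numpy() * frame[b].to_numpy()
        return frame[t].to_numpy()

    best_terms, best_aicc = None, math.inf
    for k in range(1, max_terms + 1):
        for combo in itertools.combinations(pool, k):
            cols = [column(t) for t in combo]
            X = np.column_stack(([np.ones(n)] if include_intercept else []) + cols)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(((y - X @ beta) ** 2).sum())
            ncoef = X.shape[1]
            if n - (ncoef + 1) - 1 <= 0 or rss <= 0:
                continue
            a = gaussian_aicc(n, rss, ncoef)
            if a < best_aicc:
                best_terms, best_aicc = tuple(sorted(combo)), a
    return best_terms, best_aicc


def gaussian_log_densities(x: float, means, variances, priors) -> dict:
    """Brute-force per-group log(prior * normal density)."""
    out = {}
    for g in means:
        var = variances[g]
        dens = math.exp(-((x - means[g]) ** 2) / (2 * var)) / math.sqrt(
            2 * math.pi * var
        )
        out[g] = math.log(priors[g]) + math.log(dens)
    return out


def prediction_halfwidth(X: np.ndarray, y: np.ndarray, x0: np.ndarray, level=0.95):
    """Closed-form OLS prediction-interval halfwidth at x0 (intercept included
    in X and x0 by the caller)."""
    from scipy import stats

    X = np.asarray(X, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    n, p = X.shape
    rss = float(((y - X @ beta) ** 2).sum())
    s2 = rss / (n - p)
    lev = float(x0 @ np.linalg.inv(X.T @ X) @ x0)
    t = float(stats.t.ppf(0.5 * (1 + level), n - p))
    return t * math.sqrt(s2 * (1.0 + lev))
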