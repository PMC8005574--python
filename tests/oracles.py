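"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle is written from the mathematical definition, deliberately
avoiding the package's own code paths.
"""

from itertools import product

import numpy as np
from scipy import optimize


def svm_primal_objective(w, b, X, y, C):
    margins = 1 - y * (X @ w + b)
    return 0.5 * w @ w + C * np.clip(margins, 0, None).sum()


def svm_qp_oracle(X, y, C):
    """Solve the primal soft-margin QP with a generic constrained optimizer.

    Variables are (w, b, xi); constraints xi >= 0 and
    xi >= 1 - y (w.x + b) are linear, the objective is smooth quadratic.
    """
    n, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1:]

    def fun(z):
        w, b, xi = unpack(z)
        return 0.5 * w @ w + C * xi.sum()

    def grad(z):
        w, b, xi = unpack(z)
        return np.r_[w, 0.0, np.full(n, C)]

    A = np.zeros((n, d + 1 + n))
    A[:, :d] = y[:, None] * X
    A[:, d] = y
    A[:, d + 1:] = np.eye(n)
    constraints = [
        optimize.LinearConstraint(A, lb=1.0, ub=np.inf),
        optimize.LinearConstraint(
            np.hstack([np.zeros((n, d + 1)), np.eye(n)]), lb=0.0, ub=np.inf),
    ]
    z0 = np.r_[np.zeros(d + 1), np.ones(n)]
    res = optimize.minimize(fun, z0, jac=grad, method="trust-constr",
                            constraints=constraints,
                            options={"maxiter": 3000, "gtol": 1e-12,
                                     "xtol": 1e-14})
    w, b, _ = unpack(res.x)
    return w, b, fun(res.x)


def comparable_points(decision_oracle, margin_tol=0.02):
    """Mask of points whose predicted sign is well-posed for comparison.

    Two solvers meeting the same objective tolerance may legitimately place
    a point a hair's breadth on either side of the boundary; sign equality
    is only a meaningful contract away from |decision| ~ 0.
    """
    return np.abs(np.asarray(decision_oracle)) > margin_tol


def random_svm_instance(seed, max_n=20, max_d=8):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, max_n + 1))
    d = int(rng.integers(1, max_d + 1))
    X = rng.standard_normal((n, d))
    y = np.where(rng.random(n) < 0.5, -1, 1)
    if len(np.unique(y)) < 2:
        y[0] = -y[1]
    C = float(10.0 ** rng.uniform(-2, 2))
    return X, y, C


def wilcoxon_enumeration_oracle(diffs):
    """Exhaustive two-sided signed-rank p, written from the definition."""
    diffs = np.asarray([d for d in diffs if d != 0], dtype=float)
    n = len(diffs)
    order = np.argsort(np.abs(diffs), kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_abs = np.abs(diffs)[order]
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of 1-based positions
        i = j
    w_obs = ranks[diffs > 0].sum()
    center = n * (n + 1) / 4.0
    count = 0
    total = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - center) >= abs(w_obs - center) - 1e-12:
            count += 1
    return count / total


def bh_stepup_oracle(p, q=0.05):
    """Literal step-up definition: find the largest i with p(i) <= (i/m) q."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank / m * q:
            k = rank
    reject = [False] * m
    for idx in order[:k]:
        reject[idx] = True
    return reject


def friedman_recomputation_oracle(scores):
    """Tie-corrected Friedman statistic straight from the rank definition."""
    from scipy import stats as ss

    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    ranks = np.array([ss.rankdata(row) for row in scores])
    col = ranks.sum(axis=0)
    num = (k - 1) * float(((col - n * (k + 1) / 2) ** 2).sum())
    den = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4)
    return 0.0 if den == 0 else num / den


def grid_search_oracle(objective, lo=-6.0, hi=6.0, resolution=0.01):
    grid = np.arange(lo, hi + resolution / 2, resolution)
    values = np.array([objective(u) for u in grid])
    return grid[np.argmin(values)], values.min()


def unimodal_objectives(n, seed):
    """Deterministic unimodal test functions with random minima and shapes."""
    rng = np.random.default_rng(seed)
    funcs = []
    for _ in range(n):
        mode = float(rng.uniform(-5.5, 5.5))
        scale = float(rng.uniform(0.05, 2.0))
        power = float(rng.choice([1.0, 2.0]))
        offset = float(rng.uniform(-1, 1))
        funcs.append(lambda u, m=mode, s=scale, p=power, o=offset:
                     s * abs(u - m) ** p + o)
    return funcs
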