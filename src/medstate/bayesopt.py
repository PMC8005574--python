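"""One-dimensional Bayesian optimization of the SVM box constraint.

The search runs in log10(C) space over [-6, +6]: a Gaussian-process
surrogate (constant mean, squared-exponential kernel, maximum-likelihood
hyperparameters) is fitted to the evaluated points and the next point
maximizes expected improvement with an exploration floor, with a seeded
random restart every 8th iteration.  At most 30 objective evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.stats import norm, qmc

_JITTER = 1e-10
_XI = 0.01           # exploration floor added to the incumbent in EI
_RESTART_EVERY = 8   # seeded random point instead of EI on these iterations
_N_INIT = 4          # quasi-random initial design size
_ACQ_RESOLUTION = 0.01


@dataclass(frozen=True)
class OptTrace:
    evaluated_points: np.ndarray   # log10(C)
    objective_values: np.ndarray
    seed: int

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.objective_values))

    @property
    def best_point(self) -> float:
        return float(self.evaluated_points[self.best_index])

    @property
    def best_objective(self) -> float:
        return float(self.objective_values[self.best_index])

    def to_dict(self) -> dict:
        return {
            "evaluated_points": self.evaluated_points.tolist(),
            "objective_values": self.objective_values.tolist(),
            "best_point": self.best_point,
            "best_objective": self.best_objective,
            "seed": self.seed,
        }


def _gp_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """ML estimates (mean, signal_var, lengthscale, noise_var) for a 1-D GP."""
    y_var = y.var()
    noise = max(1e-6 * y_var, _JITTER)
    mean = y.mean()
    yc = y - mean
    span = x.max() - x.min() if len(x) > 1 else 1.0

    def neg_mll(theta):
        log_sf2, log_ell = theta
        K = np.exp(log_sf2) * np.exp(
            -0.5 * ((x[:, None] - x[None, :]) / np.exp(log_ell)) ** 2)
        K[np.diag_indices_from(K)] += noise + _JITTER
        try:
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            return 1e12
        alpha = np.linalg.solve(L.T, np.linalg.solve(L, yc))
        return float(0.5 * yc @ alpha + np.log(np.diag(L)).sum())

    best = None
    for ell0 in (0.5, span / 4 + 1e-3, 2.0):
        res = optimize.minimize(
            neg_mll, x0=[np.log(y_var + 1e-8), np.log(ell0)],
            method="L-BFGS-B",
            bounds=[(np.log(1e-10), np.log(1e4)), (np.log(1e-2), np.log(50.0))])
        if best is None or res.fun < best.fun:
            best = res
    sf2, ell = np.exp(best.x)
    return mean, float(sf2), float(ell), noise


def _gp_predict(x: np.ndarray, y: np.ndarray, xstar: np.ndarray,
                params: tuple[float, float, float, float],
                ) -> tuple[np.ndarray, np.ndarray]:
    mean, sf2, ell, noise = params
    K = sf2 * np.exp(-0.5 * ((x[:, None] - x[None, :]) / ell) ** 2)
    K[np.diag_indices_from(K)] += noise + _JITTER
    Ks = sf2 * np.exp(-0.5 * ((xstar[:, None] - x[None, :]) / ell) ** 2)
    L = np.linalg.cholesky(K)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y - mean))
    mu = mean + Ks @ alpha
    v = np.linalg.solve(L, Ks.T)
    var = np.clip(sf2 - np.sum(v * v, axis=0), 0.0, None)
    return mu, var


def _expected_improvement(mu: np.ndarray, var: np.ndarray, incumbent: float,
                          ) -> np.ndarray:
    sd = np.sqrt(var)
    improvement = incumbent - _XI - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, improvement / sd, 0.0)
    ei = improvement * norm.cdf(z) + sd * norm.pdf(z)
    return np.where(sd > 0, ei, np.maximum(improvement, 0.0))


def optimize_1d(objective: Callable[[float], float],
                bounds: tuple[float, float] = (-6.0, 6.0),
                max_evals: int = 30, seed: int = 0) -> OptTrace:
    """Minimize a scalar objective over ``bounds`` in at most ``max_evals`` calls."""
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("bounds must satisfy hi > lo")
    rng = np.random.default_rng(seed)
    grid = np.arange(lo, hi + _ACQ_RESOLUTION / 2, _ACQ_RESOLUTION)

    def evaluate(u: float) -> float:
        v = float(objective(float(u)))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value at log10(C)={u}")
        return v

    sobol = qmc.Sobol(d=1, scramble=True, rng=np.random.default_rng(seed))
    xs = list(lo + (hi - lo) * sobol.random(_N_INIT).ravel())
    ys = [evaluate(u) for u in xs]

    iteration = 0
    while len(xs) < max_evals:
        iteration += 1
        x = np.array(xs)
        y = np.array(ys)
        if iteration % _RESTART_EVERY == 0:
            candidate = float(rng.uniform(lo, hi))
        else:
            params = _gp_fit(x, y)
            mu, var = _gp_predict(x, y, grid, params)
            ei = _expected_improvement(mu, var, float(y.min()))
            candidate = float(grid[int(np.argmax(ei))])
            if np.min(np.abs(x - candidate)) < _ACQ_RESOLUTION / 2:
                candidate = float(rng.uniform(lo, hi))  # avoid re-evaluating
        xs.append(candidate)
        ys.append(evaluate(candidate))
    return OptTrace(np.array(xs), np.array(ys), seed)


def select_box_constraint(table, k: int = 10, seed: int = 0,
                          bounds: tuple[float, float] = (-6.0, 6.0),
                          max_evals: int = 30,
                          standardization: str = "global",
                          ) -> tuple[float, OptTrace]:
    """Pick the box constraint minimizing k-fold cross-validation loss.

    Returns (C, trace); the same C is reused for every fold of the final
    reported cross-validation.
    """
    from .decoder import cv_loss

    cache: dict[float, float] = {}

    def objective(u: float) -> float:
        if u not in cache:
            cache[u] = cv_loss(table, 10.0 ** u, k, standardization)
        return cache[u]

    trace = optimize_1d(objective, bounds=bounds, max_evals=max_evals, seed=seed)
    return 10.0 ** trace.best_point, trace
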