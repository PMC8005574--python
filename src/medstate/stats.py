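"""Clinical and brain-behavior statistics.

Paired Wilcoxon signed-rank tests (exact by sign enumeration for small n)
with Bonferroni control, a tie-corrected Friedman omnibus, Benjamini-
Hochberg step-up post hocs, a Spearman correlation matrix of factor-score
changes, and per-factor ordinary-least-squares regression of factor change
on decoding accuracy with 95% pointwise confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as ss

_EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_effective: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    x_grid: np.ndarray
    fit_line: np.ndarray
    conf_low: np.ndarray
    conf_high: np.ndarray


def _signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = ss.rankdata(np.abs(diffs))  # mid-ranks for tied magnitudes
    return float(ranks[diffs > 0].sum()), ranks


def wilcoxon_signed_rank(off: np.ndarray, on: np.ndarray) -> PairedTestResult:
    """Two-sided paired signed-rank test; zero differences are dropped.

    Exact p by enumerating all 2**n sign assignments when the effective n is
    at most 12, otherwise a normal approximation with tie correction.
    """
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    if off.shape != on.shape:
        raise ValueError("paired samples must have equal length")
    diffs = off - on
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if n < 3:
        raise ValueError("need at least 3 nonzero differences")
    w_plus, ranks = _signed_rank_statistic(diffs)
    center = n * (n + 1) / 4.0
    if n <= _EXACT_WILCOXON_MAX_N:
        # distribution of W+ over all sign assignments, respecting tied ranks
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)
        w_all = signs @ ranks
        p = float(np.mean(np.abs(w_all - center) >= np.abs(w_plus - center) - 1e-12))
    else:
        tie_term = (ranks**2).sum()  # equals n(n+1)(2n+1)/6 without ties
        sd = np.sqrt(tie_term / 4.0)
        z = (w_plus - center) / sd
        p = float(min(1.0, 2.0 * ss.norm.sf(abs(z))))
    return PairedTestResult(statistic=w_plus, p_value=p, n_effective=n)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p); m defaults to the number of tests."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def friedman_test(scores: np.ndarray) -> dict:
    """Tie-corrected Friedman chi-square test on a subjects x conditions matrix.

    Set ``iman_davenport=True`` on :func:`friedman_f` for the F transformation.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D subjects x conditions matrix")
    n, k = scores.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(scores)):
        raise ValueError("missing cells are not allowed")
    ranks = np.apply_along_axis(ss.rankdata, 1, scores)
    col_sums = ranks.sum(axis=0)
    ss_total = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    denom = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    if denom == 0:  # all rows fully tied
        return {"statistic": 0.0, "p": 1.0, "df": k - 1}
    statistic = (k - 1) * ss_total / denom
    p = float(ss.chi2.sf(statistic, k - 1))
    return {"statistic": float(statistic), "p": p, "df": k - 1}


def friedman_f(scores: np.ndarray) -> dict:
    """Iman-Davenport F transformation of the Friedman statistic."""
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    chi = friedman_test(scores)["statistic"]
    if n * (k - 1) == chi:
        return {"statistic": np.inf, "p": 0.0, "df": (k - 1, (n - 1) * (k - 1))}
    f = (n - 1) * chi / (n * (k - 1) - chi)
    p = float(ss.f.sf(f, k - 1, (n - 1) * (k - 1)))
    return {"statistic": float(f), "p": p, "df": (k - 1, (n - 1) * (k - 1))}


def benjamini_hochberg(p_values, q: float = 0.05) -> dict:
    """Step-up FDR control: rejections, adjusted p-values and the critical p.

    The critical p is the largest ordered p(i) satisfying p(i) <= (i/m) q.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ranked <= thresholds)
    critical_p = float(ranked[passing[-1]]) if len(passing) else np.nan
    reject = np.zeros(m, dtype=bool)
    if len(passing):
        reject[order[: passing[-1] + 1]] = True
    adjusted_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(1.0, adjusted_sorted)
    return {"adjusted": adjusted, "reject": reject, "critical_p": critical_p}


def spearman_matrix(changes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho (mid-ranks) and p-values for column pairs."""
    changes = np.asarray(changes, dtype=float)
    if changes.ndim != 2 or changes.shape[0] < 4:
        raise ValueError("need a 2-D matrix with at least 4 rows")
    k = changes.shape[1]
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    import warnings

    for i, j in combinations(range(k), 2):
        with warnings.catch_warnings():
            # constant columns yield NaN rho, which callers may inspect
            warnings.simplefilter("ignore", ss.ConstantInputWarning)
            r, p = ss.spearmanr(changes[:, i], changes[:, j])
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
    return rho, pmat


def accuracy_change_regression(accuracies: np.ndarray, changes: np.ndarray,
                               n_grid: int = 50) -> list[RegressionResult]:
    """OLS of each factor's score change on decoding accuracy.

    Returns one result per factor column with the unadjusted two-sided slope
    p-value and the 95% pointwise confidence band of the fitted line.
    """
    accuracies = np.asarray(accuracies, dtype=float)
    changes = np.asarray(changes, dtype=float)
    if changes.ndim != 2 or len(accuracies) != changes.shape[0]:
        raise ValueError("accuracies and changes must have matching rows")
    if len(accuracies) < 3:
        raise ValueError("need at least 3 subjects")
    if accuracies.std() == 0:
        raise ValueError("accuracy has zero variance; regression undefined")
    X = sm.add_constant(accuracies)
    x_grid = np.linspace(accuracies.min(), accuracies.max(), n_grid)
    Xg = sm.add_constant(x_grid)
    out = []
    for f in range(changes.shape[1]):
        model = sm.OLS(changes[:, f], X).fit()
        pred = model.get_prediction(Xg).summary_frame(alpha=0.05)
        out.append(RegressionResult(
            slope=float(model.params[1]),
            intercept=float(model.params[0]),
            r_squared=float(model.rsquared),
            p_value=float(model.pvalues[1]),
            x_grid=x_grid,
            fit_line=pred["mean"].to_numpy(),
            conf_low=pred["mean_ci_lower"].to_numpy(),
            conf_high=pred["mean_ci_upper"].to_numpy(),
        ))
    return out


def clinical_battery(change_matrix: np.ndarray, off_matrix: np.ndarray,
                     on_matrix: np.ndarray, q: float = 0.05) -> pd.DataFrame:
    """The per-factor and pairwise clinical tests as one tidy table.

    Per factor: OFF vs ON signed-rank with Bonferroni over 7 comparisons.
    Omnibus: Friedman across the 7 change columns.  Post hoc: signed-rank on
    every change-column pair (21 comparisons) with Benjamini-Hochberg.
    """
    def _safe_wilcoxon(a, b):
        try:
            res = wilcoxon_signed_rank(a, b)
            return res.statistic, res.p_value
        except ValueError:  # degenerate pair (all-zero or too few differences)
            return np.nan, np.nan

    rows = []
    raw_p = []
    for f in range(7):
        stat, p = _safe_wilcoxon(off_matrix[:, f], on_matrix[:, f])
        raw_p.append(p)
        rows.append({"test": "wilcoxon_off_vs_on", "target": f"factor_{f + 1}",
                     "statistic": stat, "p_raw": p, "method": "bonferroni"})
    adj = np.minimum(1.0, 7 * np.asarray(raw_p, dtype=float))
    for row, p_adj in zip(rows, adj):
        row["p_adjusted"] = float(p_adj)

    fr = friedman_test(change_matrix)
    rows.append({"test": "friedman_change", "target": "factors_1_to_7",
                 "statistic": fr["statistic"], "p_raw": fr["p"],
                 "p_adjusted": fr["p"], "method": f"chi2_df{fr['df']}"})

    pair_rows = []
    pair_p = []
    for i, j in combinations(range(7), 2):
        stat, p = _safe_wilcoxon(change_matrix[:, i], change_matrix[:, j])
        pair_p.append(p)
        pair_rows.append({"test": "wilcoxon_pairwise_change",
                          "target": f"factor_{i + 1}_vs_{j + 1}",
                          "statistic": stat, "p_raw": p,
                          "method": "benjamini_hochberg"})
    valid = ~np.isnan(pair_p)
    bh = benjamini_hochberg(np.asarray(pair_p)[valid], q)
    adjusted = np.full(len(pair_p), np.nan)
    adjusted[valid] = bh["adjusted"]
    for row, p_adj in zip(pair_rows, adjusted):
        row["p_adjusted"] = float(p_adj)
    rows.extend(pair_rows)
    df = pd.DataFrame(rows)
    df.attrs["bh_critical_p"] = bh["critical_p"]
    return df
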