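"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: normal equations are
solved directly, Type III sums of squares come from explicit effect-coded
regression increments, and Johnson-Neyman boundaries from a dense grid scan.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def normal_equations_ols(X: np.ndarray, y: np.ndarray):
    """(beta, R^2, residual variance) via the raw normal equations."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df = len(y) - X.shape[1]
    return beta, 1.0 - rss / tss, rss / df


def sum_coded_columns(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (effect) coding: k-1 columns, last level coded -1."""
    k = len(levels)
    cols = np.zeros((len(labels), k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols


def type3_anova_oracle(y: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Type III SS/F via effect-coded regression increments.

    Returns dict effect -> (ss, df, F) plus the residual (ss, df).
    """
    levels_a = sorted(set(a.tolist()))
    levels_b = sorted(set(b.tolist()))
    A = sum_coded_columns(a, levels_a)
    B = sum_coded_columns(b, levels_b)
    AB = np.concatenate(
        [A[:, [i]] * B[:, [j]] for i in range(A.shape[1]) for j in range(B.shape[1])],
        axis=1,
    )
    ones = np.ones((len(y), 1))
    full = np.concatenate([ones, A, B, AB], axis=1)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(full)
    df_resid = len(y) - full.shape[1]
    out = {}
    for name, drop in (("A", A), ("B", B), ("A:B", AB)):
        keep = [blk for blk in (A, B, AB) if blk is not drop]
        X_red = np.concatenate([ones, *keep], axis=1)
        ss_eff = rss(X_red) - rss_full
        df_eff = drop.shape[1]
        F = (ss_eff / df_eff) / (rss_full / df_resid)
        out[name] = (ss_eff, df_eff, F)
    out["Residual"] = (rss_full, df_resid)
    return out


def jn_boundaries_grid(fit, focal: str, moderator: str | None, alpha: float,
                       lo: float, hi: float, step: float = 1e-4) -> np.ndarray:
    """Sign changes of |t(slope)| - t_crit over a dense moderator grid."""
    params = fit.params
    cov = fit.cov
    if moderator is None or moderator == focal:
        b1 = params[focal]
        hi_term = f"{focal}^2"
        g = 2.0
    else:
        b1 = params[focal]
        hi_term = (
            f"{focal}:{moderator}"
            if f"{focal}:{moderator}" in params.index
            else f"{moderator}:{focal}"
        )
        g = 1.0
    b3 = params[hi_term]
    v11 = cov.loc[focal, focal]
    v13 = cov.loc[focal, hi_term]
    v33 = cov.loc[hi_term, hi_term]
    m = np.arange(lo, hi + step, step)
    slope = b1 + g * b3 * m
    var = v11 + 2 * g * m * v13 + (g * m) ** 2 * v33
    tcrit = stats.t.isf(alpha / 2, fit.df_resid)
    stat = np.abs(slope / np.sqrt(var)) - tcrit
    flips = np.nonzero(np.diff(np.sign(stat)) != 0)[0]
    return 0.5 * (m[flips] + m[flips + 1])


def point_biserial_toy(groups: np.ndarray, y: np.ndarray) -> float:
    """Hand point-biserial formula: (M1-M0)/s_y * sqrt(p*q), population SD."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups)
    m1, m0 = y[g == 1].mean(), y[g == 0].mean()
    p = (g == 1).mean()
    return (m1 - m0) / y.std() * np.sqrt(p * (1 - p))


def steiger_z_reference(r13: float, r23: float, r12: float, n: int) -> float:
    """Published Steiger Z1* formula, written out independently."""
    import math

    z1, z2 = math.atanh(r13), math.atanh(r23)
    rm = (r13 + r23) / 2.0
    cov_num = r12 * (1.0 - rm**2 - rm**2) - 0.5 * rm**2 * (
        1.0 - rm**2 - rm**2 - r12**2
    )
    s = cov_num / (1.0 - rm**2) ** 2
    return (z1 - z2) * math.sqrt((n - 3.0) / (2.0 - 2.0 * s))
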