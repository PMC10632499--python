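"""Probing fitted interaction and quadratic surfaces.

For a moderated model y = b0 + b1*X + b2*Z + b3*X*Z the simple slope of X at
moderator value z is w(z) = b1 + b3*z with Var(w) = V11 + 2z*V13 + z^2*V33,
the V entries coming from the fitted coefficient covariance.  For a quadratic
model y = b0 + ... + b2*X + b3*X^2 the probed quantity is the instantaneous
(derivative) slope w(x) = b2 + 2*b3*x with Var(w) = V22 + 4x*V23 + 4x^2*V33.
Both cases share the form w(m) = b_lin + g*b_hi*m with g = 1 or 2.

The Johnson-Neyman boundaries are the real roots of

    w(m)^2 - t_crit^2 * Var(w(m)) = 0,

a quadratic in m; the critical value is the central t at the fit's residual
df.  Intervals between boundaries are classified by a direct significance
test at their midpoints.  All moderator values are on the design scale: if
the fit mean-centered the moderator, points and boundaries are deviations
from its mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    IncompleteFitError,
    InvalidFitError,
    InvalidParameterError,
    TermLookupError,
)

__all__ = ["SimpleSlope", "JNRegion", "simple_slope_at", "jn_region", "floodlight",
           "pick_a_point"]


@dataclass(frozen=True)
class SimpleSlope:
    """Conditional (simple) slope at one moderator value."""

    at: float
    slope: float
    se: float
    t: float
    p: float
    df: float
    ci_low: float
    ci_high: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class JNRegion:
    """Johnson-Neyman partition of the moderator axis.

    ``roots`` are the unclipped real boundary solutions; ``boundaries`` those
    inside the evaluated range.  ``intervals``/``significant`` describe the
    partition of the range, and ``touches`` flags the tangent (double-root)
    case.
    """

    focal: str
    moderator: str
    kind: str
    alpha: float
    df: float
    t_crit: float
    roots: tuple[float, ...]
    boundaries: tuple[float, ...]
    mod_range: tuple[float, float]
    intervals: tuple[tuple[float, float], ...]
    significant: tuple[bool, ...]
    touches: bool = False

    def significant_at(self, m: float) -> bool:
        for (lo, hi), sig in zip(self.intervals, self.significant):
            if lo <= m <= hi:
                return sig
        raise InvalidParameterError(f"{m} outside evaluated range {self.mod_range}")


def _slope_setup(fit, focal: str, moderator: str | None):
    """Resolve term names, coefficients, covariance entries and gain g."""
    params = fit.params
    cov = fit.cov

    if moderator is None or moderator == focal:
        kind = "quadratic"
        mod_name = focal
        lin_term = focal
        hi_term = f"{focal}^2"
        g = 2.0
        if hi_term not in params.index:
            raise IncompleteFitError(f"fit has no {hi_term!r} term to probe")
    else:
        kind = "moderated"
        mod_name = moderator
        lin_term = focal
        for cand in (f"{focal}:{moderator}", f"{moderator}:{focal}"):
            if cand in params.index:
                hi_term = cand
                break
        else:
            raise IncompleteFitError(
                f"fit has no {focal}:{moderator} interaction term to probe"
            )
        g = 1.0
    if lin_term not in params.index:
        raise IncompleteFitError(f"fit has no {lin_term!r} term")
    try:
        b1 = float(params[lin_term])
        b3 = float(params[hi_term])
        v11 = float(cov.loc[lin_term, lin_term])
        v13 = float(cov.loc[lin_term, hi_term])
        v33 = float(cov.loc[hi_term, hi_term])
    except KeyError as exc:  # pragma: no cover - params/cov always aligned
        raise IncompleteFitError(f"missing covariance entry: {exc}") from exc
    if v11 < 0 or v33 < 0 or v11 * v33 < v13 * v13 - 1e-12 * max(v11 * v33, 1e-300):
        raise InvalidFitError("coefficient covariance is not positive semidefinite")
    return kind, mod_name, b1, b3, g, v11, v13, v33


def _observed_mod_range(fit, mod_name: str) -> tuple[float, float]:
    data = fit.model.data
    if mod_name not in data.columns:
        raise TermLookupError(f"moderator column {mod_name!r} not in data")
    x = data[mod_name].to_numpy(dtype=float) - fit.centering.get(mod_name, 0.0)
    return float(x.min()), float(x.max())


def simple_slope_at(fit, focal: str, at: float, moderator: str | None = None,
                    alpha: float = 0.05) -> SimpleSlope:
    """Simple slope of ``focal`` at one moderator value (design scale)."""
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    _, _, b1, b3, g, v11, v13, v33 = _slope_setup(fit, focal, moderator)
    m = float(at)
    slope = b1 + g * b3 * m
    var = v11 + 2 * g * m * v13 + (g * m) ** 2 * v33
    if var <= 0:
        raise InvalidFitError(f"nonpositive slope variance at moderator {m}")
    se = math.sqrt(var)
    t = slope / se
    df = fit.df_resid
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.isf(alpha / 2, df)
    return SimpleSlope(at=m, slope=slope, se=se, t=t, p=p, df=df,
                       ci_low=slope - tcrit * se, ci_high=slope + tcrit * se, alpha=alpha)


def jn_region(fit, focal: str, moderator: str | None = None, alpha: float = 0.05,
              mod_range: tuple[float, float] | None = None) -> JNRegion:
    """Johnson-Neyman region of significance for a simple slope."""
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    kind, mod_name, b1, b3, g, v11, v13, v33 = _slope_setup(fit, focal, moderator)
    df = fit.df_resid
    tcrit = float(stats.t.isf(alpha / 2, df))
    t2 = tcrit * tcrit

    # (b1 + g b3 m)^2 - t^2 (v11 + 2 g m v13 + g^2 m^2 v33) = A m^2 + B m + C
    A = g * g * (b3 * b3 - t2 * v33)
    B = 2.0 * g * (b1 * b3 - t2 * v13)
    C = b1 * b1 - t2 * v11

    scale = max(abs(A), abs(B), abs(C), 1e-300)
    touches = False
    roots: list[float] = []
    if abs(A) <= 1e-12 * scale:
        if abs(B) > 1e-12 * scale:
            roots = [-C / B]
    else:
        disc = B * B - 4.0 * A * C
        tol = 1e-12 * max(B * B, abs(4.0 * A * C), 1e-300)
        if abs(disc) <= tol:
            roots = [-B / (2.0 * A)]
            touches = True
        elif disc > 0:
            sq = math.sqrt(disc)
            # numerically stable quadratic roots
            q = -0.5 * (B + math.copysign(sq, B))
            r1, r2 = q / A, (C / q if q != 0 else -B / (2 * A))
            roots = sorted([r1, r2])

    rng = tuple(map(float, mod_range)) if mod_range is not None else _observed_mod_range(fit, mod_name)
    if not rng[0] < rng[1]:
        raise InvalidParameterError("moderator range bounds must be ordered")
    boundaries = tuple(r for r in roots if rng[0] < r < rng[1])

    edges = [rng[0], *boundaries, rng[1]]
    intervals = tuple((edges[i], edges[i + 1]) for i in range(len(edges) - 1))
    significant = tuple(
        simple_slope_at(fit, focal, 0.5 * (lo + hi), moderator=moderator,
                        alpha=alpha).significant
        for lo, hi in intervals
    )
    return JNRegion(
        focal=focal,
        moderator=mod_name,
        kind=kind,
        alpha=alpha,
        df=df,
        t_crit=tcrit,
        roots=tuple(roots),
        boundaries=boundaries,
        mod_range=rng,
        intervals=intervals,
        significant=significant,
        touches=touches,
    )


def floodlight(fit, focal: str, grid: Sequence[float], moderator: str | None = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Simple-slope table over a grid of moderator values."""
    pts = np.asarray(grid, dtype=float)
    if pts.size == 0:
        raise InvalidParameterError("floodlight grid must be non-empty")
    rows = [
        simple_slope_at(fit, focal, m, moderator=moderator, alpha=alpha) for m in pts
    ]
    return pd.DataFrame(
        {
            "at": [r.at for r in rows],
            "slope": [r.slope for r in rows],
            "se": [r.se for r in rows],
            "t": [r.t for r in rows],
            "p": [r.p for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "significant": [r.significant for r in rows],
        }
    )


def pick_a_point(fit, focal: str, moderator: str | None = None,
                 convention: str = "mean±1sd", points: Sequence[float] | None = None,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Simple slopes at conventional moderator values.

    ``convention`` is ``"mean"``, ``"mean±1sd"`` (also spelled
    ``"mean+-1sd"``), or ``"custom"`` with explicit ``points`` on the design
    scale.  Out-of-range custom points are computed but trigger a warning.
    """
    _, mod_name, *_ = _slope_setup(fit, focal, moderator)
    data = fit.model.data
    x = data[mod_name].to_numpy(dtype=float) - fit.centering.get(mod_name, 0.0)
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if convention == "mean":
        pts = [mean]
    elif convention in ("mean±1sd", "mean+-1sd"):
        pts = [mean - sd, mean, mean + sd]
    elif convention == "custom":
        if points is None or len(points) == 0:
            raise InvalidParameterError("custom convention requires explicit points")
        pts = [float(p) for p in points]
        lo, hi = x.min(), x.max()
        outside = [p for p in pts if not lo <= p <= hi]
        if outside:
            warnings.warn(
                f"points {outside} lie outside the observed moderator range "
                f"[{lo:g}, {hi:g}]", stacklevel=2)
    else:
        raise InvalidParameterError(f"unknown convention {convention!r}")
    return floodlight(fit, focal, pts, moderator=moderator, alpha=alpha)
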