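"""Estimation core: correlations, moderated/polynomial OLS, Type III factorial
ANOVA, effect sizes, and noncentral-F power analysis.

The two model classes follow the statsmodels convention: construct the model
from a DataFrame, call :meth:`fit`, and work with the returned results object
(estimates, covariance, diagnostics, ``summary()``).  Probing of fitted
interaction/quadratic surfaces lives in :mod:`splitstat.probe` and is exposed
as methods on :class:`OLSFitResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from ._terms import term_column, term_variables
from .exceptions import (
    CollinearityError,
    EmptyCellError,
    InvalidFactorError,
    InvalidParameterError,
    InvalidSizeError,
    MissingDataError,
    PowerNotAchievableError,
    TermLookupError,
    UndefinedCorrelationError,
)

__all__ = [
    "CorrelationResult",
    "pearson_r",
    "cohens_d",
    "f_squared",
    "PowerResult",
    "achieved_power",
    "required_n",
    "ModeratedOLS",
    "OLSFitResults",
    "FactorialANOVA",
    "AnovaResults",
]


# ---------------------------------------------------------------------------
# correlations and scalar effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its test and variance-explained fraction."""

    r: float
    p: float
    n: int

    @property
    def variance_explained(self) -> float:
        return self.r**2

    @property
    def df(self) -> int:
        return self.n - 2


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation of two columns with a two-sided t test.

    With a 0/1-coded group column this is the point-biserial correlation.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InvalidParameterError("x and y must be 1-d columns of equal length")
    if np.isnan(xa).any() or np.isnan(ya).any():
        raise MissingDataError("columns contain missing values")
    if xa.size < 3:
        raise InvalidSizeError("need n >= 3 for a correlation test")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant column")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=xa.size)


def cohens_d(mean1: float, mean2: float, sd_pooled: float) -> float:
    """Standardized mean difference (mean2 - mean1) / pooled SD."""
    if sd_pooled <= 0:
        raise InvalidParameterError("pooled SD must be > 0")
    return (mean2 - mean1) / sd_pooled


def f_squared(delta_r2: float, r2_full: float) -> float:
    """Cohen's f-squared for an R-squared increment: dR2 / (1 - R2_full)."""
    if r2_full >= 1:
        raise InvalidParameterError("r2_full must be < 1")
    if not 0 <= delta_r2 <= r2_full:
        raise InvalidParameterError("need 0 <= delta_r2 <= r2_full")
    return delta_r2 / (1.0 - r2_full)


# ---------------------------------------------------------------------------
# noncentral-F power analysis for R^2-increase tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerResult:
    """Sample-size requirement for an F test of an R-squared increment."""

    f2: float
    df_num: int
    n_predictors: int
    alpha: float
    power_target: float
    required_n: int
    achieved_power: float


def achieved_power(f2: float, df_num: int, p_full: int, n: int, alpha: float = 0.05) -> float:
    """Power of the R^2-increment F test at total sample size n.

    Noncentrality is Cohen's lambda = f^2 * (u + v + 1) with u = df_num and
    v = N - p_full - 1 (the convention of the G*Power F-test family); the
    test statistic is F(u, v) evaluated at the central-F critical value.
    """
    if f2 < 0:
        raise InvalidParameterError("f2 must be >= 0")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    df_den = n - p_full - 1
    if df_den < 1:
        return 0.0
    crit = stats.f.isf(alpha, df_num, df_den)
    return float(stats.ncf.sf(crit, df_num, df_den, f2 * (df_num + df_den + 1)))


def required_n(
    f2: float,
    df_num: int,
    p_full: int,
    alpha: float = 0.05,
    power_target: float = 0.80,
) -> PowerResult:
    """Smallest total N whose noncentral-F power reaches ``power_target``."""
    if f2 <= 0:
        raise PowerNotAchievableError("f2 = 0: no finite sample reaches the target power")
    if not 0 < power_target < 1:
        raise InvalidParameterError("power_target must be in (0, 1)")
    if df_num < 1 or p_full < df_num:
        raise InvalidParameterError("need df_num >= 1 and p_full >= df_num")
    lo = p_full + 2  # smallest N with positive error df
    hi = lo
    while achieved_power(f2, df_num, p_full, hi, alpha) < power_target:
        hi *= 2
        if hi > 10**9:  # pragma: no cover - guards pathological inputs
            raise PowerNotAchievableError("target power not reachable below N = 1e9")
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved_power(f2, df_num, p_full, mid, alpha) >= power_target:
            hi = mid
        else:
            lo = mid + 1
    return PowerResult(
        f2=f2,
        df_num=df_num,
        n_predictors=p_full,
        alpha=alpha,
        power_target=power_target,
        required_n=lo,
        achieved_power=achieved_power(f2, df_num, p_full, lo, alpha),
    )


# ---------------------------------------------------------------------------
# moderated / polynomial OLS
# ---------------------------------------------------------------------------

class ModeratedOLS:
    """OLS of one outcome on product/power terms of continuous predictors.

    Parameters
    ----------
    data : DataFrame
        Subject-level table holding the outcome and every predictor.
    outcome : str
        Outcome column name.
    terms : sequence of str
        Design terms, e.g. ``["nutrition_knowledge", "health_literacy",
        "health_literacy^2"]`` or ``["cr", "bmi", "cr:bmi"]``.  An intercept
        is always included.
    center : bool, sequence of str, or mapping
        Which base predictors to mean-center before building the design.
        ``True`` centers all of them; the subtracted constants are recorded
        on the results (``centering``).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        terms: Sequence[str],
        center: bool | Sequence[str] | Mapping[str, bool] = False,
    ) -> None:
        if outcome not in data.columns:
            raise TermLookupError(f"outcome column {outcome!r} not found")
        terms = list(terms)
        if not terms:
            raise InvalidParameterError("need at least one design term")
        base_vars: list[str] = []
        for t in terms:
            for v in term_variables(t):
                if v not in data.columns:
                    raise TermLookupError(f"column {v!r} (term {t!r}) not found")
                if v not in base_vars:
                    base_vars.append(v)
        used = data[[outcome, *base_vars]]
        if used.isna().any().any():
            raise MissingDataError("table contains missing values in model columns")
        if len(data) <= len(terms) + 1:
            raise InvalidSizeError(
                f"need n > {len(terms) + 1} observations for {len(terms)} terms"
            )
        if center is True:
            to_center = set(base_vars)
        elif center in (False, None):
            to_center = set()
        elif isinstance(center, Mapping):
            to_center = {k for k, v in center.items() if v}
        else:
            to_center = set(center)
        unknown = to_center - set(base_vars)
        if unknown:
            raise TermLookupError(f"center names not in model: {sorted(unknown)}")
        self.data = data
        self.outcome = outcome
        self.terms = terms
        self.centering = {v: float(data[v].mean()) for v in sorted(to_center)}
        self.base_variables = base_vars

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        terms: Sequence[str],
        center: bool | Sequence[str] | Mapping[str, bool] = False,
    ) -> "ModeratedOLS":
        return cls(data, outcome, terms, center)

    def design(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Response vector and design frame (const + one column per term)."""
        y = self.data[self.outcome].to_numpy(dtype=float)
        X = pd.DataFrame(
            {"const": np.ones(len(self.data))}
            | {t: term_column(self.data, t, self.centering) for t in self.terms}
        )
        return y, X

    def _check_rank(self, X: pd.DataFrame) -> None:
        mat = X.to_numpy()
        if np.linalg.matrix_rank(mat) == mat.shape[1]:
            return
        # name the terms whose columns fail to extend the column space
        offenders = []
        kept = mat[:, :1]
        for j, name in enumerate(X.columns[1:], start=1):
            trial = np.column_stack([kept, mat[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                offenders.append(name)
            else:
                kept = trial
        raise CollinearityError(offenders)

    def fit(self) -> "OLSFitResults":
        y, X = self.design()
        self._check_rank(X)
        res = sm.OLS(y, X).fit()
        return OLSFitResults(self, res)


class OLSFitResults:
    """Fitted moderated/polynomial OLS: estimates, covariance, partials, probing."""

    def __init__(self, model: ModeratedOLS, smres) -> None:
        self.model = model
        self._smres = smres
        self.params: pd.Series = smres.params
        self.bse: pd.Series = smres.bse
        self.tvalues: pd.Series = smres.tvalues
        self.pvalues: pd.Series = smres.pvalues
        self.cov: pd.DataFrame = smres.cov_params()
        self.df_resid: float = float(smres.df_resid)
        self.nobs: int = int(smres.nobs)
        self.rsquared: float = float(smres.rsquared)
        self.resid_var: float = float(smres.scale)
        self.centering: dict[str, float] = dict(model.centering)

    # -- per-term partial statistics ------------------------------------
    def _require_term(self, term: str) -> None:
        if term not in self.model.terms:
            raise TermLookupError(f"term {term!r} not in model terms {self.model.terms}")

    def squared_partial(self, term: str) -> float:
        """t^2 / (t^2 + df_resid): share of residual variance the term claims."""
        self._require_term(term)
        t = float(self.tvalues[term])
        return t * t / (t * t + self.df_resid)

    def squared_semipartial(self, term: str) -> float:
        """Drop in model R^2 when the term is removed (two-model refit)."""
        self._require_term(term)
        y, X = self.model.design()
        reduced = X.drop(columns=[term])
        r2_red = float(sm.OLS(y, reduced).fit().rsquared)
        return self.rsquared - r2_red

    def partial_table(self) -> pd.DataFrame:
        rows = {
            t: {
                "squared_partial": self.squared_partial(t),
                "squared_semipartial": self.squared_semipartial(t),
            }
            for t in self.model.terms
        }
        return pd.DataFrame(rows).T

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._smres.conf_int(alpha).rename(columns={0: "low", 1: "high"})

    # -- probing (delegates to splitstat.probe) -------------------------
    def simple_slope_at(self, focal: str, at: float, moderator: str | None = None,
                        alpha: float = 0.05):
        from . import probe

        return probe.simple_slope_at(self, focal, at, moderator=moderator, alpha=alpha)

    def jn_region(self, focal: str, moderator: str | None = None, alpha: float = 0.05,
                  mod_range: tuple[float, float] | None = None):
        from . import probe

        return probe.jn_region(self, focal, moderator=moderator, alpha=alpha,
                               mod_range=mod_range)

    def floodlight(self, focal: str, grid, moderator: str | None = None,
                   alpha: float = 0.05):
        from . import probe

        return probe.floodlight(self, focal, grid, moderator=moderator, alpha=alpha)

    def pick_a_point(self, focal: str, moderator: str | None = None,
                     convention: str = "mean±1sd", points=None, alpha: float = 0.05):
        from . import probe

        return probe.pick_a_point(self, focal, moderator=moderator,
                                  convention=convention, points=points, alpha=alpha)

    def summary(self) -> str:
        lines = [
            f"OLS: {self.model.outcome} ~ " + " + ".join(self.model.terms),
            f"n = {self.nobs}, R^2 = {self.rsquared:.4f}, "
            f"residual df = {self.df_resid:.0f}, residual SD = {math.sqrt(self.resid_var):.4f}",
        ]
        if self.centering:
            cen = ", ".join(f"{k} - {v:.4f}" for k, v in self.centering.items())
            lines.append(f"centered: {cen}")
        header = f"{'term':<28}{'coef':>12}{'SE':>11}{'t':>10}{'p':>13}{'pr2':>9}{'sr2':>9}"
        lines.append(header)
        for name in self.params.index:
            b = self.params[name]
            se = self.bse[name]
            t = self.tvalues[name]
            p = self.pvalues[name]
            if name == "const":
                pr2 = sr2 = float("nan")
            else:
                pr2 = self.squared_partial(name)
                sr2 = self.squared_semipartial(name)
            lines.append(
                f"{name:<28}{b:>12.4f}{se:>11.4f}{t:>10.3f}{p:>13.4g}{pr2:>9.4f}{sr2:>9.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# two-way Type III factorial ANOVA
# ---------------------------------------------------------------------------

class FactorialANOVA:
    """Two-way between-subjects ANOVA with Type III sums of squares.

    Factors are label columns (typically the output of a
    :func:`splitstat.discretize.apply_cut`).  Sums of squares use sum-to-zero
    effect coding, so each effect is tested adjusting for all others — the
    convention unbalanced-cell analyses in SPSS-style software imply.
    Marginal means are unweighted means of cell means (estimated marginal
    means), not raw level means.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, factor_a: str, factor_b: str) -> None:
        for col in (outcome, factor_a, factor_b):
            if col not in data.columns:
                raise TermLookupError(f"column {col!r} not found")
        y = data[outcome]
        if y.isna().any() or data[factor_a].isna().any() or data[factor_b].isna().any():
            raise MissingDataError("table contains missing values in model columns")
        self.data = data
        self.outcome = outcome
        self.factor_a = factor_a
        self.factor_b = factor_b
        self.levels_a = self._levels(data[factor_a])
        self.levels_b = self._levels(data[factor_b])
        if len(self.levels_a) < 2:
            raise InvalidFactorError(f"factor {factor_a!r} needs >= 2 observed levels")
        if len(self.levels_b) < 2:
            raise InvalidFactorError(f"factor {factor_b!r} needs >= 2 observed levels")
        counts = data.groupby(
            [data[factor_a].astype("object"), data[factor_b].astype("object")],
            sort=False,
        )[outcome].size()
        for la in self.levels_a:
            for lb in self.levels_b:
                if (la, lb) not in counts.index or counts[(la, lb)] == 0:
                    raise EmptyCellError(f"empty cell ({la!r}, {lb!r})")
        df_err = len(data) - len(self.levels_a) * len(self.levels_b)
        if df_err < 1:
            raise InvalidSizeError("error df < 1: too few observations per cell")

    @staticmethod
    def _levels(col: pd.Series) -> list:
        if isinstance(col.dtype, pd.CategoricalDtype):
            return [lev for lev in col.cat.categories if (col == lev).any()]
        return sorted(pd.unique(col.astype("object")))

    def fit(self) -> "AnovaResults":
        # fit on sanitized level codes so arbitrary labels survive the formula
        a_map = {lev: f"a{i}" for i, lev in enumerate(self.levels_a)}
        b_map = {lev: f"b{i}" for i, lev in enumerate(self.levels_b)}
        frame = pd.DataFrame(
            {
                "y": self.data[self.outcome].to_numpy(dtype=float),
                "A": pd.Categorical(
                    self.data[self.factor_a].astype("object").map(a_map),
                    categories=list(a_map.values()),
                ),
                "B": pd.Categorical(
                    self.data[self.factor_b].astype("object").map(b_map),
                    categories=list(b_map.values()),
                ),
            }
        )
        res = smf.ols("y ~ C(A, Sum) * C(B, Sum)", frame).fit()
        tab = anova_lm(res, typ=3)
        name_map = {
            "C(A, Sum)": self.factor_a,
            "C(B, Sum)": self.factor_b,
            "C(A, Sum):C(B, Sum)": f"{self.factor_a}:{self.factor_b}",
            "Residual": "Residual",
        }
        tab = tab.drop(index="Intercept").rename(index=name_map)
        ss_err = float(tab.loc["Residual", "sum_sq"])
        tab["partial_eta_sq"] = tab["sum_sq"] / (tab["sum_sq"] + ss_err)
        tab.loc["Residual", "partial_eta_sq"] = np.nan
        tab.loc["Residual", ["F", "PR(>F)"]] = np.nan
        tab = tab.rename(columns={"PR(>F)": "p"})
        return AnovaResults(self, res, tab)


class AnovaResults:
    """Fitted two-way ANOVA: Type III table, cells, EMMs, contrasts."""

    def __init__(self, model: FactorialANOVA, smres, table: pd.DataFrame) -> None:
        self.model = model
        self._smres = smres
        self.table = table
        self.df_resid = float(smres.df_resid)
        self.mse = float(smres.scale)
        self.rsquared = float(smres.rsquared)
        self.nobs = int(smres.nobs)
        data = model.data
        g = data.groupby(
            [data[model.factor_a].astype("object"), data[model.factor_b].astype("object")],
            sort=False,
        )[model.outcome]
        stats_ = pd.DataFrame({"mean": g.mean(), "n": g.size()})
        stats_["se"] = np.sqrt(self.mse / stats_["n"])
        idx = pd.MultiIndex.from_product(
            [model.levels_a, model.levels_b], names=[model.factor_a, model.factor_b]
        )
        self.cell_means = stats_.reindex(idx)

    def _factor_levels(self, factor: str):
        if factor == self.model.factor_a:
            return 0, self.model.levels_a
        if factor == self.model.factor_b:
            return 1, self.model.levels_b
        raise TermLookupError(f"unknown factor {factor!r}")

    def emmeans(self, factor: str) -> pd.DataFrame:
        """Estimated marginal means: unweighted means of cell means per level."""
        axis, levels = self._factor_levels(factor)
        rows = {}
        for lev in levels:
            cells = self.cell_means.xs(lev, level=axis)
            k = len(cells)
            mean = float(cells["mean"].mean())
            var = self.mse * float((1.0 / cells["n"]).sum()) / k**2
            rows[lev] = {"mean": mean, "se": math.sqrt(var)}
        out = pd.DataFrame(rows).T
        out.index.name = factor
        return out

    def bonferroni_posthoc(self, factor: str) -> pd.DataFrame:
        """All pairwise EMM contrasts with Bonferroni-adjusted p-values."""
        emm = self.emmeans(factor)
        levels = list(emm.index)
        pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
        rows = []
        for a, b in pairs:
            diff = emm.loc[b, "mean"] - emm.loc[a, "mean"]
            se = math.sqrt(emm.loc[a, "se"] ** 2 + emm.loc[b, "se"] ** 2)
            t = diff / se
            p_raw = 2 * stats.t.sf(abs(t), self.df_resid)
            rows.append(
                {
                    "level_1": a,
                    "level_2": b,
                    "diff": diff,
                    "se": se,
                    "t": t,
                    "p_raw": p_raw,
                    "p_bonferroni": min(1.0, p_raw * len(pairs)),
                }
            )
        return pd.DataFrame(rows)

    def partial_eta_sq(self, effect: str) -> float:
        if effect not in self.table.index or effect == "Residual":
            raise TermLookupError(f"unknown effect {effect!r}")
        return float(self.table.loc[effect, "partial_eta_sq"])

    def summary(self) -> str:
        lines = [
            f"Type III two-way ANOVA: {self.model.outcome} ~ "
            f"{self.model.factor_a} * {self.model.factor_b}",
            f"n = {self.nobs}, R^2 = {self.rsquared:.4f}, "
            f"error MS = {self.mse:.4f} on {self.df_resid:.0f} df",
            self.table.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "cell means (mean, SE, n):",
            self.cell_means.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
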