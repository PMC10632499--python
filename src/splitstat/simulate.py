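"""Monte-Carlo engines for the spurious-effect phenomena of dichotomization.

Three engines, all deterministic given their seed:

- :func:`spurious_increase_rate` — how often sampling error makes the
  correlation *larger* after a median (or fixed) split, despite the
  population-level attenuation.
- :func:`spurious_anova_rate` — how often a truly null predictor turns
  "significant" in a 2x2 ANOVA on double-median-split data versus in the
  continuous regression, as a function of the predictor correlation.
- :func:`power_comparison_study2` — power to detect the restraint-by-BMI
  interaction by continuous regression versus by double-median-split 2x2
  ANOVA at the Study 2 generator truth.

Splits recompute the sample median within every replicate, mirroring actual
practice.  "Spurious increase" compares absolute correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, InvalidSizeError
from .synthetic_data import StudySpec, _draw_predictors, _truth_mean, study2_spec

__all__ = [
    "SpuriousSimResult",
    "spurious_increase_rate",
    "spurious_anova_rate",
    "power_comparison_study2",
]


@dataclass(frozen=True)
class SpuriousSimResult:
    """Monte-Carlo event rates with their binomial standard errors."""

    params: dict = field(repr=False)
    reps: int
    seed: int
    primary: str
    rates: dict[str, float]

    @property
    def proportion(self) -> float:
        return self.rates[self.primary]

    @property
    def mc_se(self) -> float:
        return self.se(self.primary)

    def se(self, event: str) -> float:
        p = self.rates[event]
        return math.sqrt(p * (1.0 - p) / self.reps)


def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along axis 1 of two (reps, n) arrays."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
    return (ac * bc).sum(axis=1) / denom


def _bvn(rng: np.random.Generator, rho: float, reps: int, n: int):
    x = rng.standard_normal((reps, n))
    y = rho * x + math.sqrt(1 - rho * rho) * rng.standard_normal((reps, n))
    return x, y


def _split_codes(x: np.ndarray, cut: np.ndarray | float) -> np.ndarray:
    """0/1 codes with the 'equal goes lower' boundary rule."""
    return (x > cut).astype(float)


def spurious_increase_rate(
    rho: float,
    n: int,
    reps: int,
    seed: int = 0,
    split: str = "one-median",
) -> SpuriousSimResult:
    """Rate at which dichotomization *increases* the absolute correlation.

    Per replicate a bivariate-normal sample with population correlation
    ``rho`` is drawn; ``split`` is ``"one-median"`` (split X at its sample
    median), ``"both-median"``, or ``"at:C"`` (split X at fixed standardized
    value C).  The event is |r after split| > |r continuous|.
    """
    if not abs(rho) < 1:
        raise InvalidParameterError(f"|rho| must be < 1, got {rho}")
    if n < 4:
        raise InvalidSizeError("need n >= 4 per replicate")
    if reps < 100:
        raise InvalidSizeError("need reps >= 100")
    rng = np.random.default_rng(seed)
    events = 0
    chunk = max(1, min(reps, int(4e6) // n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        x, y = _bvn(rng, rho, m, n)
        r_cont = _row_corr(x, y)
        if split == "one-median":
            xs = _split_codes(x, np.median(x, axis=1, keepdims=True))
            r_split = _row_corr(xs, y)
        elif split == "both-median":
            xs = _split_codes(x, np.median(x, axis=1, keepdims=True))
            ys = _split_codes(y, np.median(y, axis=1, keepdims=True))
            r_split = _row_corr(xs, ys)
        elif split.startswith("at:"):
            c = float(split[3:])
            xs = _split_codes(x, c)
            if np.any(np.ptp(xs, axis=1) == 0):
                raise InvalidParameterError(
                    f"fixed cut {c} left a replicate with one empty group; "
                    "move the cut or raise n"
                )
            r_split = _row_corr(xs, y)
        else:
            raise InvalidParameterError(f"unknown split rule {split!r}")
        events += int(np.count_nonzero(np.abs(r_split) > np.abs(r_cont)))
        done += m
    rate = events / reps
    return SpuriousSimResult(
        params={"rho": rho, "n": n, "split": split},
        reps=reps,
        seed=seed,
        primary="spurious_increase",
        rates={"spurious_increase": rate},
    )


def _batch_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided OLS coefficient p-values for a batch of designs.

    X is (reps, n, k), y is (reps, n); returns (reps, k).
    """
    from scipy import stats

    reps, n, k = X.shape
    xtx = np.einsum("rni,rnj->rij", X, X)
    xty = np.einsum("rni,rn->ri", X, y)
    beta = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]
    resid = y - np.einsum("rni,ri->rn", X, beta)
    df = n - k
    sigma2 = (resid * resid).sum(axis=1) / df
    diag = np.diagonal(np.linalg.inv(xtx), axis1=1, axis2=2)
    se = np.sqrt(sigma2[:, None] * diag)
    t = beta / se
    return 2.0 * stats.t.sf(np.abs(t), df)


def spurious_anova_rate(
    rho_xz: float,
    beta_x: float,
    beta_z: float,
    n: int,
    reps: int,
    seed: int = 0,
    alpha: float = 0.05,
) -> SpuriousSimResult:
    """How often the Z effect is "significant" after double median splits.

    Truth per replicate: Y = beta_x*X + beta_z*Z + N(0, 1) with corr(X, Z) =
    ``rho_xz``.  Both predictors are median-split and a 2x2 Type III ANOVA is
    run (for 1-df effects the Type III F equals the squared t of the
    effect-coded regression coefficient); in parallel the continuous
    regression with product term is fitted.  Rates of p < alpha for the Z
    effect under both routes are returned; with beta_z = 0 these are spurious
    detections.
    """
    if not abs(rho_xz) < 1:
        raise InvalidParameterError(f"|rho_xz| must be < 1, got {rho_xz}")
    if n < 20:
        raise InvalidSizeError("need n >= 20 per replicate")
    if reps < 100:
        raise InvalidSizeError("need reps >= 100")
    rng = np.random.default_rng(seed)
    hits_anova = hits_reg = 0
    chunk = max(1, min(reps, int(2e6) // n))
    done = 0
    ones_shape = None
    while done < reps:
        m = min(chunk, reps - done)
        x, z = _bvn(rng, rho_xz, m, n)
        y = beta_x * x + beta_z * z + rng.standard_normal((m, n))
        # effect-coded 2x2 ANOVA after per-replicate median splits
        a = 2.0 * _split_codes(x, np.median(x, axis=1, keepdims=True)) - 1.0
        b = 2.0 * _split_codes(z, np.median(z, axis=1, keepdims=True)) - 1.0
        if ones_shape is None or ones_shape.shape[0] != m:
            ones_shape = np.ones((m, n))
        Xa = np.stack([ones_shape, a, b, a * b], axis=2)
        p_anova = _batch_pvalues(Xa, y)[:, 2]
        Xr = np.stack([ones_shape, x, z, x * z], axis=2)
        p_reg = _batch_pvalues(Xr, y)[:, 2]
        hits_anova += int(np.count_nonzero(p_anova < alpha))
        hits_reg += int(np.count_nonzero(p_reg < alpha))
        done += m
    return SpuriousSimResult(
        params={
            "rho_xz": rho_xz,
            "beta_x": beta_x,
            "beta_z": beta_z,
            "n": n,
            "alpha": alpha,
        },
        reps=reps,
        seed=seed,
        primary="anova",
        rates={"anova": hits_anova / reps, "regression": hits_reg / reps},
    )


def power_comparison_study2(
    n: int,
    reps: int,
    seed: int = 0,
    alpha: float = 0.05,
    spec: StudySpec | None = None,
    interaction: float | None = None,
) -> SpuriousSimResult:
    """Interaction power: continuous regression vs. double-median-split ANOVA.

    Per replicate a Study 2 table of size ``n`` is generated from the
    generator truth (``interaction`` overrides the restraint-by-BMI
    coefficient, e.g. 0 for a type-I calibration); the interaction is tested
    (i) by the continuous regression with product term and (ii) by the 2x2
    Type III ANOVA after median-splitting both predictors.  Rejection rates
    of both tests are returned.
    """
    if n < 50:
        raise InvalidSizeError("need n >= 50 per replicate")
    if reps < 100:
        raise InvalidSizeError("need reps >= 100")
    spec = spec or study2_spec()
    if interaction is not None:
        coefs = dict(spec.outcome.coefficients)
        inter_terms = [t for t in coefs if ":" in t]
        if len(inter_terms) != 1:
            raise InvalidParameterError("spec must contain exactly one interaction term")
        coefs[inter_terms[0]] = float(interaction)
        spec = spec.model_copy(
            update={"outcome": spec.outcome.model_copy(update={"coefficients": coefs})}
        )
    rng = np.random.default_rng(seed)
    name_x, name_z = (p.name for p in spec.predictors)
    lo, hi = spec.outcome_range
    hits_reg = hits_anova = 0
    chunk = max(1, min(reps, int(2e6) // n))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        cols = _draw_predictors(spec, rng, m * n)
        frame = pd.DataFrame(cols)
        yhat = _truth_mean(spec, frame)
        y = np.clip(
            yhat + spec.noise_sd * rng.standard_normal(m * n), lo, hi
        ).reshape(m, n)
        x = cols[name_x].reshape(m, n)
        z = cols[name_z].reshape(m, n)
        ones = np.ones((m, n))
        # continuous moderated regression; interaction t is centering-invariant
        Xr = np.stack([ones, x, z, x * z], axis=2)
        p_reg = _batch_pvalues(Xr, y)[:, 3]
        a = 2.0 * _split_codes(x, np.median(x, axis=1, keepdims=True)) - 1.0
        b = 2.0 * _split_codes(z, np.median(z, axis=1, keepdims=True)) - 1.0
        Xa = np.stack([ones, a, b, a * b], axis=2)
        p_anova = _batch_pvalues(Xa, y)[:, 3]
        hits_reg += int(np.count_nonzero(p_reg < alpha))
        hits_anova += int(np.count_nonzero(p_anova < alpha))
        done += m
    return SpuriousSimResult(
        params={"n": n, "alpha": alpha, "interaction": interaction, "spec": spec.name},
        reps=reps,
        seed=seed,
        primary="regression",
        rates={"regression": hits_reg / reps, "anova": hits_anova / reps},
    )
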