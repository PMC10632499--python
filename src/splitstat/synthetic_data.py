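"""Synthetic subject-level tables emulating the two demonstration studies.

Study 1: health literacy (integer 0-9) and nutrition knowledge (integer 0-20),
latently correlated 0.30, driving nutrition-label accuracy (0-16) through a
model with a quadratic health-literacy effect.

Study 2: cognitive restraint (1-4) and BMI (17.0-60.7), nearly uncorrelated
(0.04), driving a skin-carotenoid fruit/vegetable score (29-709) through a
restraint-by-BMI interaction on mean-centered predictors.

Both generators draw a latent bivariate normal, map it onto the instrument
scales (rounding integer scales, rejection-sampling bounded continuous ones),
evaluate the deterministic truth model, add Gaussian noise whose SD was
calibrated once against the target model R-squared, and clip the outcome to
the instrument range.  Everything is deterministic given (n, spec, seed).
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from ._terms import term_column
from .exceptions import InvalidParameterError, InvalidSizeError

__all__ = [
    "PredictorSpec",
    "OutcomeModel",
    "StudySpec",
    "study1_spec",
    "study2_spec",
    "generate",
    "generate_bivariate",
    "generate_study1",
    "generate_study2",
]


class PredictorSpec(BaseModel):
    """Target moments and admissible range of one predictor scale."""

    name: str
    mean: float
    sd: float = Field(gt=0)
    minimum: float
    maximum: float
    integer: bool = False

    @model_validator(mode="after")
    def _ordered_range(self) -> "PredictorSpec":
        if not self.minimum < self.maximum:
            raise ValueError("predictor range bounds must be ordered")
        return self


class OutcomeModel(BaseModel):
    """Deterministic truth model: intercept + sum of coefficient * term.

    ``centers`` holds constants subtracted from predictors before term
    evaluation (the truth model's centering convention); empty means the
    model lives on the raw scales.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    centers: dict[str, float] = Field(default_factory=dict)


class StudySpec(BaseModel):
    """Complete recipe for one synthetic study."""

    name: str
    predictors: list[PredictorSpec]
    predictor_correlation: float
    outcome: OutcomeModel
    noise_sd: float = Field(ge=0)
    outcome_range: tuple[float, float]
    seed: int = 0

    @field_validator("predictor_correlation")
    @classmethod
    def _corr_open_unit(cls, v: float) -> float:
        if not abs(v) < 1:
            raise ValueError("|predictor_correlation| must be < 1")
        return v

    @model_validator(mode="after")
    def _validate(self) -> "StudySpec":
        if len(self.predictors) != 2:
            raise ValueError("StudySpec supports exactly two predictors")
        if not self.outcome_range[0] < self.outcome_range[1]:
            raise ValueError("outcome_range bounds must be ordered")
        return self

    @classmethod
    def from_json(cls, text: str) -> "StudySpec":
        return cls.model_validate(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)


def _load_packaged_spec(fname: str) -> StudySpec:
    text = resources.files("splitstat").joinpath("configs", fname).read_text(encoding="utf-8")
    return StudySpec.from_json(text)


def study1_spec() -> StudySpec:
    """Default Study 1 recipe (health literacy / nutrition knowledge)."""
    return _load_packaged_spec("study1.json")


def study2_spec() -> StudySpec:
    """Default Study 2 recipe (cognitive restraint / BMI)."""
    return _load_packaged_spec("study2.json")


@lru_cache(maxsize=64)
def _matched_truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [lo, hi]-truncation has the target moments."""
    from scipy import optimize, stats

    def eqs(p: np.ndarray) -> list[float]:
        mu, log_sig = p
        sig = math.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(eqs, x0=np.array([mean, math.log(sd)]), method="hybr", tol=1e-12)
    if not sol.success:  # pragma: no cover - well-posed for instrument scales
        raise InvalidParameterError(
            f"cannot match truncated-normal moments mean={mean}, sd={sd} on [{lo}, {hi}]"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _latent_pair(rng: np.random.Generator, rho: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(size)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(size)
    return z1, z2


def _draw_predictors(
    spec: StudySpec, rng: np.random.Generator, n: int
) -> dict[str, np.ndarray]:
    """Draw n correlated predictor rows; rejection keeps bounded columns exact."""
    arrays: list[np.ndarray] = [np.empty(0), np.empty(0)]
    while len(arrays[0]) < n:
        remaining = n - len(arrays[0])
        batch = max(2 * remaining, 64)
        latents = _latent_pair(rng, spec.predictor_correlation, batch)
        accept = np.ones(batch, dtype=bool)
        vals: list[np.ndarray] = []
        for p, z in zip(spec.predictors, latents):
            if p.integer:
                x = np.clip(np.rint(p.mean + p.sd * z), p.minimum, p.maximum)
            else:
                mu, sigma = _matched_truncnorm_params(p.mean, p.sd, p.minimum, p.maximum)
                x = mu + sigma * z
                accept &= (x >= p.minimum) & (x <= p.maximum)
            vals.append(x)
        for i, x in enumerate(vals):
            arrays[i] = np.concatenate([arrays[i], x[accept][:remaining]])
    return {p.name: a for p, a in zip(spec.predictors, arrays)}


def _truth_mean(spec: StudySpec, data: pd.DataFrame) -> np.ndarray:
    out = spec.outcome
    yhat = np.full(len(data), out.intercept, dtype=float)
    for term, coef in out.coefficients.items():
        yhat += coef * term_column(data, term, out.centers)
    return yhat


def generate(spec: StudySpec, n: int, seed: int | None = None) -> pd.DataFrame:
    """Generate an n-row subject table under ``spec``.

    The returned frame holds both predictors on their instrument scales and
    the clipped noisy outcome; byte-identical for identical (spec, n, seed).
    """
    if n < 1:
        raise InvalidSizeError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    data = pd.DataFrame(_draw_predictors(spec, rng, n))
    yhat = _truth_mean(spec, data)
    y = yhat + spec.noise_sd * rng.standard_normal(n)
    lo, hi = spec.outcome_range
    data[spec.outcome.name] = np.clip(y, lo, hi)
    return data


def generate_bivariate(rho: float, n: int, seed: int = 0) -> pd.DataFrame:
    """Two standard-normal columns ``x``, ``y`` with population correlation rho."""
    if not abs(rho) < 1:
        raise InvalidParameterError(f"|rho| must be < 1, got {rho}")
    if n < 2:
        raise InvalidSizeError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    x, y = _latent_pair(rng, rho, n)
    return pd.DataFrame({"x": x, "y": y})


def generate_study1(n: int, spec: StudySpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Study 1 table: health_literacy, nutrition_knowledge, label_accuracy."""
    return generate(spec or study1_spec(), n, seed)


def generate_study2(n: int, spec: StudySpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Study 2 table: cognitive_restraint, bmi, fv_intake."""
    return generate(spec or study2_spec(), n, seed)


def calibrate_noise_sd(
    spec: StudySpec,
    target_r2: float,
    n: int = 1_000_000,
    seed: int = 20230,
    tol: float = 1e-4,
) -> float:
    """Noise SD at which refitting the truth model attains ``target_r2``.

    Deterministic bisection on the realized (post-clipping) R-squared of an
    OLS refit of the truth terms at large n.  Used once per default spec;
    the result is frozen into the packaged JSON configs.
    """
    if not 0 < target_r2 < 1:
        raise InvalidParameterError("target_r2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(_draw_predictors(spec, rng, n))
    yhat = _truth_mean(spec, data)
    eps = rng.standard_normal(n)
    cols = [np.ones(n)] + [
        term_column(data, t, spec.outcome.centers) for t in spec.outcome.coefficients
    ]
    X = np.column_stack(cols)
    lo_b, hi_b = spec.outcome_range

    def realized_r2(sigma: float) -> float:
        y = np.clip(yhat + sigma * eps, lo_b, hi_b)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return 1.0 - resid.var() / y.var()

    var_model = float(yhat.var())
    # closed-form start ignoring clipping, then bisect around it
    sigma0 = math.sqrt(var_model * (1 - target_r2) / target_r2)
    lo, hi = sigma0 / 4, sigma0 * 4
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized_r2(mid) > target_r2:  # more noise lowers R^2
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def sample_moments(data: pd.DataFrame) -> pd.DataFrame:
    """Convenience mean/SD/min/max table for a generated frame."""
    return pd.DataFrame(
        {
            "mean": data.mean(),
            "sd": data.std(ddof=1),
            "min": data.min(),
            "max": data.max(),
        }
    )
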