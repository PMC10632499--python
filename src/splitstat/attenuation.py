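"""Closed-form consequences of dichotomization for correlations.

Splitting a standard-normal predictor at standardized cut c multiplies its
correlation with any outcome by phi(c) / sqrt(p(1-p)), where phi is the
normal density and p the upper-tail probability at c; at the mean the factor
is sqrt(2/pi) ~= 0.79788 (Cohen's classical result).  Splitting both members
of a bivariate-normal pair gives the phi coefficient of the resulting 2x2
table, which for two median splits equals (2/pi) * arcsin(rho).

Also here: the percent reduction in variance explained between a continuous
and a dichotomized analysis, and Steiger-type Z tests comparing two
dependent overlapping correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidParameterError, InvalidSizeError, UndefinedReductionError

__all__ = [
    "AttenuationReport",
    "point_biserial_attenuation",
    "double_dichotomization_phi",
    "percent_reduction",
    "DependentCorrelationTest",
    "compare_dependent_correlations",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class AttenuationReport:
    """What a split does to a latent correlation rho."""

    rho: float
    kind: str  # "point-biserial" or "phi"
    cut: tuple[float, ...]
    attenuated_r: float
    factor: float  # attenuated_r / rho (nan at rho = 0)

    @property
    def variance_ratio(self) -> float:
        """Variance explained after the split relative to before."""
        return self.factor**2

    @property
    def percent_reduction(self) -> float:
        """Percent of variance explained lost to the split."""
        return 100.0 * (1.0 - self.variance_ratio)


def _check_rho(rho: float) -> float:
    if not abs(rho) < 1:
        raise InvalidParameterError(f"|rho| must be < 1, got {rho}")
    return float(rho)


def point_biserial_attenuation(rho: float, cut: float = 0.0) -> AttenuationReport:
    """Population point-biserial correlation after splitting one normal
    variable at standardized cut ``cut``.

    The attenuation factor phi(c)/sqrt(p(1-p)) is 1 at no split, sqrt(2/pi)
    at the mean, and decays as the cut moves into the tails.
    """
    rho = _check_rho(rho)
    c = float(cut)
    p = stats.norm.sf(c)
    factor = stats.norm.pdf(c) / math.sqrt(p * (1.0 - p))
    return AttenuationReport(
        rho=rho,
        kind="point-biserial",
        cut=(c,),
        attenuated_r=rho * factor,
        factor=factor,
    )


def double_dichotomization_phi(rho: float, cut_x: float = 0.0, cut_y: float = 0.0) -> AttenuationReport:
    """Population phi coefficient after splitting both members of a
    bivariate-normal pair at standardized cuts.

    Computed from the bivariate-normal quadrant probability; for both cuts at
    the mean this reduces to (2/pi) * arcsin(rho).
    """
    rho = _check_rho(rho)
    cx, cy = float(cut_x), float(cut_y)
    px, py = stats.norm.sf(cx), stats.norm.sf(cy)
    # P(X > cx, Y > cy) = Phi2(-cx, -cy; rho) by central symmetry
    p11 = float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
            [-cx, -cy]
        )
    )
    phi = (p11 - px * py) / math.sqrt(px * (1 - px) * py * (1 - py))
    factor = phi / rho if rho != 0 else float("nan")
    return AttenuationReport(
        rho=rho, kind="phi", cut=(cx, cy), attenuated_r=phi, factor=factor
    )


def median_split_factor() -> float:
    """Cohen's attenuation factor for a single mean/median split: sqrt(2/pi)."""
    return _SQRT_2_OVER_PI


def percent_reduction(ve_continuous: float, ve_dichotomized: float) -> float:
    """Percent reduction in variance explained, 100*(c - d)/c.

    Inputs are variance-explained percentages (or any common positive scale);
    the result is scale-invariant.  Negative when dichotomization inflated
    the effect.
    """
    if ve_continuous < 0 or ve_dichotomized < 0:
        raise InvalidParameterError("variance-explained inputs must be >= 0")
    if ve_continuous == 0:
        raise UndefinedReductionError("baseline variance explained is 0")
    return 100.0 * (ve_continuous - ve_dichotomized) / ve_continuous


@dataclass(frozen=True)
class DependentCorrelationTest:
    """Z test of H0: rho13 = rho23 for correlations sharing variable 3."""

    z: float
    p: float
    method: str
    n: int


def _check_corr_triple(r13: float, r23: float, r12: float) -> None:
    for r in (r13, r23, r12):
        if not abs(r) < 1:
            raise InvalidParameterError("correlations must lie in (-1, 1)")
    mat = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise InvalidParameterError("(r12, r13, r23) is not a valid correlation matrix")


def compare_dependent_correlations(
    r13: float, r23: float, r12: float, n: int, method: str = "steiger"
) -> DependentCorrelationTest:
    """Compare two dependent overlapping correlations r13 and r23.

    ``method="steiger"`` is Steiger's Z1* with the pooled correlation in the
    covariance term; ``method="meng"`` is the Meng-Rosenthal-Rubin variant.
    Both Fisher-z transform the correlations and refer Z to the standard
    normal.
    """
    if n < 4:
        raise InvalidSizeError("need n >= 4")
    _check_corr_triple(r13, r23, r12)
    z13, z23 = math.atanh(r13), math.atanh(r23)
    if method == "steiger":
        rbar = 0.5 * (r13 + r23)
        rb2 = rbar * rbar
        psi = r12 * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r12 * r12)
        s = psi / ((1 - rb2) * (1 - rb2))
        z = (z13 - z23) * math.sqrt((n - 3) / (2.0 - 2.0 * s))
    elif method == "meng":
        rb2 = 0.5 * (r13 * r13 + r23 * r23)
        f = min((1 - r12) / (2 * (1 - rb2)), 1.0)
        h = (1 - f * rb2) / (1 - rb2)
        z = (z13 - z23) * math.sqrt((n - 3) / (2 * (1 - r12) * h))
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    p = 2 * stats.norm.sf(abs(z))
    return DependentCorrelationTest(z=float(z), p=float(p), method=method, n=int(n))
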