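"""Turn continuous columns into ordered group labels.

A :class:`CutScheme` is a named, ordered set of breakpoints plus labels; the
boundary rule decides where a value equal to a breakpoint lands.  The schemes
used in practice are the sample median split ("X or lower is low"), fixed
thresholds, and the CDC BMI classification (half-open intervals, so a BMI of
exactly 18.5 is "healthy weight" and 30.0 is "class 1 obesity").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateSplitError,
    InvalidParameterError,
    InvalidSizeError,
    MissingDataError,
)

__all__ = [
    "CutScheme",
    "GroupAssignment",
    "apply_cut",
    "median_split",
    "cdc_bmi_scheme",
    "dichotomize_at",
]

CDC_LABELS = (
    "underweight",
    "healthy weight",
    "overweight",
    "class 1 obesity",
    "class 2 obesity",
    "class 3 obesity",
)
CDC_BREAKPOINTS = (18.5, 25.0, 30.0, 35.0, 40.0)


@dataclass(frozen=True)
class CutScheme:
    """Named breakpoints + ordered labels defining a discretization.

    ``boundary`` is either ``"lower"`` (a value equal to a breakpoint joins
    the lower group — the "X or lower is low" convention) or ``"upper"``
    (half-open ``[lo, hi)`` intervals, the CDC convention).
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]
    boundary: str = "lower"

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(bp) + 1:
            raise InvalidParameterError(
                f"scheme {self.name!r}: need {len(bp) + 1} labels, got {len(self.labels)}"
            )
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise InvalidParameterError(f"scheme {self.name!r}: breakpoints must strictly increase")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidParameterError(f"scheme {self.name!r}: labels must be unique")
        if self.boundary not in ("lower", "upper"):
            raise InvalidParameterError("boundary must be 'lower' or 'upper'")

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def assign_one(self, value: float) -> str:
        """Label for a single value."""
        side = "left" if self.boundary == "lower" else "right"
        idx = int(np.searchsorted(self.breakpoints, value, side=side))
        return self.labels[idx]


@dataclass(frozen=True)
class GroupAssignment:
    """Per-subject labels plus group bookkeeping for one applied scheme."""

    scheme: CutScheme
    labels: pd.Categorical
    counts: dict[str, int] = field(repr=False)
    proportions: dict[str, float] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.labels)

    def codes(self) -> np.ndarray:
        """Ordinal 0..k-1 codes in scheme order (0/1 for a dichotomy)."""
        return np.asarray(self.labels.codes, dtype=int)


def apply_cut(values: Sequence[float] | pd.Series, scheme: CutScheme) -> GroupAssignment:
    """Assign every value a label under ``scheme``.

    Raises
    ------
    InvalidSizeError
        If ``values`` is empty.
    MissingDataError
        If ``values`` contains NaN.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidSizeError("cannot apply a cut to an empty column")
    if np.isnan(arr).any():
        raise MissingDataError("column contains missing values; drop or impute first")
    side = "left" if scheme.boundary == "lower" else "right"
    idx = np.searchsorted(scheme.breakpoints, arr, side=side)
    cat = pd.Categorical.from_codes(idx, categories=list(scheme.labels), ordered=True)
    counts = {lab: 0 for lab in scheme.labels}
    for lab, cnt in zip(*np.unique(np.asarray(cat), return_counts=True)):
        counts[str(lab)] = int(cnt)
    # recover scheme order (np.unique sorts alphabetically)
    counts = {lab: counts[lab] for lab in scheme.labels}
    props = {lab: c / arr.size for lab, c in counts.items()}
    return GroupAssignment(scheme=scheme, labels=cat, counts=counts, proportions=props)


def median_split(values: Sequence[float] | pd.Series, name: str = "median") -> CutScheme:
    """Build a low/high scheme cut at the sample median (ties go low)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidSizeError("cannot median-split an empty column")
    if np.isnan(arr).any():
        raise MissingDataError("column contains missing values")
    if np.ptp(arr) == 0:
        raise DegenerateSplitError("all values identical; median split is degenerate")
    med = float(np.median(arr))
    return CutScheme(name=name, breakpoints=(med,), labels=("low", "high"), boundary="lower")


def dichotomize_at(threshold: float, name: str | None = None) -> CutScheme:
    """Low/high scheme at a fixed threshold, 'threshold or lower' being low."""
    return CutScheme(
        name=name or f"at:{threshold:g}",
        breakpoints=(float(threshold),),
        labels=("low", "high"),
        boundary="lower",
    )


def cdc_bmi_scheme(collapse_obesity: bool = False) -> CutScheme:
    """CDC BMI classification.

    Six classes by default (underweight < 18.5, healthy [18.5, 25), overweight
    [25, 30), obesity classes 1-3 at [30, 35), [35, 40), >= 40); with
    ``collapse_obesity`` the three obesity classes merge into one.
    """
    if collapse_obesity:
        return CutScheme(
            name="cdc4",
            breakpoints=CDC_BREAKPOINTS[:3],
            labels=CDC_LABELS[:3] + ("obesity",),
            boundary="upper",
        )
    return CutScheme(name="cdc", breakpoints=CDC_BREAKPOINTS, labels=CDC_LABELS, boundary="upper")
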