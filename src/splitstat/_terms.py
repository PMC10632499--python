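"""Tiny term-string algebra shared by the generator and the OLS builder.

Terms are products of (possibly powered) predictor names: ``"bmi"``,
``"health_literacy^2"``, ``"cognitive_restraint:bmi"``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, TermLookupError


def parse_term(term: str) -> tuple[tuple[str, int], ...]:
    """Decompose a term into ((variable, power), ...) factors."""
    factors: list[tuple[str, int]] = []
    for part in term.split(":"):
        part = part.strip()
        if not part:
            raise InvalidParameterError(f"malformed term {term!r}")
        if "^" in part:
            var, _, pow_s = part.partition("^")
            try:
                k = int(pow_s)
            except ValueError as exc:
                raise InvalidParameterError(f"malformed power in term {term!r}") from exc
            if k < 1:
                raise InvalidParameterError(f"power must be >= 1 in term {term!r}")
            factors.append((var.strip(), k))
        else:
            factors.append((part, 1))
    return tuple(factors)


def term_variables(term: str) -> tuple[str, ...]:
    return tuple(v for v, _ in parse_term(term))


def term_column(
    data: pd.DataFrame,
    term: str,
    centers: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Evaluate one term on a table, subtracting per-variable centers first."""
    col = np.ones(len(data))
    for var, k in parse_term(term):
        if var not in data.columns:
            raise TermLookupError(f"column {var!r} not found for term {term!r}")
        x = data[var].to_numpy(dtype=float)
        if centers and var in centers:
            x = x - centers[var]
        col = col * x**k
    return col
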