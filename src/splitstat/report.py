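"""End-to-end "dichotomized ANOVA vs. continuous regression" comparison.

:func:`run_comparison` takes one subject table plus an
:class:`AnalysisConfig` and produces a :class:`ComparisonReport` with three
blocks mirroring how such comparisons are reported: univariate correlations
(continuous vs. 0/1-coded dichotomized predictor), factorial ANOVAs per cut
scheme, and the continuous moderated/polynomial regression with probing.
The report is a pydantic model: it serializes to JSON losslessly and renders
to markdown with the usual display conventions (4 significant digits,
p-values floored at "<0.001").
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from ._terms import term_variables
from .attenuation import percent_reduction
from .discretize import CutScheme, apply_cut, cdc_bmi_scheme, dichotomize_at, median_split
from .exceptions import InvalidParameterError, TermLookupError
from .linear_model import FactorialANOVA, ModeratedOLS, pearson_r
from .probe import JNRegion

__all__ = [
    "SchemeSpec",
    "AnovaDesign",
    "ProbeSpec",
    "AnalysisConfig",
    "ComparisonReport",
    "run_comparison",
    "write_report",
    "render_markdown",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class SchemeSpec(BaseModel):
    """A named cut scheme applied to one column.

    ``scheme`` is ``"median"``, ``"cdc"``, ``"cdc4"``, or ``"at:VALUE"``.
    """

    column: str
    scheme: str = "median"

    def build(self, values) -> CutScheme:
        s = self.scheme
        if s == "median":
            return median_split(values)
        if s == "cdc":
            return cdc_bmi_scheme(collapse_obesity=False)
        if s == "cdc4":
            return cdc_bmi_scheme(collapse_obesity=True)
        if s.startswith("at:"):
            return dichotomize_at(float(s[3:]))
        raise InvalidParameterError(f"unknown scheme {s!r}")

    @property
    def label(self) -> str:
        return f"{self.column}[{self.scheme}]"


class AnovaDesign(BaseModel):
    a: SchemeSpec
    b: SchemeSpec


class ProbeSpec(BaseModel):
    """Which simple slope to probe; moderator None means quadratic-in-focal."""

    focal: str
    moderator: Optional[str] = None


class AnalysisConfig(BaseModel):
    """Everything needed to rerun one comparison."""

    outcome: str
    predictors: list[str]
    terms: list[str]
    center: list[str] = Field(default_factory=list)
    anova_designs: list[AnovaDesign] = Field(default_factory=list)
    dichotomies: dict[str, str] = Field(default_factory=dict)
    probe: Optional[ProbeSpec] = None
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# report model
# ---------------------------------------------------------------------------

class UnivariateEntry(BaseModel):
    predictor: str
    scheme: str
    r_continuous: float
    p_continuous: float
    r_dichotomized: float
    p_dichotomized: float
    ve_continuous_pct: float
    ve_dichotomized_pct: float
    percent_reduction_ve: float  # negative when the split inflated the effect


class EffectRow(BaseModel):
    effect: str
    sum_sq: float
    df: float
    F: Optional[float] = None
    p: Optional[float] = None
    partial_eta_sq: Optional[float] = None


class CellMeanRow(BaseModel):
    level_a: str
    level_b: str
    mean: float
    se: float
    n: int


class PosthocRow(BaseModel):
    level_1: str
    level_2: str
    diff: float
    se: float
    t: float
    p_raw: float
    p_bonferroni: float


class AnovaBlock(BaseModel):
    design: str
    factor_a: str
    factor_b: str
    effects: list[EffectRow]
    rsquared: float
    cell_means: list[CellMeanRow]
    posthoc: dict[str, list[PosthocRow]]


class TermRow(BaseModel):
    term: str
    coef: float
    se: float
    t: float
    p: float
    squared_partial: Optional[float] = None
    squared_semipartial: Optional[float] = None


class JNBlock(BaseModel):
    focal: str
    moderator: str
    kind: str
    alpha: float
    t_crit: float
    roots: list[float]
    boundaries: list[float]
    mod_range: tuple[float, float]
    intervals: list[tuple[float, float]]
    significant: list[bool]

    @classmethod
    def from_region(cls, region: JNRegion) -> "JNBlock":
        return cls(
            focal=region.focal,
            moderator=region.moderator,
            kind=region.kind,
            alpha=region.alpha,
            t_crit=region.t_crit,
            roots=list(region.roots),
            boundaries=list(region.boundaries),
            mod_range=region.mod_range,
            intervals=[tuple(iv) for iv in region.intervals],
            significant=list(region.significant),
        )


class RegressionBlock(BaseModel):
    terms: list[TermRow]
    rsquared: float
    df_resid: float
    centering: dict[str, float]
    jn: Optional[JNBlock] = None
    floodlight: Optional[list[dict]] = None


class Provenance(BaseModel):
    input_sha256: str
    n_rows: int
    config: AnalysisConfig
    package_version: str


class ComparisonReport(BaseModel):
    univariate: list[UnivariateEntry]
    anova: list[AnovaBlock]
    regression: RegressionBlock
    provenance: Provenance

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls.model_validate(json.loads(text))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _table_hash(table: pd.DataFrame) -> str:
    return hashlib.sha256(table.to_csv(index=False).encode("utf-8")).hexdigest()


def _univariate_block(table, config) -> list[UnivariateEntry]:
    out = []
    y = table[config.outcome]
    for pred in config.predictors:
        if pred not in table.columns:
            raise TermLookupError(f"predictor column {pred!r} not found")
        scheme_name = config.dichotomies.get(pred, "median")
        scheme_spec = SchemeSpec(column=pred, scheme=scheme_name)
        scheme = scheme_spec.build(table[pred])
        if scheme.n_groups != 2:
            raise InvalidParameterError(
                f"univariate comparison needs a dichotomy; {scheme_name!r} has "
                f"{scheme.n_groups} groups"
            )
        codes = apply_cut(table[pred], scheme).codes()  # 0/1-coded groups
        cont = pearson_r(table[pred], y)
        dich = pearson_r(codes, y)
        ve_c = 100.0 * cont.variance_explained
        ve_d = 100.0 * dich.variance_explained
        out.append(
            UnivariateEntry(
                predictor=pred,
                scheme=scheme_name,
                r_continuous=cont.r,
                p_continuous=cont.p,
                r_dichotomized=dich.r,
                p_dichotomized=dich.p,
                ve_continuous_pct=ve_c,
                ve_dichotomized_pct=ve_d,
                percent_reduction_ve=percent_reduction(ve_c, ve_d),
            )
        )
    return out


def _anova_block(table, config, design: AnovaDesign) -> AnovaBlock:
    labeled = table.copy()
    cols = {}
    for side, spec in (("a", design.a), ("b", design.b)):
        scheme = spec.build(table[spec.column])
        col = f"{spec.column}__{scheme.name}"
        labeled[col] = apply_cut(table[spec.column], scheme).labels
        # drop never-observed categories so the ANOVA sees realized levels
        labeled[col] = labeled[col].cat.remove_unused_categories()
        cols[side] = col
    res = FactorialANOVA(labeled, config.outcome, cols["a"], cols["b"]).fit()
    effects = [
        EffectRow(
            effect=name,
            sum_sq=float(row["sum_sq"]),
            df=float(row["df"]),
            F=None if math.isnan(row["F"]) else float(row["F"]),
            p=None if math.isnan(row["p"]) else float(row["p"]),
            partial_eta_sq=(
                None if math.isnan(row["partial_eta_sq"]) else float(row["partial_eta_sq"])
            ),
        )
        for name, row in res.table.iterrows()
    ]
    cells = [
        CellMeanRow(level_a=str(a), level_b=str(b), mean=float(r["mean"]),
                    se=float(r["se"]), n=int(r["n"]))
        for (a, b), r in res.cell_means.iterrows()
    ]
    posthoc = {}
    for factor in (cols["a"], cols["b"]):
        ph = res.bonferroni_posthoc(factor)
        posthoc[factor] = [
            PosthocRow(level_1=str(r.level_1), level_2=str(r.level_2), diff=r.diff,
                       se=r.se, t=r.t, p_raw=r.p_raw, p_bonferroni=r.p_bonferroni)
            for r in ph.itertuples()
        ]
    return AnovaBlock(
        design=f"{design.a.label} x {design.b.label}",
        factor_a=cols["a"],
        factor_b=cols["b"],
        effects=effects,
        rsquared=res.rsquared,
        cell_means=cells,
        posthoc=posthoc,
    )


def _regression_block(table, config) -> RegressionBlock:
    fit = ModeratedOLS(table, config.outcome, config.terms, center=config.center).fit()
    rows = []
    for name in fit.params.index:
        is_term = name != "const"
        rows.append(
            TermRow(
                term=name,
                coef=float(fit.params[name]),
                se=float(fit.bse[name]),
                t=float(fit.tvalues[name]),
                p=float(fit.pvalues[name]),
                squared_partial=fit.squared_partial(name) if is_term else None,
                squared_semipartial=fit.squared_semipartial(name) if is_term else None,
            )
        )
    jn_block = None
    flood = None
    if config.probe is not None:
        region = fit.jn_region(config.probe.focal, config.probe.moderator,
                               alpha=config.alpha)
        jn_block = JNBlock.from_region(region)
        grid = np.linspace(region.mod_range[0], region.mod_range[1], 21)
        flood_df = fit.floodlight(config.probe.focal, grid,
                                  moderator=config.probe.moderator, alpha=config.alpha)
        flood = flood_df.to_dict(orient="records")
    return RegressionBlock(
        terms=rows,
        rsquared=fit.rsquared,
        df_resid=fit.df_resid,
        centering=fit.centering,
        jn=jn_block,
        floodlight=flood,
    )


def run_comparison(table: pd.DataFrame, config: AnalysisConfig) -> ComparisonReport:
    """Run the full dichotomized-vs-continuous comparison on one table."""
    if config.outcome not in table.columns:
        raise TermLookupError(f"outcome column {config.outcome!r} not found")
    for t in config.terms:
        for v in term_variables(t):
            if v not in table.columns:
                raise TermLookupError(f"column {v!r} (term {t!r}) not found")
    from . import __version__

    return ComparisonReport(
        univariate=_univariate_block(table, config),
        anova=[_anova_block(table, config, d) for d in config.anova_designs],
        regression=_regression_block(table, config),
        provenance=Provenance(
            input_sha256=_table_hash(table),
            n_rows=len(table),
            config=config,
            package_version=__version__,
        ),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.4g}"


def _fmt_p(p: Optional[float]) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_markdown(report: ComparisonReport) -> str:
    lines = ["# Dichotomized ANOVA vs. continuous regression", ""]
    lines += ["## Univariate correlations", ""]
    lines.append(
        "| predictor | scheme | r (cont.) | p | r (dich.) | p | VE% cont. | VE% dich. | reduction% |"
    )
    lines.append("|---|---|---|---|---|---|---|---|---|")
    for u in report.univariate:
        lines.append(
            f"| {u.predictor} | {u.scheme} | {_fmt(u.r_continuous)} | {_fmt_p(u.p_continuous)}"
            f" | {_fmt(u.r_dichotomized)} | {_fmt_p(u.p_dichotomized)} | {_fmt(u.ve_continuous_pct)}"
            f" | {_fmt(u.ve_dichotomized_pct)} | {_fmt(u.percent_reduction_ve)} |"
        )
    lines.append("")
    for blk in report.anova:
        lines += [f"## ANOVA: {blk.design}", ""]
        lines.append("| effect | SS | df | F | p | partial eta^2 |")
        lines.append("|---|---|---|---|---|---|")
        for e in blk.effects:
            lines.append(
                f"| {e.effect} | {_fmt(e.sum_sq)} | {_fmt(e.df)} | {_fmt(e.F)} |"
                f" {_fmt_p(e.p)} | {_fmt(e.partial_eta_sq)} |"
            )
        lines.append("")
        lines.append(f"R^2 = {_fmt(blk.rsquared)}")
        lines.append("")
        lines.append("| cell | mean | SE | n |")
        lines.append("|---|---|---|---|")
        for c in blk.cell_means:
            lines.append(
                f"| {c.level_a} / {c.level_b} | {_fmt(c.mean)} | {_fmt(c.se)} | {c.n} |"
            )
        lines.append("")
    lines += ["## Continuous regression", ""]
    lines.append("| term | coef | SE | t | p | partial r^2 | semipartial r^2 |")
    lines.append("|---|---|---|---|---|---|---|")
    for t in report.regression.terms:
        lines.append(
            f"| {t.term} | {_fmt(t.coef)} | {_fmt(t.se)} | {_fmt(t.t)} | {_fmt_p(t.p)} |"
            f" {_fmt(t.squared_partial)} | {_fmt(t.squared_semipartial)} |"
        )
    lines.append("")
    lines.append(f"R^2 = {_fmt(report.regression.rsquared)}")
    if report.regression.centering:
        cen = ", ".join(f"{k} - {_fmt(v)}" for k, v in report.regression.centering.items())
        lines.append(f"centering: {cen}")
    if report.regression.jn is not None:
        jn = report.regression.jn
        lines += ["", f"## Johnson-Neyman region ({jn.kind})", ""]
        lines.append(
            f"focal {jn.focal}, moderator {jn.moderator}, alpha {jn.alpha},"
            f" t_crit {_fmt(jn.t_crit)}"
        )
        lines.append(f"boundaries (moderator scale): {[round(b, 4) for b in jn.boundaries]}")
        for (lo, hi), sig in zip(jn.intervals, jn.significant):
            lines.append(
                f"- [{_fmt(lo)}, {_fmt(hi)}]: "
                + ("significant" if sig else "not significant")
            )
    lines.append("")
    return "\n".join(lines)


def write_report(report: ComparisonReport, path: str | Path, format: str = "json") -> Path:
    """Write the report as schema-validated JSON or rendered markdown."""
    path = Path(path)
    if format == "json":
        text = report.to_json()
        ComparisonReport.from_json(text)  # round-trip validation
    elif format == "markdown":
        text = render_markdown(report)
    else:
        raise InvalidParameterError(f"unknown format {format!r}")
    path.write_text(text, encoding="utf-8")
    return path
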