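"""Group-level inference on tuning parameters.

The design is a 2 x 2 x 2 mixed (split-plot) layout: pairing phase
(pre/post) is a repeated, within-unit factor; drug (tPA/saline) and
pairing side (conditioning tone above/below the pre-pairing BF) are
between-unit factors.  For each tuning parameter (offset, gain, FWHM,
BF) the analysis yields the seven ANOVA effects (3 main, 3 two-way, 1
three-way) with F, degrees of freedom, p and partial eta squared, plus
a fixed family of post-hoc t-tests (paired within groups, independent
two-sample on per-unit pre-post differences between groups) with
Cohen's D / Dz effect sizes, 95% CIs and Benjamini-Hochberg FDR.

Because the within factor has exactly two levels, the classical mixed
ANOVA reduces exactly to two effect-coded OLS problems: the between
effects act on per-unit phase means, the within effects on per-unit
pre-post differences (the phase main effect is the difference-model
intercept).  Type-III single-df F statistics are the squared t's of the
corresponding coefficients; partial eta squared uses each stratum's own
error term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tuning import TuningFitResult, include_unit

__all__ = [
    "UnitRecord",
    "EffectRow",
    "PosthocRow",
    "classify_pairing_side",
    "mixed_anova",
    "posthoc_paired",
    "posthoc_independent",
    "fdr_bh",
    "full_analysis",
    "PairingStudy",
    "PairingStudyResults",
]

DRUGS = ("tPA", "saline")
SIDES = ("above", "below")
PARAMETERS = ("offset", "gain", "fwhm", "bf")

EFFECT_NAMES = (
    "drug", "side", "phase",
    "drug:side", "phase:drug", "phase:side",
    "phase:drug:side",
)


def classify_pairing_side(bf_pre_oct: float, pairing_oct: float) -> str:
    """Which side of the pre-pairing BF the conditioning tone sits on.

    Returns "above" when the pairing tone is above the BF.  Exact
    equality is undefined and raises; callers should exclude (and log)
    such units rather than assign a side silently.
    """
    if not (np.isfinite(bf_pre_oct) and np.isfinite(pairing_oct)):
        raise ValueError("BF and pairing frequency must be finite")
    if pairing_oct == bf_pre_oct:
        raise ValueError("pairing frequency equals the BF; side is undefined")
    return "above" if pairing_oct > bf_pre_oct else "below"


@dataclass
class UnitRecord:
    """Per-unit analysis state: metadata, both fits, inclusion flag."""

    unit_id: object
    drug: str
    pairing_frequency_hz: float
    side: str
    fit_pre: TuningFitResult
    fit_post: TuningFitResult
    included: bool = field(default=None)
    vaf_threshold: float = 0.70

    def __post_init__(self):
        if self.drug not in DRUGS:
            raise ValueError(f"drug must be one of {DRUGS}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.included is None:
            self.included = include_unit(self.fit_pre.vaf, self.fit_post.vaf,
                                         self.vaf_threshold)

    def parameter_rows(self) -> list[dict]:
        rows = []
        for phase, fit in (("pre", self.fit_pre), ("post", self.fit_post)):
            rows.append({
                "unit_id": self.unit_id, "drug": self.drug, "side": self.side,
                "phase": phase, "offset": fit.offset, "gain": fit.gain,
                "fwhm": fit.fwhm_oct, "bf": fit.bf_oct,
            })
        return rows


@dataclass(frozen=True)
class EffectRow:
    """One ANOVA effect: F(df1, df2), p, and partial eta squared."""

    parameter: str
    factor: str
    F: float
    df1: int
    df2: int
    p: float
    eta_sq_p: float


@dataclass(frozen=True)
class PosthocRow:
    """One post-hoc comparison with CI and standardized effect size."""

    comparison: str
    paired: bool
    n: int
    t: float
    df: int
    p: float
    diff: float
    ci_low: float
    ci_high: float
    effect_size: float
    effect_kind: str  # "Dz" for paired, "D" for independent
    p_fdr: float = np.nan
    parameter: str = ""


def _wide_by_phase(data: pd.DataFrame, value: str) -> pd.DataFrame:
    """Pivot a long parameter table to one row per unit with pre/post columns."""
    wide = data.pivot_table(index=["unit_id", "drug", "side"], columns="phase",
                            values=value, aggfunc="first").reset_index()
    if "pre" not in wide or "post" not in wide or wide[["pre", "post"]].isna().any().any():
        raise ValueError("every unit needs both a pre and a post value")
    return wide


def mixed_anova(data: pd.DataFrame, value: str = "value") -> list[EffectRow]:
    """Three-way mixed ANOVA (phase within; drug, side between), Type III.

    ``data`` is long format with columns ``unit_id, drug, side, phase``
    and the value column.  Returns the seven effects in
    :data:`EFFECT_NAMES` order.  Raises if any drug x side cell has
    fewer than two units or a unit is missing a phase.
    """
    wide = _wide_by_phase(data, value)
    for d in DRUGS:
        for s in SIDES:
            n_cell = int(((wide["drug"] == d) & (wide["side"] == s)).sum())
            if n_cell < 2:
                raise ValueError(f"cell {d}/{s} has {n_cell} unit(s); need >= 2")
    n = len(wide)
    a = np.where(wide["drug"].to_numpy() == "tPA", 1.0, -1.0)
    b = np.where(wide["side"].to_numpy() == "above", 1.0, -1.0)
    X = np.column_stack([np.ones(n), a, b, a * b])
    m = (wide["pre"].to_numpy(float) + wide["post"].to_numpy(float)) / 2.0
    d_ = wide["pre"].to_numpy(float) - wide["post"].to_numpy(float)
    df2 = n - 4
    if df2 < 1:
        raise ValueError("not enough units for the 2x2 between design")
    xtx_inv = np.linalg.inv(X.T @ X)

    def stratum(y, terms):
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        sse = float(resid @ resid)
        mse = sse / df2
        rows = []
        for j, factor in terms:
            ss = beta[j] ** 2 / xtx_inv[j, j]
            F = ss / mse if mse > 0 else np.inf
            p = float(sps.f.sf(F, 1, df2))
            rows.append(EffectRow(parameter=value, factor=factor, F=float(F),
                                  df1=1, df2=df2, p=p,
                                  eta_sq_p=float(ss / (ss + sse)) if ss + sse > 0 else 0.0))
        return rows

    between = stratum(m, [(1, "drug"), (2, "side"), (3, "drug:side")])
    within = stratum(d_, [(0, "phase"), (1, "phase:drug"), (2, "phase:side"),
                          (3, "phase:drug:side")])
    by_name = {r.factor: r for r in between + within}
    return [by_name[name] for name in EFFECT_NAMES]


def posthoc_paired(values_pre, values_post, comparison: str = "pre vs post") -> PosthocRow:
    """Two-sided paired t-test with Cohen's Dz = mean(diff)/SD(diff).

    The reported difference is mean(pre) - mean(post), so a negative
    difference means the parameter increased after pairing.
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("paired samples must share a length >= 2")
    d = pre - post
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("pre-post differences have zero variance")
    n = d.size
    res = sps.ttest_rel(pre, post)
    diff = float(np.mean(d))
    se = sd / np.sqrt(n)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return PosthocRow(
        comparison=comparison, paired=True, n=n, t=float(res.statistic),
        df=n - 1, p=float(res.pvalue), diff=diff,
        ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
        effect_size=diff / sd, effect_kind="Dz",
    )


def posthoc_independent(group_a, group_b,
                        comparison: str = "group a vs group b") -> PosthocRow:
    """Two-sided two-sample t-test (pooled variance) with Cohen's D.

    Used on per-unit pre-post differences to compare pairing effects
    between groups (difference of differences).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    df = na + nb - 2
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    if pooled_var == 0:
        raise ValueError("pooled variance is zero")
    pooled_sd = float(np.sqrt(pooled_var))
    res = sps.ttest_ind(a, b, equal_var=True)
    diff = float(np.mean(a) - np.mean(b))
    se = pooled_sd * np.sqrt(1.0 / na + 1.0 / nb)
    tcrit = float(sps.t.ppf(0.975, df))
    return PosthocRow(
        comparison=comparison, paired=False, n=na + nb, t=float(res.statistic),
        df=df, p=float(res.pvalue), diff=diff,
        ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
        effect_size=diff / pooled_sd, effect_kind="D",
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _posthoc_family(wide: pd.DataFrame, parameter: str) -> list[PosthocRow]:
    """The fixed 16-comparison post-hoc family for one tuning parameter.

    Pooled-by-drug and pooled-by-side paired tests with their
    between-group companions mirror the two-way interaction follow-ups;
    the four per-cell paired tests and six cell-pair difference
    comparisons mirror the three-way follow-up tables.
    """
    rows: list[PosthocRow] = []

    def paired_for(mask, label):
        sub = wide[mask]
        rows.append(posthoc_paired(sub["pre"], sub["post"],
                                   comparison=f"{label}: pre vs post"))

    def diffs_for(mask):
        sub = wide[mask]
        return (sub["pre"] - sub["post"]).to_numpy()

    for d in DRUGS:
        paired_for(wide["drug"] == d, d)
    rows.append(posthoc_independent(
        diffs_for(wide["drug"] == "tPA"), diffs_for(wide["drug"] == "saline"),
        comparison="tPA vs saline: pre-post difference"))
    for s in SIDES:
        paired_for(wide["side"] == s, s)
    rows.append(posthoc_independent(
        diffs_for(wide["side"] == "above"), diffs_for(wide["side"] == "below"),
        comparison="above vs below: pre-post difference"))
    cells = [(d, s) for d in DRUGS for s in SIDES]
    for d, s in cells:
        paired_for((wide["drug"] == d) & (wide["side"] == s), f"{d}/{s}")
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d1, s1 = cells[i]
            d2, s2 = cells[j]
            rows.append(posthoc_independent(
                diffs_for((wide["drug"] == d1) & (wide["side"] == s1)),
                diffs_for((wide["drug"] == d2) & (wide["side"] == s2)),
                comparison=f"{d1}/{s1} vs {d2}/{s2}: pre-post difference"))
    adj = fdr_bh([r.p for r in rows])
    return [PosthocRow(**{**asdict(r), "p_fdr": float(q), "parameter": parameter})
            for r, q in zip(rows, adj)]


def full_analysis(data: pd.DataFrame,
                  parameters=PARAMETERS) -> dict[str, dict[str, pd.DataFrame]]:
    """Run the ANOVA and post-hoc family for each tuning parameter.

    ``data`` is long format: columns ``unit_id, drug, side, phase`` plus
    one column per parameter.  Returns, per parameter, an ``anova``
    table (7 effects) and a ``posthoc`` table (16 FDR-adjusted rows).
    """
    out = {}
    for param in parameters:
        if param not in data.columns:
            raise ValueError(f"data has no column {param!r}")
        effects = mixed_anova(data, value=param)
        wide = _wide_by_phase(data, param)
        posthocs = _posthoc_family(wide, param)
        out[param] = {
            "anova": pd.DataFrame([asdict(e) for e in effects]),
            "posthoc": pd.DataFrame([asdict(r) for r in posthocs]),
        }
    return out


class PairingStudy:
    """Model object for the full pairing-effect inference on a cohort.

    Built from a long-format table of fitted tuning parameters (two rows
    per unit, one per phase) or from :class:`UnitRecord` objects; ``fit``
    runs the mixed ANOVA plus post-hoc families for every parameter and
    returns a :class:`PairingStudyResults`.
    """

    def __init__(self, data: pd.DataFrame, parameters=PARAMETERS):
        required = {"unit_id", "drug", "side", "phase"} | set(parameters)
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"study table missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.parameters = tuple(parameters)

    @classmethod
    def from_unit_records(cls, records, only_included: bool = True) -> "PairingStudy":
        rows = []
        for rec in records:
            if only_included and not rec.included:
                continue
            rows.extend(rec.parameter_rows())
        if not rows:
            raise ValueError("no included units to analyse")
        return cls(pd.DataFrame(rows))

    def fit(self) -> "PairingStudyResults":
        tables = full_analysis(self.data, parameters=self.parameters)
        wide = _wide_by_phase(self.data, self.parameters[0])
        cell_counts = (wide.groupby(["drug", "side"]).size()
                       .rename("n_units").reset_index())
        return PairingStudyResults(tables=tables, cell_counts=cell_counts,
                                   n_units=len(wide), parameters=self.parameters)


@dataclass
class PairingStudyResults:
    """ANOVA and post-hoc tables per tuning parameter, with writers."""

    tables: dict
    cell_counts: pd.DataFrame
    n_units: int
    parameters: tuple

    def anova(self, parameter: str) -> pd.DataFrame:
        return self.tables[parameter]["anova"]

    def posthoc(self, parameter: str) -> pd.DataFrame:
        return self.tables[parameter]["posthoc"]

    def flat_posthoc_table(self) -> pd.DataFrame:
        """All post-hoc rows, one flat table mirroring the printed columns."""
        return pd.concat([self.posthoc(p) for p in self.parameters],
                         ignore_index=True)[
            ["parameter", "comparison", "paired", "n", "t", "df", "p", "p_fdr",
             "diff", "ci_low", "ci_high", "effect_size", "effect_kind"]]

    def flat_anova_table(self) -> pd.DataFrame:
        return pd.concat([self.anova(p) for p in self.parameters],
                         ignore_index=True)

    def to_dict(self) -> dict:
        """Nested machine-readable structure: parameter -> effects/posthocs."""
        return {
            "n_units": self.n_units,
            "cells": self.cell_counts.to_dict(orient="records"),
            "parameters": {
                p: {
                    "anova": self.anova(p).to_dict(orient="records"),
                    "posthoc": self.posthoc(p).to_dict(orient="records"),
                }
                for p in self.parameters
            },
        }

    def summary(self) -> str:
        lines = [f"Pairing-effect analysis: {self.n_units} units"]
        for _, row in self.cell_counts.iterrows():
            lines.append(f"  {row['drug']}/{row['side']}: n={row['n_units']}")
        for p in self.parameters:
            lines.append(f"\n== {p} ==")
            for _, e in self.anova(p).iterrows():
                star = " *" if e["p"] < 0.05 else ""
                lines.append(
                    f"  {e['factor']:<18} F({e['df1']},{e['df2']}) = "
                    f"{e['F']:7.3f}  p = {e['p']:.4f}  eta2p = {e['eta_sq_p']:.3f}{star}"
                )
        return "\n".join(lines)
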