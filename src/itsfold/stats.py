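"""Summary statistics and class-comparison tests for structure metrics.

The central object is the metric table: one row per sequence with its class
(real vs random), dataset half (ITS1-matched vs ITS2-matched), and the
structure metrics (MFE energy, ensemble size, paired bases, hairpins).
Class differences are tested with a two-way ANOVA — factors sequence class
and dataset half, type-II sums of squares — fitted with statsmodels OLS;
the "ratio test" applies the same machinery to the per-sequence
energy/ensemble-size ratio, which is expected to show no class effect when
energy and ensemble size scale together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

#: canonical metric-table columns
CLASS_COL = "seq_class"
HALF_COL = "half"
METRICS = ["length", "mfe_energy", "n_structures", "n_paired", "pct_paired",
           "n_hairpins", "n_stems"]


def make_metric_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble and validate a metric table from per-sequence dicts."""
    df = pd.DataFrame(rows)
    for col in ("seq_id", CLASS_COL, "mfe_energy", "n_structures"):
        if col not in df.columns:
            raise ValueError(f"metric table missing required column {col!r}")
        if df[col].isna().any():
            raise ValueError(f"metric table has missing values in {col!r}")
    return df


def summarize(
    table: pd.DataFrame,
    by: list[str] | str = CLASS_COL,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Mean/median/min/max per group and metric (medians by the midpoint
    convention for even group sizes, i.e. the ordinary sample median)."""
    if table.empty:
        raise ValueError("empty metric table")
    if isinstance(by, str):
        by = [by]
    metrics = metrics or [m for m in METRICS if m in table.columns]
    out = (
        table.groupby(by, dropna=False)[metrics]
        .agg(["mean", "median", "min", "max", "count"])
        .reset_index()
    )
    out.columns = [
        c[0] if not c[1] else f"{c[0]}_{c[1]}" for c in out.columns.to_flat_index()
    ]
    return out


@dataclass
class ComparisonResult:
    """Per-metric ANOVA comparison between sequence classes."""

    metric: str
    anova: pd.DataFrame  # terms x (sum_sq, df, F, PR(>F))
    group_summary: pd.DataFrame
    degenerate: bool = False  # zero-variance response: F undefined

    @property
    def p_class(self) -> float:
        """P-value of the sequence-class factor (NaN when degenerate)."""
        if self.degenerate:
            return float("nan")
        return float(self.anova.loc[f"C({CLASS_COL})", "PR(>F)"])

    @property
    def f_class(self) -> float:
        if self.degenerate:
            return float("nan")
        return float(self.anova.loc[f"C({CLASS_COL})", "F"])


def anova_two_way(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = (CLASS_COL, HALF_COL),
) -> ComparisonResult:
    """Two-way ANOVA (type-II sums of squares) of a metric.

    Requires >= 2 levels per factor and >= 2 observations per cell; a
    degenerate design (an empty cell) raises with the offending cells
    listed. A response with zero variance is flagged and p reported as NaN.
    """
    fa, fb = factors
    df = table[[response, fa, fb]].dropna().copy()
    cells = df.groupby([fa, fb], observed=True).size()
    levels_a = df[fa].nunique()
    levels_b = df[fb].nunique()
    if levels_a < 2 or levels_b < 2:
        raise ValueError(
            f"need >= 2 levels per factor, got {levels_a} x {levels_b}"
        )
    expected = levels_a * levels_b
    if len(cells) < expected or (cells < 2).any():
        raise ValueError(f"degenerate design; cell counts:\n{cells}")
    grouped = summarize(df, by=[fa, fb], metrics=[response])
    if np.isclose(df[response].var(ddof=0), 0.0):
        empty = pd.DataFrame(
            index=[f"C({fa})", f"C({fb})", f"C({fa}):C({fb})", "Residual"],
            columns=["sum_sq", "df", "F", "PR(>F)"],
            dtype=float,
        )
        return ComparisonResult(response, empty, grouped, degenerate=True)
    model = smf.ols(f"Q('{response}') ~ C({fa}) * C({fb})", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table_out = anova_lm(model, typ=2)
    table_out.index = [str(ix).replace(f"Q('{response}')", response)
                       for ix in table_out.index]
    return ComparisonResult(response, table_out, grouped)


def anova_one_way(table: pd.DataFrame, response: str,
                  factor: str = CLASS_COL) -> ComparisonResult:
    """One-way fallback for designs with a single dataset half."""
    df = table[[response, factor]].dropna().copy()
    if df[factor].nunique() < 2:
        raise ValueError(f"need >= 2 levels of {factor!r}")
    grouped = summarize(df, by=[factor], metrics=[response])
    if np.isclose(df[response].var(ddof=0), 0.0):
        empty = pd.DataFrame(
            index=[f"C({factor})", "Residual"],
            columns=["sum_sq", "df", "F", "PR(>F)"], dtype=float,
        )
        return ComparisonResult(response, empty, grouped, degenerate=True)
    model = smf.ols(f"Q('{response}') ~ C({factor})", data=df).fit()
    out = anova_lm(model, typ=2)
    return ComparisonResult(response, out, grouped)


def ratio_comparison(
    table: pd.DataFrame,
    factors: tuple[str, str] = (CLASS_COL, HALF_COL),
) -> ComparisonResult:
    """ANOVA of the per-sequence energy / ensemble-size ratio.

    When MFE and ensemble size scale together within every class, the ratio
    carries no class signal even if both raw metrics differ strongly.
    """
    if (table["n_structures"] < 1).any():
        raise ValueError("n_structures must be >= 1 for every sequence")
    work = table.copy()
    work["energy_count_ratio"] = work["mfe_energy"] / work["n_structures"]
    res = anova_two_way(work, "energy_count_ratio", factors)
    return res


def write_metric_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_metric_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
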