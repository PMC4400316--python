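"""Geographic and temporal aggregation of tweet sentiment.

Positive-sentiment proportions are tabulated by city or by local hour bin,
compared with a Pearson chi-square test of homogeneity on the k x 2
contingency table, and (for cities) correlated against demographic/climate
covariates with Spearman rank correlations.  These are descriptive,
ecological-level analyses: correlations across city aggregates say nothing
about individual tweeters (the ecological fallacy), and no causal claims are
attached to any reported association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupProportionTable",
    "CorrelationResult",
    "proportion_by_group",
    "homogeneity_test",
    "spearman_correlation",
    "load_covariates",
    "correlate_covariates",
    "COVARIATE_COLUMNS",
]

# Documented covariate CSV schema (one row per city).
COVARIATE_COLUMNS = [
    "city", "population", "density", "median_age", "pct_hs_grad",
    "pct_bachelors", "median_income", "pct_below_poverty", "pct_uninsured",
    "sep_avg_high_temp", "sep_precip_days", "latitude", "longitude",
    "utc_offset",
]


@dataclass
class GroupProportionTable:
    """Per-group positive counts with percentages, plus the cross-group median."""

    table: pd.DataFrame  # columns: group, n_positive, n_total, percent_positive
    grouping: str
    median_percent: float

    def __len__(self) -> int:
        return len(self.table)


def proportion_by_group(
    groups: Sequence,
    positives: Sequence[bool],
    grouping: str = "city",
) -> GroupProportionTable:
    """Tabulate positive-sentiment proportions per group label.

    ``groups[i]`` is the grouping attribute (city or hour bin) of result i and
    ``positives[i]`` whether it was classified positive.
    """
    if len(groups) != len(positives):
        raise ValueError("groups and positives must align")
    df = pd.DataFrame({"group": list(groups), "positive": [bool(p) for p in positives]})
    agg = (
        df.groupby("group", sort=True)["positive"]
        .agg(n_positive="sum", n_total="count")
        .reset_index()
    )
    agg["percent_positive"] = 100.0 * agg["n_positive"] / agg["n_total"]
    return GroupProportionTable(
        table=agg, grouping=grouping,
        median_percent=float(agg["percent_positive"].median()),
    )


def homogeneity_test(table: GroupProportionTable) -> tuple[float, int, float]:
    """Pearson chi-square test that positive proportions are equal across groups.

    Returns (statistic, df, p) for the k x 2 table of (positive, negative)
    counts; df = k - 1.  Attaches a warning when any expected cell is < 1.
    """
    t = table.table
    if len(t) < 2:
        raise ValueError("need at least 2 groups for a homogeneity test")
    if (t["n_total"] <= 0).any():
        raise ValueError("all groups must have n_total > 0")
    obs = np.column_stack([t["n_positive"], t["n_total"] - t["n_positive"]])
    if obs.sum(axis=0).min() == 0:
        # all-positive or all-negative: every group identical in that margin
        return 0.0, len(t) - 1, 1.0
    stat, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if expected.min() < 1:
        warnings.warn("chi-square approximation unreliable: expected cell count < 1")
    return float(stat), int(df), float(p)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    variable: Optional[str] = None


def spearman_correlation(x: Sequence[float], y: Sequence[float],
                         variable: Optional[str] = None) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties; p from the
    t-approximation with n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=len(x), variable=variable)


def load_covariates(path: str | Path) -> pd.DataFrame:
    """Read the city covariate CSV (see :data:`COVARIATE_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = [c for c in ("city",) if c not in df.columns]
    if missing:
        raise ValueError(f"covariate CSV missing required columns: {missing}")
    return df


def correlate_covariates(
    city_table: GroupProportionTable,
    covariates: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
) -> list[CorrelationResult]:
    """Spearman rho between per-city percent positive and each covariate.

    Cities are matched by label; covariates absent for some city drop that
    city pairwise. Returns one result per covariate column, ordered by |rho|
    descending (the layout used for reporting).
    """
    merged = city_table.table.merge(
        covariates, left_on="group", right_on="city", how="inner")
    if columns is None:
        columns = [c for c in covariates.columns
                   if c not in ("city", "utc_offset")
                   and pd.api.types.is_numeric_dtype(covariates[c])]
    out = []
    for col in columns:
        sub = merged[[col, "percent_positive"]].dropna()
        if len(sub) < 4 or sub[col].nunique() < 2:
            continue
        out.append(spearman_correlation(sub[col], sub["percent_positive"], variable=col))
    out.sort(key=lambda r: -abs(r.rho))
    return out
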