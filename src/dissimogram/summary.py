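"""Across-year summaries of fitted nuggets and descriptive statistics.

Nuggets are fitted per region x year (and per stratum: all plots,
high/low management intensity, turnover cut-offs); this module aggregates
the per-year values into summary rows — mean, sample standard deviation,
minimum, maximum — and 95% t-based confidence intervals for the mean, and
provides descriptive richness/abundance tables plus the (purely
descriptive) nugget ~ richness regression.

Missing entries ("n/a": non-converged fits or nuggets outside [0, 1])
propagate and are never imputed; summary statistics are computed over the
non-missing yearly values only.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .community import CommunityMatrix
from .exceptions import ValidationError


def _clean(values: Iterable) -> np.ndarray:
    arr = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        float,
    )
    return arr


def across_year_stats(yearly: Iterable[float]) -> dict:
    """Mean, sample sd, min, max and n over non-missing yearly nuggets.

    The standard deviation uses the n-1 divisor; with a single value the
    sd is reported missing (nan).  All-missing input is an error.
    """
    vals = _clean(yearly)
    if vals.size == 0:
        raise ValidationError("no non-missing yearly values")
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n": int(vals.size),
    }


def ci95(yearly: Iterable[float]) -> dict:
    """95% t confidence interval for the mean of yearly nuggets.

    Uses mean +/- t_{0.975, n-1} * sd / sqrt(n); requires at least two
    non-missing values.
    """
    vals = _clean(yearly)
    if vals.size < 2:
        raise ValidationError("need >= 2 non-missing values for a CI")
    n = vals.size
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return {
        "mean": mean,
        "halfwidth": half,
        "lower": mean - half,
        "upper": mean + half,
        "n": int(n),
    }


def nugget_summary_table(series: Mapping[str, Mapping]) -> pd.DataFrame:
    """Assemble per-region/stratum yearly nuggets into a summary table.

    ``series`` maps a label (e.g. ``"north/gompertz"``) to a mapping with
    keys ``yearly`` (year -> nugget or nan) and optionally ``cumulative``.
    The output mirrors the per-year rows plus Mean / sd / Minimum /
    Maximum summary rows, with nan marking "n/a" cells.
    """
    frames = {}
    for label, entry in series.items():
        yearly = dict(entry["yearly"])
        col = {f"{y}": yearly[y] for y in sorted(yearly)}
        if "cumulative" in entry:
            col["cumulative"] = entry["cumulative"]
        vals = _clean(yearly.values())
        if vals.size:
            s = across_year_stats(yearly.values())
            col.update(
                {
                    "mean": s["mean"],
                    "sd": s["sd"],
                    "min": s["min"],
                    "max": s["max"],
                }
            )
        else:
            col.update({"mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan})
        frames[label] = col
    return pd.DataFrame(frames)


def richness_abundance_summary(
    matrices: Sequence[CommunityMatrix],
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-scope descriptive statistics of plot richness and abundance.

    For each matrix: per-plot richness (and total abundance when the
    matrix is an abundance matrix), summarized as median and quartiles,
    optionally per region.
    """
    rows = []
    region_of = (
        meta.set_index("plot_id")["region"] if meta is not None else None
    )
    for m in matrices:
        rich = m.richness()
        abund = m.total_abundance() if m.kind == "abundance" else None
        groups = (
            rich.groupby(region_of.reindex(rich.index))
            if region_of is not None
            else [("all", rich)]
        )
        for region, r in groups:
            q1, med, q3 = np.percentile(r, [25, 50, 75])
            row = {
                "scope": m.scope,
                "region": region,
                "n_plots": int(len(r)),
                "richness_median": med,
                "richness_q1": q1,
                "richness_q3": q3,
            }
            if abund is not None:
                a = abund.loc[r.index]
                aq1, amed, aq3 = np.percentile(a, [25, 50, 75])
                row.update(
                    abundance_median=amed, abundance_q1=aq1, abundance_q3=aq3
                )
            rows.append(row)
    return pd.DataFrame(rows)


def nugget_richness_association(nuggets, richness) -> dict:
    """Descriptive OLS of nugget on richness: slope, F, p, adjusted R².

    No decision logic is attached; this is a reported diagnostic only.
    """
    x = np.asarray(richness, float)
    y = np.asarray(nuggets, float)
    if len(x) < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.std(x) == 0:
        raise ValidationError("zero variance in the predictor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "F": float(fit.fvalue),
        "p": float(fit.f_pvalue),
        "r2": float(fit.rsquared),
        "adj_r2": float(fit.rsquared_adj),
        "n": int(fit.nobs),
    }


def format_fixed(value: float, decimals: int = 4) -> str:
    """Fixed-decimal formatting with "n/a" for missing cells."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "n/a"
    return f"{value:.{decimals}f}"
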