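"""Inter-annual species turnover per plot, and turnover-based plot filters.

If high nuggets were driven by incomplete sampling, plots whose species
lists churn between years would inflate them.  The check: for each plot,
split its cumulative species list into *persistent* species (present in at
least ``threshold`` of the surveyed years; default 4 of 5) and *transient*
ones, define turnover as the transient fraction of the cumulative list,
and re-fit the dissimogram after excluding plots whose turnover exceeds a
cut-off (60%, 70% or 80%).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import pandas as pd

from .community import CommunityMatrix
from .exceptions import ConfigError, EmptySelectionError

DEFAULT_PERSISTENCE_YEARS = 4


def scaled_persistence_threshold(n_years: int, threshold: int | None = None) -> int:
    """Persistence threshold, scaled when fewer than 5 years are available.

    With the default 4-of-5 rule, supplying ``n_years < 5`` scales the
    threshold to ``ceil(0.8 * n_years)``.
    """
    if threshold is not None:
        if not 1 <= threshold <= n_years:
            raise ConfigError(
                f"persistence threshold {threshold} outside 1..{n_years}"
            )
        return threshold
    if n_years >= 5:
        return DEFAULT_PERSISTENCE_YEARS
    return math.ceil(0.8 * n_years)


def _presence_years(per_year: Mapping[int, CommunityMatrix], plot) -> pd.Series:
    """Number of years each species was present at ``plot``."""
    rows = []
    for year, matrix in per_year.items():
        if plot not in matrix.data.index:
            raise EmptySelectionError(f"plot {plot!r} absent from year {year}")
        rows.append(matrix.data.loc[plot])
    return pd.DataFrame(rows).fillna(0).astype(int).sum(axis=0)


def persistent_species(
    per_year: Mapping[int, CommunityMatrix], plot, threshold: int | None = None
) -> set:
    """Species present at ``plot`` in at least ``threshold`` years."""
    thr = scaled_persistence_threshold(len(per_year), threshold)
    counts = _presence_years(per_year, plot)
    return set(counts.index[counts >= thr])


def plot_turnover(
    per_year: Mapping[int, CommunityMatrix], plot, threshold: int | None = None
) -> dict:
    """Turnover record for one plot.

    Turnover is the transient fraction of the cumulative species list:
    ``(n_cumulative - n_persistent) / n_cumulative``.  Undefined (nan) when
    the plot's cumulative list is empty; such plots are flagged.
    """
    thr = scaled_persistence_threshold(len(per_year), threshold)
    counts = _presence_years(per_year, plot)
    n_cum = int((counts > 0).sum())
    n_pers = int((counts >= thr).sum())
    turnover = (n_cum - n_pers) / n_cum if n_cum > 0 else float("nan")
    return {
        "plot_id": plot,
        "n_cumulative": n_cum,
        "n_persistent": n_pers,
        "turnover": turnover,
    }


def turnover_table(
    per_year: Mapping[int, CommunityMatrix], threshold: int | None = None
) -> pd.DataFrame:
    """Turnover records for every plot, as a DataFrame."""
    plots = next(iter(per_year.values())).plots
    return pd.DataFrame([plot_turnover(per_year, p, threshold) for p in plots])


def filter_by_turnover(
    plots: Sequence, records: pd.DataFrame, cutoff: float
) -> set:
    """Plots whose turnover does not exceed ``cutoff`` (strict exclusion).

    A plot with turnover exactly equal to the cut-off is retained; plots
    with undefined turnover (empty cumulative list) are excluded.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ConfigError(f"turnover cutoff {cutoff} outside (0, 1]")
    rec = records.set_index("plot_id")["turnover"]
    missing = [p for p in plots if p not in rec.index]
    if missing:
        raise EmptySelectionError(f"plots without turnover records: {missing[:10]}")
    return {p for p in plots if rec[p] <= cutoff}
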