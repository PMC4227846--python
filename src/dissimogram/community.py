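"""Survey ingestion and community-matrix construction.

Point-count survey data arrive as long-format records: one row per
(plot, year, survey round, species) with the number of territorial males
recorded.  This module validates those records and aggregates them into
plots x species community matrices under the standard rules for repeated
point counts:

* the relative abundance of a species at a plot in a year is the *maximum*
  count over the survey rounds of that year;
* a species is *present* at a plot in a year if it was recorded at least
  once in any round of that year;
* the *cumulative* composition of a plot over a span of years is the union
  of its per-year presences.

Plot metadata (projected coordinates in metres, region, and a per-plot
management-intensity score) are read from a companion table; the intensity
score is consumed as given and split at the regional median to form
high/low-intensity strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    EmptySelectionError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("dissimogram")

#: canonical column names for survey records
SURVEY_COLUMNS = ("plot_id", "region", "year", "round", "species", "count")
#: canonical column names for plot metadata
PLOT_COLUMNS = ("plot_id", "region", "x", "y", "intensity")


@dataclass
class SurveySchema:
    """Column-name mapping and survey design for a raw CSV.

    ``columns`` maps canonical names (see :data:`SURVEY_COLUMNS`) to the
    names used in the file; canonical names absent from the mapping are
    assumed to appear verbatim.  ``n_rounds`` is the number of survey
    rounds per year (default 5).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    n_rounds: int = 5

    def rename_map(self) -> dict:
        return {v: k for k, v in self.columns.items()}


def read_surveys(
    path,
    schema: SurveySchema | None = None,
    plots: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format survey CSV.

    Parameters
    ----------
    path : str or file-like
        CSV with (possibly renamed) columns ``plot_id, region, year, round,
        species, count``.
    schema : SurveySchema, optional
        Column mapping and number of rounds; defaults to canonical names
        and 5 rounds.
    plots : DataFrame, optional
        Plot metadata (from :func:`read_plots`); survey plots absent from
        it are reported as a warning.

    Returns
    -------
    DataFrame with canonical columns, validated:
    duplicate (plot, year, round, species) keys and negative counts raise
    :class:`~dissimogram.exceptions.ValidationError`; missing columns raise
    :class:`~dissimogram.exceptions.SchemaError` naming the column.
    """
    schema = schema or SurveySchema()
    table = pd.read_csv(path)
    table = table.rename(columns=schema.rename_map())
    return validate_surveys(table, schema=schema, plots=plots)


def validate_surveys(
    table: pd.DataFrame,
    schema: SurveySchema | None = None,
    plots: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Validate an in-memory survey table (see :func:`read_surveys`)."""
    schema = schema or SurveySchema()
    for col in SURVEY_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"survey table is missing required column {col!r}")
    table = table.loc[:, list(SURVEY_COLUMNS)].copy()
    table["count"] = pd.to_numeric(table["count"])
    negative = table.index[table["count"] < 0]
    if len(negative):
        raise ValidationError(
            f"negative count at row(s) {list(negative[:10])}"
        )
    bad_round = table.index[
        (table["round"] < 1) | (table["round"] > schema.n_rounds)
    ]
    if len(bad_round):
        raise ValidationError(
            f"survey round outside 1..{schema.n_rounds} at row(s) "
            f"{list(bad_round[:10])}"
        )
    key = ["plot_id", "year", "round", "species"]
    dupes = table[table.duplicated(key, keep=False)]
    if len(dupes):
        keys = dupes[key].drop_duplicates().values.tolist()
        raise ValidationError(
            f"duplicate (plot, year, round, species) records: {keys[:10]}"
        )
    if plots is not None:
        unknown = set(table["plot_id"]) - set(plots["plot_id"])
        if unknown:
            logger.warning(
                "%d survey plot(s) absent from plot metadata: %s",
                len(unknown),
                sorted(unknown)[:10],
            )
    return table


def read_plots(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read plot metadata: plot_id, region, x, y (metres), intensity."""
    table = pd.read_csv(path)
    if columns:
        table = table.rename(columns={v: k for k, v in columns.items()})
    for col in PLOT_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"plot table is missing required column {col!r}")
    table = table.loc[:, list(PLOT_COLUMNS)].copy()
    if table["plot_id"].duplicated().any():
        raise ValidationError("duplicate plot_id in plot metadata")
    if not np.isfinite(table[["x", "y"]].to_numpy(float)).all():
        raise ValidationError("non-finite plot coordinates")
    return table


def exclude_species(table: pd.DataFrame, excluded: Iterable[str]) -> pd.DataFrame:
    """Drop all records of the given species (e.g. aerial foragers such as
    swifts and swallows that are surveyed too irregularly for point counts).

    Excluding a species not present is a no-op.
    """
    excluded = set(excluded)
    if not excluded:
        return table
    return table[~table["species"].isin(excluded)].reset_index(drop=True)


class CommunityMatrix:
    """A plots x species matrix of abundances or incidences.

    Parameters
    ----------
    data : DataFrame
        Index = plot ids, columns = species ids, non-negative values.
    kind : {"abundance", "incidence"}
    scope : str
        ``"year:<y>"`` for a single year or ``"cumulative:<y0>-<y1>"``.
    """

    def __init__(self, data: pd.DataFrame, kind: str, scope: str):
        if kind not in ("abundance", "incidence"):
            raise ValueError(f"unknown matrix kind {kind!r}")
        values = data.to_numpy()
        if (values < 0).any():
            raise ValidationError("negative community-matrix values")
        if kind == "incidence" and not np.isin(values, (0, 1)).all():
            raise ValidationError("incidence matrix must contain only 0/1")
        self.data = data
        self.kind = kind
        self.scope = scope

    @property
    def plots(self) -> list:
        return list(self.data.index)

    @property
    def species(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def richness(self) -> pd.Series:
        """Per-plot species richness (count of species with value > 0)."""
        return (self.data > 0).sum(axis=1)

    def total_abundance(self) -> pd.Series:
        """Per-plot summed abundance (row sums)."""
        return self.data.sum(axis=1)

    def subset_plots(self, plots: Sequence) -> "CommunityMatrix":
        keep = [p for p in self.plots if p in set(plots)]
        return CommunityMatrix(self.data.loc[keep], self.kind, self.scope)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CommunityMatrix {self.kind} {self.scope} "
            f"{len(self.plots)} plots x {len(self.species)} species>"
        )


def max_abundance(
    table: pd.DataFrame,
    year: int,
    plots: Sequence | None = None,
    species: Sequence | None = None,
) -> CommunityMatrix:
    """Maximum count over survey rounds of ``year``, per plot x species.

    ``plots``/``species`` fix the matrix axes (species never recorded at a
    plot get 0); by default the axes are all plots and species appearing
    anywhere in ``table`` so that per-year matrices are mutually aligned.
    """
    sel = table[table["year"] == year]
    if sel.empty:
        raise EmptySelectionError(f"no survey records for year {year}")
    plots = list(plots) if plots is not None else sorted(table["plot_id"].unique())
    species = (
        list(species) if species is not None else sorted(table["species"].unique())
    )
    wide = sel.pivot_table(
        index="plot_id", columns="species", values="count", aggfunc="max"
    )
    wide = wide.reindex(index=plots, columns=species).fillna(0).astype(int)
    wide.index.name = "plot_id"
    return CommunityMatrix(wide, kind="abundance", scope=f"year:{year}")


def to_presence(matrix: CommunityMatrix) -> CommunityMatrix:
    """Threshold an abundance matrix to 0/1 incidence (idempotent)."""
    data = (matrix.data > 0).astype(int)
    return CommunityMatrix(data, kind="incidence", scope=matrix.scope)


def cumulative_composition(per_year: Sequence[CommunityMatrix]) -> CommunityMatrix:
    """Element-wise union of per-year incidence matrices.

    A species is cumulatively present at a plot iff it was present there in
    at least one year.  All matrices must share the plot set; species lists
    are unioned.
    """
    if not per_year:
        raise ValueError("no matrices supplied")
    plot_sets = {frozenset(m.plots) for m in per_year}
    if len(plot_sets) != 1:
        raise AlignmentError("per-year matrices do not share a plot set")
    for m in per_year:
        if m.kind != "incidence":
            raise ValidationError("cumulative composition needs incidence matrices")
    plots = per_year[0].plots
    species = sorted(set().union(*(m.species for m in per_year)))
    acc = pd.DataFrame(0, index=plots, columns=species)
    for m in per_year:
        acc = acc | m.data.reindex(index=plots, columns=species).fillna(0).astype(int)
    years = sorted(m.scope.split(":", 1)[1] for m in per_year)
    scope = f"cumulative:{years[0]}-{years[-1]}" if len(years) > 1 else f"cumulative:{years[0]}"
    acc.index.name = "plot_id"
    return CommunityMatrix(acc.astype(int), kind="incidence", scope=scope)


def presence_by_year(
    table: pd.DataFrame,
    years: Sequence[int] | None = None,
    plots: Sequence | None = None,
    species: Sequence | None = None,
) -> dict[int, CommunityMatrix]:
    """Per-year incidence matrices with shared plot/species axes."""
    years = sorted(table["year"].unique()) if years is None else list(years)
    plots = list(plots) if plots is not None else sorted(table["plot_id"].unique())
    species = (
        list(species) if species is not None else sorted(table["species"].unique())
    )
    return {
        y: to_presence(max_abundance(table, y, plots=plots, species=species))
        for y in years
    }


def median_split(meta: pd.DataFrame, region) -> tuple[set, set]:
    """Split a region's plots at the median management intensity.

    Returns ``(high, low)`` plot-id sets: ``high`` holds plots with
    intensity strictly above the regional median; ties at the median go to
    ``low`` so the behaviour is deterministic.  Plots with missing
    intensity are dropped with a warning.
    """
    sel = meta[meta["region"] == region]
    if sel.empty:
        raise EmptySelectionError(f"no plots in region {region!r}")
    known = sel[sel["intensity"].notna()]
    if known.empty:
        raise ValidationError(f"all intensities missing in region {region!r}")
    if len(known) < len(sel):
        logger.warning(
            "region %s: %d plot(s) dropped from the intensity split "
            "(missing intensity)",
            region,
            len(sel) - len(known),
        )
    med = float(np.median(known["intensity"]))
    high = set(known.loc[known["intensity"] > med, "plot_id"])
    low = set(known["plot_id"]) - high
    return high, low
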