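"""End-to-end orchestration: surveys -> pair tables -> fits -> summaries.

`run_analysis` executes the full randomness analysis for every region:
per-year and cumulative compositions; all-plot, high/low management
intensity and turnover cut-off strata; both curve families; and the
summary tables (per-year nuggets with across-year mean/sd/min/max, 95%
CIs of the mean nugget, and a pseudo-R² matrix).  Failures of individual
cells (too few plots, non-convergence, out-of-range nuggets) degrade to
explicit "n/a" entries and a run-log record rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import community, occupancy, pairs, summary, turnover
from .exceptions import ConfigError, DissimogramError
from .model import Dissimogram

logger = logging.getLogger("dissimogram")

FIT_COLUMNS = (
    "region", "scope", "stratum", "family", "a", "b", "c", "nugget",
    "asymptote", "pseudo_r2", "converged", "valid", "n_pairs",
)


@dataclass
class RunConfig:
    """Options of a full analysis run."""

    families: Sequence[str] = ("gompertz", "negexp")
    cutoffs: Sequence[float] = (0.6, 0.7, 0.8)
    years: Sequence[int] | None = None
    n_rounds: int = 5
    excluded_species: Sequence[str] = ()
    intensity_split: bool = True
    persistence_threshold: int | None = None
    occupancy_model: str | None = None  # None, "single" or "multi"
    out_dir: str | None = None

    def __post_init__(self):
        if not self.families:
            raise ConfigError("at least one curve family is required")
        for c in self.cutoffs:
            if not 0.0 < c <= 1.0:
                raise ConfigError(f"turnover cutoff {c} outside (0, 1]")


def _na_row(region, scope, stratum, family, n_pairs=0):
    return {
        "region": region, "scope": scope, "stratum": stratum, "family": family,
        "a": np.nan, "b": np.nan, "c": np.nan, "nugget": np.nan,
        "asymptote": np.nan, "pseudo_r2": np.nan, "converged": False,
        "valid": False, "n_pairs": n_pairs,
    }


def _fit_cell(matrix, meta, region, scope, stratum, family, log):
    if len(matrix.plots) < 2:
        log.append(
            {"stage": "fit", "code": "too_few_plots", "region": region,
             "scope": scope, "stratum": stratum, "family": family,
             "detail": f"{len(matrix.plots)} plot(s)"}
        )
        return _na_row(region, scope, stratum, family)
    try:
        pt = pairs.build_pair_table(matrix, meta)
        if pt.attrs.get("n_excluded"):
            log.append(
                {"stage": "pairs", "code": "undefined_dissimilarity",
                 "region": region, "scope": scope, "stratum": stratum,
                 "family": family, "detail": f"{pt.attrs['n_excluded']} pair(s)"}
            )
        res = Dissimogram.from_pair_table(pt, family=family).fit()
    except DissimogramError as exc:
        log.append(
            {"stage": "fit", "code": "fit_error", "region": region,
             "scope": scope, "stratum": stratum, "family": family,
             "detail": str(exc)}
        )
        return _na_row(region, scope, stratum, family)
    row = {
        "region": region, "scope": scope, "stratum": stratum, "family": family,
        "a": res.params[0], "b": res.params[1], "c": res.params[2],
        "nugget": res._nugget if res.converged else np.nan,
        "asymptote": res.asymptote if res.converged else np.nan,
        "pseudo_r2": res.pseudo_r2, "converged": res.converged,
        "valid": res.valid, "n_pairs": res.n_pairs,
    }
    if not res.valid:
        code = "not_converged" if not res.converged else "nugget_out_of_range"
        log.append(
            {"stage": "fit", "code": code, "region": region, "scope": scope,
             "stratum": stratum, "family": family,
             "detail": f"nugget={res._nugget:.4f}"}
        )
    return row


def run_analysis(
    surveys: pd.DataFrame, meta: pd.DataFrame, config: RunConfig | None = None
) -> dict:
    """Full analysis over all regions; returns a result bundle.

    The bundle maps names to DataFrames: ``fits`` (one row per region x
    scope x stratum x family), ``turnover``, ``nugget_summary`` (mean, sd,
    min, max of yearly nuggets), ``nugget_ci`` (95% t intervals),
    ``pseudo_r2`` matrix, ``richness`` descriptives, optional
    ``detectability``, and ``log``.
    """
    config = config or RunConfig()
    surveys = community.validate_surveys(
        surveys, community.SurveySchema(n_rounds=config.n_rounds), plots=meta
    )
    surveys = community.exclude_species(surveys, config.excluded_species)
    years = (
        list(config.years)
        if config.years is not None
        else sorted(surveys["year"].unique())
    )
    log: list[dict] = []
    fit_rows: list[dict] = []
    turnover_frames = []
    matrices = []

    for region in sorted(meta["region"].unique()):
        region_meta = meta[meta["region"] == region]
        region_surveys = surveys[surveys["plot_id"].isin(region_meta["plot_id"])]
        if region_surveys.empty:
            log.append({"stage": "region", "code": "no_surveys",
                        "region": region, "scope": "", "stratum": "",
                        "family": "", "detail": "region skipped"})
            continue
        plots = sorted(region_meta["plot_id"].unique())
        per_year = community.presence_by_year(region_surveys, years, plots=plots)
        cumulative = community.cumulative_composition(list(per_year.values()))
        matrices.extend(
            [community.max_abundance(region_surveys, y, plots=plots) for y in years]
        )

        strata: dict[str, set] = {"all": set(plots)}
        if config.intensity_split:
            try:
                high, low = community.median_split(region_meta, region)
                strata["high_intensity"] = high
                strata["low_intensity"] = low
            except DissimogramError as exc:
                log.append({"stage": "strata", "code": "intensity_split_failed",
                            "region": region, "scope": "", "stratum": "",
                            "family": "", "detail": str(exc)})

        tt = turnover.turnover_table(per_year, config.persistence_threshold)
        tt.insert(0, "region", region)
        turnover_frames.append(tt)
        cutoff_strata: dict[str, set] = {}
        for c in config.cutoffs:
            cutoff_strata[f"cutoff_{int(round(c * 100))}"] = (
                turnover.filter_by_turnover(plots, tt, c)
            )

        scopes = {str(y): per_year[y] for y in years}
        scopes["cumulative"] = cumulative
        for scope, matrix in scopes.items():
            scope_strata = dict(strata)
            if scope == "cumulative":  # cut-off analyses use cumulative lists
                scope_strata.update(cutoff_strata)
            for stratum, keep in scope_strata.items():
                sub = matrix.subset_plots(keep)
                for family in config.families:
                    fit_rows.append(
                        _fit_cell(sub, region_meta, region, scope, stratum,
                                  family, log)
                    )

    fits = pd.DataFrame(fit_rows, columns=list(FIT_COLUMNS))
    bundle: dict = {
        "fits": fits,
        "turnover": (
            pd.concat(turnover_frames, ignore_index=True)
            if turnover_frames
            else pd.DataFrame()
        ),
        "nugget_summary": _nugget_summary(fits, years),
        "nugget_ci": _nugget_ci(fits, years),
        "pseudo_r2": _pseudo_r2_matrix(fits),
        "richness": summary.richness_abundance_summary(matrices, meta),
        "log": pd.DataFrame(
            log,
            columns=["stage", "code", "region", "scope", "stratum", "family",
                     "detail"],
        ),
    }
    if config.occupancy_model:
        bundle["detectability"] = occupancy.species_detectability(
            surveys,
            plots=sorted(meta["plot_id"].unique()),
            years=years,
            n_rounds=config.n_rounds,
            model=config.occupancy_model,
        )
    if config.out_dir:
        write_results(bundle, config.out_dir)
    return bundle


def _yearly_valid_nuggets(fits, years, region, stratum, family):
    sel = fits[
        (fits.region == region) & (fits.stratum == stratum)
        & (fits.family == family) & (fits.scope != "cumulative")
    ]
    out = {}
    for y in years:
        row = sel[sel.scope == str(y)]
        v = np.nan
        if len(row) == 1 and bool(row["valid"].iloc[0]):
            v = float(row["nugget"].iloc[0])
        out[y] = v
    return out


def _nugget_summary(fits: pd.DataFrame, years) -> pd.DataFrame:
    rows = []
    for (region, stratum, family), _ in fits.groupby(
        ["region", "stratum", "family"]
    ):
        yearly = _yearly_valid_nuggets(fits, years, region, stratum, family)
        cum = fits[
            (fits.region == region) & (fits.stratum == stratum)
            & (fits.family == family) & (fits.scope == "cumulative")
        ]
        cum_v = (
            float(cum["nugget"].iloc[0])
            if len(cum) == 1 and bool(cum["valid"].iloc[0])
            else np.nan
        )
        row = {"region": region, "stratum": stratum, "family": family,
               "cumulative": cum_v}
        row.update({f"y{y}": v for y, v in yearly.items()})
        vals = [v for v in yearly.values() if not np.isnan(v)]
        if vals:
            s = summary.across_year_stats(vals)
            row.update(mean=s["mean"], sd=s["sd"], min=s["min"], max=s["max"],
                       n=s["n"])
        else:
            row.update(mean=np.nan, sd=np.nan, min=np.nan, max=np.nan, n=0)
        rows.append(row)
    return pd.DataFrame(rows)


def _nugget_ci(fits: pd.DataFrame, years) -> pd.DataFrame:
    rows = []
    for region in sorted(fits["region"].unique()):
        for family in sorted(fits["family"].unique()):
            yearly = _yearly_valid_nuggets(fits, years, region, "all", family)
            vals = [v for v in yearly.values() if not np.isnan(v)]
            if len(vals) >= 2:
                ci = summary.ci95(vals)
                rows.append({"region": region, "family": family, **ci})
            else:
                rows.append({"region": region, "family": family,
                             "mean": np.nan, "halfwidth": np.nan,
                             "lower": np.nan, "upper": np.nan, "n": len(vals)})
    return pd.DataFrame(rows)


def _pseudo_r2_matrix(fits: pd.DataFrame) -> pd.DataFrame:
    mat = fits.pivot_table(
        index=["region", "scope", "family"], columns="stratum",
        values="pseudo_r2", aggfunc="first", dropna=False,
    ).reset_index()
    mat.columns.name = None
    return mat


def write_results(bundle: dict, out_dir) -> None:
    """Serialize a result bundle to CSV files (4-decimal fixed format)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in bundle.items():
        if isinstance(frame, pd.DataFrame):
            frame.to_csv(out / f"{name}.csv", index=False, float_format="%.4f",
                         na_rep="n/a")


def run_simulation(sim_config, run_config: RunConfig | None = None) -> dict:
    """Generate one synthetic metacommunity and analyse it end to end."""
    from .synthetic import simulate_metacommunity

    surveys, meta, truth = simulate_metacommunity(sim_config)
    bundle = run_analysis(surveys, meta, run_config)
    bundle["truth_rho"] = truth.rho
    return bundle
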