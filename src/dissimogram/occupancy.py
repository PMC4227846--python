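"""Occupancy-detection models for repeated point-count surveys.

Species are missed even when present; repeated surveys of the same plot
let occupancy (psi, the probability a plot is occupied) be separated from
per-occasion detection (p).  The single-season likelihood for one plot's
detection history with y detections in T occasions is

    psi * p^y * (1-p)^(T-y)                      if y >= 1
    psi * (1-p)^T + (1 - psi)                    if y == 0,

and the dynamic multi-season model lets the latent occupancy state evolve
between years via colonization (gamma) and extinction (epsilon):
P(occupied_{t+1}) = psi_t*(1-epsilon) + (1-psi_t)*gamma, evaluated by a
forward recursion over the two latent states.  Parameters are constant
across plots and occasions (no covariates); missing occasions contribute
no emission term.

Maximum-likelihood estimation is by quasi-Newton optimisation on
logit-transformed parameters from a multi-start grid.  In survey reports
the occupancy estimate psi-hat doubles as a per-species "detectability"
summary of how completely the community was sampled; both psi-hat and
p-hat are reported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .exceptions import EmptySelectionError, ValidationError

_P_FLOOR = 1e-300  # likelihood floor before taking logs (impossible events)


@dataclass
class DetectionHistories:
    """Detection histories for one species: plots x seasons x occasions.

    ``data`` holds 0 (surveyed, not detected), 1 (detected) or nan (occasion
    not surveyed).
    """

    data: np.ndarray  # (n_plots, n_seasons, n_occasions), float with nan
    plot_ids: list
    years: list
    species: str | None = None

    def __post_init__(self):
        vals = self.data[~np.isnan(self.data)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("detection histories must be 0/1/nan")

    @property
    def n_plots(self) -> int:
        return self.data.shape[0]

    @property
    def n_seasons(self) -> int:
        return self.data.shape[1]

    def single_season(self, season: int = 0) -> "DetectionHistories":
        """One season's histories, shaped (plots, 1, occasions)."""
        return DetectionHistories(
            self.data[:, season : season + 1, :],
            self.plot_ids,
            [self.years[season]],
            self.species,
        )


def build_histories(
    table: pd.DataFrame,
    species: str,
    plots: Sequence | None = None,
    years: Sequence[int] | None = None,
    n_rounds: int = 5,
    effort: pd.DataFrame | None = None,
) -> DetectionHistories:
    """Detection histories for one species from a long survey table.

    An occasion is 1 iff a record with count > 0 exists for that
    plot/year/round; otherwise 0.  ``effort``, if given, lists the
    (plot_id, year, round) combinations actually surveyed — occasions
    absent from it are marked missing (nan) and skipped in the likelihood.
    A species never recorded yields all-zero histories.
    """
    plots = list(plots) if plots is not None else sorted(table["plot_id"].unique())
    years = list(years) if years is not None else sorted(table["year"].unique())
    plot_ix = {p: i for i, p in enumerate(plots)}
    year_ix = {y: i for i, y in enumerate(years)}

    data = np.zeros((len(plots), len(years), n_rounds))
    if effort is not None:
        data[:] = np.nan
        for row in effort.itertuples(index=False):
            if row.plot_id in plot_ix and row.year in year_ix:
                data[plot_ix[row.plot_id], year_ix[row.year], row.round - 1] = 0.0

    sel = table[(table["species"] == species) & (table["count"] > 0)]
    for row in sel.itertuples(index=False):
        if row.plot_id in plot_ix and row.year in year_ix:
            cell = (plot_ix[row.plot_id], year_ix[row.year], row.round - 1)
            if effort is not None and np.isnan(data[cell]):
                continue  # detection outside declared effort: ignore
            data[cell] = 1.0
    return DetectionHistories(data, plots, years, species)


def _check_probs(**kwargs):
    for name, v in kwargs.items():
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name}={v} outside [0, 1]")


def _emission(data_2d: np.ndarray, p: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-plot season emission probabilities under the two latent states.

    Returns (e_occupied, e_unoccupied) for histories shaped (plots,
    occasions); nan occasions are skipped.
    """
    obs = ~np.isnan(data_2d)
    y = np.nansum(data_2d, axis=1)
    T = obs.sum(axis=1)
    with np.errstate(divide="ignore"):
        e1 = np.where(
            (p == 1.0) & (T - y > 0),
            0.0,
            np.where((p == 0.0) & (y > 0), 0.0, p**y * (1.0 - p) ** (T - y)),
        )
    e0 = np.where(y == 0, 1.0, 0.0)
    return e1, e0


def single_season_loglik(histories: DetectionHistories, psi: float, p: float) -> float:
    """Log-likelihood of the static occupancy-detection model.

    Sums over plots: log[psi*p^y*(1-p)^(T-y)] for histories with at least
    one detection, log[psi*(1-p)^T + (1-psi)] for all-zero histories.
    """
    _check_probs(psi=psi, p=p)
    if histories.n_seasons != 1:
        raise ValidationError("single-season likelihood needs exactly one season")
    e1, e0 = _emission(histories.data[:, 0, :], p)
    lik = psi * e1 + (1.0 - psi) * e0
    return float(np.sum(np.log(np.maximum(lik, _P_FLOOR))))


def multi_season_loglik(
    histories: DetectionHistories,
    psi1: float,
    gamma: float,
    epsilon: float,
    p: float,
) -> float:
    """Log-likelihood of the dynamic (multi-season) occupancy model.

    Forward recursion over the latent occupied/unoccupied state of each
    plot; reduces exactly to :func:`single_season_loglik` with one season.
    """
    _check_probs(psi1=psi1, gamma=gamma, epsilon=epsilon, p=p)
    n_plots, n_seasons, _ = histories.data.shape
    # alpha[:, z]: joint prob of data so far and latent state z
    alpha = np.tile([1.0 - psi1, psi1], (n_plots, 1))
    for t in range(n_seasons):
        e1, e0 = _emission(histories.data[:, t, :], p)
        alpha = alpha * np.column_stack([e0, e1])
        if t < n_seasons - 1:
            trans = np.array(
                [[1.0 - gamma, gamma], [epsilon, 1.0 - epsilon]]
            )
            alpha = alpha @ trans
    lik = alpha.sum(axis=1)
    return float(np.sum(np.log(np.maximum(lik, _P_FLOOR))))


def seasonal_occupancy(
    psi1: float, gamma: float, epsilon: float, n_seasons: int
) -> np.ndarray:
    """Unconditional occupancy probability for each season."""
    psis = [psi1]
    for _ in range(n_seasons - 1):
        psis.append(psis[-1] * (1.0 - epsilon) + (1.0 - psis[-1]) * gamma)
    return np.array(psis)


_DEFAULT_GRID = (0.2, 0.5, 0.8)


class OccupancyModel:
    """Occupancy-detection model for one species' histories.

    Parameters
    ----------
    histories : DetectionHistories
    model : {"single", "multi"}
        Static single-season or dynamic multi-season likelihood.  "single"
        with multi-season histories uses the first season.
    """

    def __init__(self, histories: DetectionHistories, model: str = "single"):
        if model not in ("single", "multi"):
            raise ValueError(f"unknown occupancy model {model!r}")
        if histories.n_plots < 1:
            raise EmptySelectionError("no detection histories")
        if model == "single" and histories.n_seasons > 1:
            histories = histories.single_season(0)
        self.histories = histories
        self.model = model
        self.param_names = (
            ["psi", "p"] if model == "single" else ["psi", "gamma", "epsilon", "p"]
        )

    def loglik(self, params: Sequence[float]) -> float:
        if self.model == "single":
            return single_season_loglik(self.histories, *params)
        psi1, gamma, epsilon, p = params
        return multi_season_loglik(self.histories, psi1, gamma, epsilon, p)

    def _neg_loglik_logit(self, z: np.ndarray) -> float:
        return -self.loglik(expit(z))

    def fit(
        self,
        starts: Iterable[Sequence[float]] | None = None,
        tol: float = 1e-8,
    ) -> "OccupancyResults":
        """Maximum likelihood on the logit scale with multi-start.

        Default starts are the grid {0.2, 0.5, 0.8} over (psi, p); the
        dynamic model adds gamma = epsilon in {0.2, 0.5, 0.8}.  Degenerate
        data (e.g. no detections anywhere) give a boundary estimate flagged
        via ``at_boundary``, not an exception.
        """
        if starts is None:
            if self.model == "single":
                starts = list(product(_DEFAULT_GRID, _DEFAULT_GRID))
            else:
                starts = [
                    (psi, g, g, p)
                    for psi, g, p in product(
                        _DEFAULT_GRID, _DEFAULT_GRID, _DEFAULT_GRID
                    )
                ]
        best = None
        for start in starts:
            res = minimize(
                self._neg_loglik_logit,
                logit(np.asarray(start, float)),
                method="L-BFGS-B",
                tol=tol,
            )
            if best is None or res.fun < best.fun:
                best = res
        params = expit(best.x)
        return OccupancyResults(
            self, params, loglik=-float(best.fun), converged=bool(best.success)
        )


class OccupancyResults:
    """MLE of occupancy/detection parameters with diagnostics."""

    def __init__(self, model, params, loglik, converged):
        self.model = model
        self.params = dict(zip(model.param_names, (float(v) for v in params)))
        self.loglik = float(loglik)
        self.converged = bool(converged)

    @property
    def psi(self) -> float:
        return self.params["psi"]

    @property
    def p(self) -> float:
        return self.params["p"]

    @property
    def gamma(self) -> float | None:
        return self.params.get("gamma")

    @property
    def epsilon(self) -> float | None:
        return self.params.get("epsilon")

    @property
    def mean_psi(self) -> float:
        """Occupancy averaged over seasons (equals psi for one season)."""
        if self.model.model == "single":
            return self.psi
        return float(
            seasonal_occupancy(
                self.psi, self.gamma, self.epsilon, self.model.histories.n_seasons
            ).mean()
        )

    @property
    def at_boundary(self) -> bool:
        """True when any estimate sits at the edge of [0, 1]."""
        eps = 1e-4
        return any(v < eps or v > 1 - eps for v in self.params.values())

    def summary(self) -> str:
        lines = [
            f"Occupancy fit ({self.model.model}-season)",
            "=" * 40,
            f"n plots:   {self.model.histories.n_plots}",
            f"n seasons: {self.model.histories.n_seasons}",
        ]
        for name, v in self.params.items():
            lines.append(f"{name:<8}  {v: .4f}")
        lines.append(f"log-lik   {self.loglik: .4f}")
        lines.append(f"converged {self.converged}   boundary {self.at_boundary}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        pars = ", ".join(f"{k}={v:.3f}" for k, v in self.params.items())
        return f"<OccupancyResults {self.model.model} {pars} ll={self.loglik:.2f}>"


def fit_occupancy(histories: DetectionHistories, model: str = "single") -> OccupancyResults:
    """Convenience wrapper: build and fit an :class:`OccupancyModel`."""
    return OccupancyModel(histories, model=model).fit()


def species_detectability(
    table: pd.DataFrame,
    species: Sequence[str] | None = None,
    plots: Sequence | None = None,
    years: Sequence[int] | None = None,
    n_rounds: int = 5,
    model: str = "single",
) -> pd.DataFrame:
    """Per-species occupancy fits over the whole survey table."""
    if species is None:
        species = sorted(table.loc[table["count"] > 0, "species"].unique())
    rows = []
    for sp in species:
        hist = build_histories(table, sp, plots=plots, years=years, n_rounds=n_rounds)
        res = fit_occupancy(hist, model=model)
        rows.append(
            {
                "species": sp,
                "model": model,
                "psi": res.psi,
                "p": res.p,
                "gamma": res.gamma,
                "epsilon": res.epsilon,
                "loglik": res.loglik,
                "converged": res.converged,
                "at_boundary": res.at_boundary,
            }
        )
    return pd.DataFrame(rows)


def summarize_detectability(fits: pd.DataFrame) -> dict:
    """Mean and quantiles of per-species occupancy over converged fits."""
    conv = fits[fits["converged"]]
    if conv.empty:
        raise EmptySelectionError("no converged occupancy fits to summarize")
    psi = conv["psi"].to_numpy(float)
    qs = np.quantile(psi, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "mean_psi": float(psi.mean()),
        "n_species": int(len(psi)),
        "quantiles": {
            "min": qs[0],
            "q25": qs[1],
            "median": qs[2],
            "q75": qs[3],
            "max": qs[4],
        },
    }
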