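"""Non-linear distance-decay models for community dissimilarity.

The *dissimogram* is the spatial-autocorrelation analogue of a variogram
for composition: pairwise Jaccard dissimilarity plotted against pairwise
geographic distance.  Two three-parameter curve families are supported:

* **Gompertz**:  D'(d) = a * exp(-b * exp(-c * d))
* **Negative exponential**:  D'(d) = a - b * exp(-c * d)

For both, the *asymptote* is ``a`` (the fitted maximum dissimilarity as
d -> inf) and the *nugget* is the y-intercept D'(0) — ``a*exp(-b)`` for
Gompertz, ``a - b`` for the negative exponential.  The nugget is the
compositional dissimilarity remaining at zero geographic distance and is
interpreted as the fraction of community composition driven by random
(spatially unpredictable) processes: larger nuggets mean a larger role for
chance.  Nuggets outside [0, 1] indicate a poorly fitting model and are
flagged invalid rather than reported.

Parameters are estimated by Gauss-Newton least squares with Levenberg-style
damping when a step fails to reduce the residual, from multiple starting
points.  Distances are rescaled to kilometres internally for conditioning
(a decay rate of ~1e-4 per metre is poorly scaled); the decay rate ``c``
is reported back in per-metre units.

Examples
--------
>>> model = Dissimogram(distance_m, dissimilarity, family="gompertz")
>>> res = model.fit()
>>> res.nugget, res.asymptote, res.pseudo_r2
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FitError

logger = logging.getLogger("dissimogram")

FAMILIES = ("gompertz", "negexp")

_EXP_CLIP = 700.0  # exp argument bound to avoid overflow during line search


def _safe_exp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def gompertz_eval(d, a, b, c):
    """Gompertz dissimogram value a*exp(-b*exp(-c*d)).

    Monotone non-decreasing in ``d`` for positive parameters; equals
    ``a*exp(-b)`` at d=0 and tends to ``a`` as d -> inf.
    """
    return a * _safe_exp(-b * _safe_exp(-np.asarray(c) * np.asarray(d)))


def negexp_eval(d, a, b, c):
    """Negative-exponential dissimogram value a - b*exp(-c*d)."""
    return a - b * _safe_exp(-np.asarray(c) * np.asarray(d))


def _gompertz_jac(d, a, b, c):
    e_cd = _safe_exp(-c * d)
    inner = _safe_exp(-b * e_cd)
    return np.column_stack([inner, -a * e_cd * inner, a * b * d * e_cd * inner])


def _negexp_jac(d, a, b, c):
    e_cd = _safe_exp(-c * d)
    return np.column_stack([np.ones_like(d), -e_cd, b * d * e_cd])


class _Family:
    def __init__(self, name, fun, jac, nugget, starts):
        self.name = name
        self.fun = fun
        self.jac = jac
        self.nugget = nugget
        self.starts = starts


def _gompertz_starts(d_km, y):
    a0 = float(np.percentile(y, 95))
    a0 = max(a0, 1e-3)
    c0s = [1.0 / np.median(d_km), 1.0 / np.max(d_km), 10.0 / np.max(d_km)]
    return [(a0, b0, c0) for b0 in (0.1, 0.5, 1.0, 2.0) for c0 in c0s]


def _negexp_starts(d_km, y):
    a0 = float(np.percentile(y, 95))
    a0 = max(a0, 1e-3)
    b0 = max(a0 - float(np.min(y)), 1e-3)
    c0s = [1.0 / np.median(d_km), 1.0 / np.max(d_km), 10.0 / np.max(d_km)]
    return [(a0, b0, c0) for c0 in c0s]


_FAMILY_TABLE = {
    "gompertz": _Family(
        "gompertz",
        gompertz_eval,
        _gompertz_jac,
        lambda a, b: a * np.exp(-np.clip(b, -_EXP_CLIP, _EXP_CLIP)),
        _gompertz_starts,
    ),
    "negexp": _Family(
        "negexp", negexp_eval, _negexp_jac, lambda a, b: a - b, _negexp_starts
    ),
}


def nugget_of(family: str, a: float, b: float) -> float:
    """Model value at d=0: Gompertz ``a*exp(-b)``; negexp ``a - b``."""
    if family not in _FAMILY_TABLE:
        raise ValueError(f"unknown family {family!r}")
    return float(_FAMILY_TABLE[family].nugget(a, b))


def pseudo_r_squared(fitted, observed) -> float:
    """Squared Pearson correlation of fitted against observed values.

    A goodness-of-fit proxy for non-linear models; undefined (nan) when the
    fitted values are constant.
    """
    fitted = np.asarray(fitted, float)
    observed = np.asarray(observed, float)
    if np.std(fitted) == 0 or np.std(observed) == 0:
        return float("nan")
    return float(np.corrcoef(fitted, observed)[0, 1] ** 2)


def _gauss_newton(fun, jac, theta0, d, y, max_iter=200, tol=1e-10):
    """Damped Gauss-Newton on residuals y - fun(d, *theta).

    Pure Gauss-Newton steps; when a step fails to reduce the residual sum
    of squares, Levenberg damping (lambda * diag(J'J)) is increased until
    it does or the damping saturates.  Convergence when the relative RSS
    reduction or the parameter step falls below ``tol``.
    """
    theta = np.asarray(theta0, float)
    r = y - fun(d, *theta)
    rss = float(r @ r)
    lam = 0.0
    for it in range(1, max_iter + 1):
        J = jac(d, *theta)
        if not np.isfinite(J).all():
            return theta, rss, False, it
        JtJ = J.T @ J
        Jtr = J.T @ r
        diag = np.diag(np.maximum(np.diag(JtJ), 1e-12))
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(JtJ + lam * diag, Jtr)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-8)
                continue
            trial = theta + step
            with np.errstate(over="ignore", invalid="ignore"):
                r_trial = y - fun(d, *trial)
                rss_trial = float(r_trial @ r_trial)
            if np.isfinite(rss_trial) and rss_trial <= rss:
                accepted = True
                break
            lam = max(lam * 10.0, 1e-8)
        if not accepted:
            # damping saturated without improvement: local minimum
            return theta, rss, True, it
        rel_drop = (rss - rss_trial) / max(rss, 1e-300)
        step_size = float(np.max(np.abs(step))) / (1.0 + float(np.max(np.abs(theta))))
        theta, r, rss = trial, r_trial, rss_trial
        lam /= 10.0
        if lam < 1e-12:
            lam = 0.0
        if rel_drop < tol or step_size < tol:
            return theta, rss, True, it
    return theta, rss, False, max_iter


class Dissimogram:
    """Distance-decay model of community dissimilarity.

    Parameters
    ----------
    distance : array-like
        Pairwise plot distances in metres.
    dissimilarity : array-like
        Pairwise Jaccard dissimilarities in [0, 1].
    family : {"gompertz", "negexp"}

    See Also
    --------
    Dissimogram.from_pair_table : construct from a pair table DataFrame.
    """

    def __init__(self, distance, dissimilarity, family: str = "gompertz"):
        if family not in _FAMILY_TABLE:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        d = np.asarray(distance, float)
        y = np.asarray(dissimilarity, float)
        keep = np.isfinite(d) & np.isfinite(y)
        self.n_dropped = int(len(d) - keep.sum())
        if self.n_dropped:
            logger.warning("%d pair(s) with non-finite values dropped", self.n_dropped)
        self.distance = d[keep]
        self.dissimilarity = y[keep]
        self.family = family

    @classmethod
    def from_pair_table(cls, pairs: pd.DataFrame, family: str = "gompertz"):
        """Build from a pair table with columns distance_m, dissimilarity."""
        return cls(pairs["distance_m"], pairs["dissimilarity"], family=family)

    def predict(self, params: Sequence[float], distance=None):
        """Evaluate the family curve at the given distances (metres)."""
        d = self.distance if distance is None else np.asarray(distance, float)
        return _FAMILY_TABLE[self.family].fun(d, *params)

    def fit(self, max_iter: int = 200, tol: float = 1e-10) -> "DissimogramResults":
        """Gauss-Newton least-squares fit with multi-start initialisation.

        Starting values: ``a0`` = 95th percentile of observed dissimilarity;
        shape starts b0 in {0.1, 0.5, 1, 2} (Gompertz) or a0 - min(y)
        (negative exponential); decay starts c0 in {1/median(d), 1/max(d),
        10/max(d)}.  The best converged start wins (lowest residual, then
        fewest iterations).  No box constraints are applied during
        optimisation; out-of-range nuggets are flagged by the validity rule
        afterwards.
        """
        d_m, y = self.distance, self.dissimilarity
        if len(d_m) < 3 or np.unique(d_m).size < 3:
            raise FitError(
                "need at least 3 pairs with distinct distances "
                f"(got {len(d_m)} pairs, {np.unique(d_m).size} distinct)"
            )
        fam = _FAMILY_TABLE[self.family]
        d_km = d_m / 1000.0

        if np.ptp(y) == 0.0:
            # flat dissimilarity: a = const, b = 0; c is unidentifiable
            logger.warning("constant dissimilarity: degenerate flat-curve fit")
            a = float(y[0])
            c_km = 1.0 / float(np.median(d_km))
            return DissimogramResults(
                self, (a, 0.0, c_km / 1000.0), rss=0.0, converged=True,
                iterations=0, degenerate=True,
            )

        best = None
        for theta0 in fam.starts(d_km, y):
            theta, rss, conv, iters = _gauss_newton(
                fam.fun, fam.jac, theta0, d_km, y, max_iter=max_iter, tol=tol
            )
            cand = (not conv, rss, iters, tuple(theta))
            if best is None or cand < best[0]:
                best = (cand, theta, rss, conv, iters)
        _, theta, rss, conv, iters = best
        a, b, c_km = (float(v) for v in theta)
        return DissimogramResults(
            self, (a, b, c_km / 1000.0), rss=rss, converged=conv, iterations=iters
        )


class DissimogramResults:
    """Fit results: parameters, nugget, asymptote, pseudo-R², flags.

    Attributes
    ----------
    params : (a, b, c)
        ``a`` asymptotic dissimilarity, ``b`` shape, ``c`` decay rate per
        metre.
    nugget : float
        Model value at d=0 (raises FitError on a non-converged fit).
    asymptote : float
        Fitted maximum dissimilarity (= a).
    pseudo_r2 : float
        Squared Pearson correlation of fitted vs observed; nan when the
        fitted values are constant.
    converged, valid, degenerate : bool
        ``valid`` means converged with nugget in [0, 1]; invalid fits are
        carried through reporting as "n/a".
    """

    def __init__(self, model, params, rss, converged, iterations, degenerate=False):
        self.model = model
        self.family = model.family
        self.params = tuple(float(p) for p in params)
        self.rss = float(rss)
        self.converged = bool(converged)
        self.iterations = int(iterations)
        self.degenerate = bool(degenerate)
        self.n_pairs = len(model.distance)
        a, b, _ = self.params
        self._nugget = nugget_of(self.family, a, b)
        self.fittedvalues = model.predict(self.params)
        self.resid = model.dissimilarity - self.fittedvalues
        self.pseudo_r2 = (
            pseudo_r_squared(self.fittedvalues, model.dissimilarity)
            if self.converged
            else float("nan")
        )

    @property
    def nugget(self) -> float:
        if not self.converged:
            raise FitError("nugget undefined: fit did not converge")
        return self._nugget

    @property
    def asymptote(self) -> float:
        return self.params[0]

    @property
    def valid(self) -> bool:
        """Converged with a nugget inside [0, 1].

        Nuggets outside [0, 1] indicate a poorly fitting model and are
        excluded from downstream summaries.
        """
        return self.converged and 0.0 <= self._nugget <= 1.0

    def predict(self, distance):
        return self.model.predict(self.params, distance)

    def summary(self) -> str:
        a, b, c = self.params
        lines = [
            "Dissimogram fit",
            "=" * 46,
            f"family:        {self.family}",
            f"n pairs:       {self.n_pairs}",
            f"a (asymptote): {a: .6f}",
            f"b (shape):     {b: .6f}",
            f"c (per m):     {c: .3e}",
            f"nugget:        {self._nugget: .4f}",
            f"pseudo R2:     {self.pseudo_r2: .4f}",
            f"RSS:           {self.rss: .6f}",
            f"converged:     {self.converged}   valid: {self.valid}"
            + ("   (degenerate flat curve)" if self.degenerate else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_curve: int = 200):
        """Scatter of pairs with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.distance
        ax.plot(d, self.model.dissimilarity, ".", ms=3, alpha=0.4, color="k")
        grid = np.linspace(0, d.max(), n_curve)
        ax.plot(grid, self.predict(grid), "-", color="grey", lw=2)
        ax.set_xlabel("distance (m)")
        ax.set_ylabel("Jaccard dissimilarity (1 - D')")
        ax.set_ylim(-0.02, 1.02)
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        a, b, c = self.params
        return (
            f"<DissimogramResults {self.family} a={a:.4f} b={b:.4f} "
            f"c={c:.3e} nugget={self._nugget:.4f} valid={self.valid}>"
        )


def fit_dissimogram(pairs: pd.DataFrame, family: str = "gompertz") -> DissimogramResults:
    """Convenience wrapper: fit a family to a pair table."""
    return Dissimogram.from_pair_table(pairs, family=family).fit()
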