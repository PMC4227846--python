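"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written the slow, obvious way and never shares
code with the implementation it checks.
"""

from itertools import product

import numpy as np


def jaccard_by_enumeration(a, b, universe):
    """Jaccard dissimilarity by walking every element of the universe."""
    shared = 0
    either = 0
    for x in universe:
        ina, inb = x in a, x in b
        if ina and inb:
            shared += 1
        if ina or inb:
            either += 1
    if either == 0:
        return float("nan")
    return 1.0 - shared / either


def gompertz_grid_rss(d_km, y, a_grid, b_grid, c_grid):
    """Lowest residual sum of squares over a dense (a, b, c) grid."""
    best = np.inf
    for c in c_grid:
        decay = np.exp(-c * d_km)
        inner = np.exp(-np.outer(b_grid, decay))  # (nb, n)
        model = a_grid[:, None, None] * inner[None, :, :]
        rss = ((model - y) ** 2).sum(axis=2)
        best = min(best, float(rss.min()))
    return best


def occupancy_likelihood_by_paths(history, psi1, gamma, epsilon, p):
    """One plot's dynamic-occupancy likelihood by enumerating all latent
    occupancy paths (2^n_seasons terms).

    ``history`` is a (n_seasons, n_occasions) 0/1/nan array.
    """
    history = np.asarray(history, float)
    n_seasons = history.shape[0]
    total = 0.0
    for path in product((0, 1), repeat=n_seasons):
        prob = psi1 if path[0] == 1 else 1.0 - psi1
        for t in range(1, n_seasons):
            prev, cur = path[t - 1], path[t]
            if prev == 1:
                prob *= (1.0 - epsilon) if cur == 1 else epsilon
            else:
                prob *= gamma if cur == 1 else 1.0 - gamma
        for t in range(n_seasons):
            for occ in history[t]:
                if np.isnan(occ):
                    continue
                if path[t] == 1:
                    prob *= p if occ == 1 else 1.0 - p
                else:
                    prob *= 1.0 if occ == 0 else 0.0
        total += prob
    return total


def single_season_grid_mle(histories_2d, n_grid=200):
    """MLE of (psi, p) by brute grid search on the static model."""
    grid = np.linspace(1e-4, 1 - 1e-4, n_grid)
    y = np.nansum(histories_2d, axis=1)
    T = (~np.isnan(histories_2d)).sum(axis=1)
    best = (-np.inf, None, None)
    for psi in grid:
        for p in grid:
            lik = np.where(
                y > 0,
                psi * p**y * (1 - p) ** (T - y),
                psi * (1 - p) ** T + (1 - psi),
            )
            ll = float(np.sum(np.log(np.maximum(lik, 1e-300))))
            if ll > best[0]:
                best = (ll, psi, p)
    return best
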