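"""Pairwise Jaccard dissimilarity and geographic distance.

The regression data for a dissimogram are all unordered pairs of plots
within a region, each with the Euclidean distance between plot centroids
(projected coordinates, metres) and the incidence-based Jaccard
dissimilarity 1 - |A∩B|/|A∪B| between the two plots' species sets.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .exceptions import FitError, ValidationError

logger = logging.getLogger("dissimogram")

#: columns of a serialized pair table
PAIR_COLUMNS = ("plot_i", "plot_j", "distance_m", "dissimilarity")


def jaccard_dissimilarity(a, b) -> float:
    """Incidence-based Jaccard dissimilarity 1 - |A∩B| / |A∪B|.

    Returns ``nan`` when both sets are empty (the quantity is undefined;
    such pairs are excluded downstream rather than coerced to 0 or 1).
    """
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return float("nan")
    return 1.0 - len(a & b) / union


def euclidean_distance(p, q) -> float:
    """Centroid-to-centroid Euclidean distance in metres.

    ``p`` and ``q`` are mappings (e.g. plot-metadata rows) with finite
    projected coordinates ``x`` and ``y``.
    """
    for plot in (p, q):
        if not (np.isfinite(plot["x"]) and np.isfinite(plot["y"])):
            raise ValidationError(
                f"plot {plot.get('plot_id', '?')!r} has missing coordinates"
            )
    return float(np.hypot(p["x"] - q["x"], p["y"] - q["y"]))


def build_pair_table(matrix: CommunityMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """All unordered plot pairs with distance and Jaccard dissimilarity.

    For ``n`` plots the result has ``n(n-1)/2`` rows minus any pairs whose
    dissimilarity is undefined (both communities empty); exclusions are
    logged.  Every plot in the matrix must have coordinates in ``meta``.
    """
    if matrix.kind != "incidence":
        raise ValidationError("pair table requires an incidence matrix")
    plots = matrix.plots
    if len(plots) < 2:
        raise FitError(f"need at least 2 plots, got {len(plots)}")
    coords = meta.set_index("plot_id")[["x", "y"]]
    missing = [p for p in plots if p not in coords.index]
    if missing:
        raise ValidationError(f"plots without coordinates: {missing[:10]}")
    xy = coords.loc[plots].to_numpy(float)
    if not np.isfinite(xy).all():
        bad = [plots[i] for i in np.where(~np.isfinite(xy).all(axis=1))[0]]
        raise ValidationError(f"plots with non-finite coordinates: {bad[:10]}")

    inc = matrix.values.astype(bool)
    rows = []
    n_undefined = 0
    for i, j in combinations(range(len(plots)), 2):
        union = np.count_nonzero(inc[i] | inc[j])
        if union == 0:
            n_undefined += 1
            continue
        shared = np.count_nonzero(inc[i] & inc[j])
        dist = float(np.hypot(*(xy[i] - xy[j])))
        rows.append((plots[i], plots[j], dist, 1.0 - shared / union))
    if n_undefined:
        logger.warning(
            "%d pair(s) excluded: dissimilarity undefined (both communities empty)",
            n_undefined,
        )
    table = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    table.attrs["n_excluded"] = n_undefined
    return table
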