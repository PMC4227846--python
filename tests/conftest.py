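import numpy as np
import pandas as pd
import pytest

from dissimogram.community import CommunityMatrix


@pytest.fixture
def small_surveys() -> pd.DataFrame:
    """Hand-built long-format survey table: 3 plots, 2 years, 3 rounds."""
    rows = []
    counts = {
        # (plot, year, round, species): count
        ("P1", 1, 1, "s1"): 1, ("P1", 1, 2, "s1"): 3, ("P1", 1, 3, "s1"): 2,
        ("P1", 1, 1, "s2"): 2,
        ("P2", 1, 2, "s2"): 1, ("P2", 1, 3, "s3"): 4,
        ("P3", 1, 1, "s3"): 1,
        ("P1", 2, 1, "s1"): 1,
        ("P2", 2, 2, "s3"): 2, ("P3", 2, 3, "s2"): 1,
    }
    for (plot, year, rnd, sp), count in counts.items():
        rows.append(
            {"plot_id": plot, "region": "A", "year": year, "round": rnd,
             "species": sp, "count": count}
        )
    return pd.DataFrame(rows)


@pytest.fixture
def small_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": ["P1", "P2", "P3"],
            "region": ["A", "A", "A"],
            "x": [0.0, 3000.0, 0.0],
            "y": [0.0, 4000.0, 1000.0],
            "intensity": [1.0, 2.0, 3.0],
        }
    )


def incidence(values, plots=None, species=None, scope="year:1") -> CommunityMatrix:
    """Helper: build an incidence CommunityMatrix from a nested list."""
    values = np.asarray(values)
    plots = plots or [f"P{i+1}" for i in range(values.shape[0])]
    species = species or [f"s{j+1}" for j in range(values.shape[1])]
    return CommunityMatrix(
        pd.DataFrame(values, index=plots, columns=species), "incidence", scope
    )
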