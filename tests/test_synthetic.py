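import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dissimogram import (
    SimConfig,
    gaussian_random_field,
    presence_by_year,
    sample_plot_coordinates,
    simulate_metacommunity,
)
from dissimogram.community import validate_surveys
from dissimogram.exceptions import ConfigError


SMALL = dict(n_regions=1, n_plots=15, n_species=20, n_years=2, n_rounds=3)


class TestSimConfig:
    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, rho=1.5)

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(seed=1, extent=100.0, min_spacing=200.0)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimConfig(seed=5, rho=0.3, n_plots=10)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg


class TestCoordinates:
    def test_geometric_bounds(self):
        rng = np.random.default_rng(0)
        pts = sample_plot_coordinates(50, 45_000.0, 250.0, rng)
        d = np.hypot(
            pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1]
        )
        iu = np.triu_indices(50, 1)
        assert d[iu].min() >= 250.0
        assert d[iu].max() <= 45_000.0 * np.sqrt(2)
        assert (pts >= 0).all() and (pts <= 45_000.0).all()

    def test_deterministic_given_seed(self):
        a = sample_plot_coordinates(20, 10_000.0, 100.0, np.random.default_rng(3))
        b = sample_plot_coordinates(20, 10_000.0, 100.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_single_plot(self):
        pts = sample_plot_coordinates(1, 1000.0, 10.0, np.random.default_rng(1))
        assert pts.shape == (1, 2)

    def test_infeasible_packing_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ConfigError):
            sample_plot_coordinates(200, 1000.0, 900.0, rng, max_tries=500)


class TestGaussianRandomField:
    def test_coincident_plots_identical(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [5000.0, 0.0]])
        f = gaussian_random_field(coords, 1000.0, np.random.default_rng(4))
        assert f[0] == pytest.approx(f[1], abs=1e-5)

    def test_short_range_decorrelates(self):
        coords = np.array([[0.0, 0.0], [5000.0, 0.0]])
        vals = np.array(
            [
                gaussian_random_field(coords, 1.0, np.random.default_rng(s))
                for s in range(500)
            ]
        )
        r = np.corrcoef(vals[:, 0], vals[:, 1])[0, 1]
        assert abs(r) < 0.12

    def test_empirical_covariance_matches_exponential_model(self):
        rng = np.random.default_rng(6)
        coords = np.array([[0.0, 0.0], [2000.0, 0.0], [8000.0, 0.0]])
        range_m = 4000.0
        draws = np.array(
            [gaussian_random_field(coords, range_m, rng) for _ in range(2000)]
        )
        emp = np.cov(draws.T)
        d = np.array([[0, 2000, 8000], [2000, 0, 6000], [8000, 6000, 0]], float)
        want = np.exp(-d / range_m)
        assert np.abs(emp - want).max() < 0.08

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ConfigError):
            gaussian_random_field(np.array([[np.nan, 0.0]]), 100.0,
                                  np.random.default_rng(0))


class TestSimulateMetacommunity:
    def test_full_determinism(self):
        cfg = SimConfig(seed=11, **SMALL)
        s1, m1, _ = simulate_metacommunity(cfg)
        s2, m2, _ = simulate_metacommunity(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(m1, m2)
        b1, b2 = io.StringIO(), io.StringIO()
        s1.to_csv(b1, index=False)
        s2.to_csv(b2, index=False)
        assert b1.getvalue() == b2.getvalue()

    def test_perfect_detection_matches_latent_presence(self):
        cfg = SimConfig(seed=12, detection_p=1.0, **SMALL)
        surveys, meta, truth = simulate_metacommunity(cfg)
        per_year = presence_by_year(
            surveys,
            years=[1, 2],
            plots=list(meta["plot_id"]),
            species=[f"sp{s + 1:03d}" for s in range(cfg.n_species)],
        )
        latent = truth.latent_presence["R1"]
        for t, year in enumerate([1, 2]):
            np.testing.assert_array_equal(per_year[year].values, latent[t])

    def test_emitted_table_roundtrips_through_reader(self, tmp_path):
        cfg = SimConfig(seed=13, **SMALL)
        surveys, meta, _ = simulate_metacommunity(cfg)
        path = tmp_path / "surveys.csv"
        surveys.to_csv(path, index=False)
        from dissimogram import read_surveys, SurveySchema

        got = read_surveys(path, schema=SurveySchema(n_rounds=3), plots=meta)
        pd.testing.assert_frame_equal(
            got.sort_values(list(got.columns)).reset_index(drop=True),
            surveys.sort_values(list(got.columns)).reset_index(drop=True),
        )

    def test_occupancy_probability_in_unit_interval(self):
        for rho in (0.0, 0.37, 1.0):
            cfg = SimConfig(seed=14, rho=rho, **SMALL)
            _, _, truth = simulate_metacommunity(cfg)
            q = truth.occupancy_prob["R1"].to_numpy()
            assert (q >= 0).all() and (q <= 1).all()

    def test_rho_one_occupancy_independent_of_space(self):
        """At rho = 1 occupancy probability is constant across plots."""
        cfg = SimConfig(seed=15, rho=1.0, **SMALL)
        _, _, truth = simulate_metacommunity(cfg)
        q = truth.occupancy_prob["R1"].to_numpy()
        assert np.ptp(q, axis=0).max() < 1e-12

    def test_rho_zero_distance_decay_in_truth(self):
        """At rho = 0 with strong autocorrelation, mean dissimilarity rises
        across distance bins within the correlation length scale and
        saturates beyond it (seed-averaged; the environmental covariance
        exp(-d/range) is negligible past a few correlation lengths)."""
        from dissimogram import build_pair_table

        edges = [0, 5_000, 10_000, 20_000, 35_000, 70_000]
        per_seed = []
        for seed in range(100, 120):
            cfg = SimConfig(
                seed=seed, rho=0.0, detection_p=1.0, n_regions=1, n_plots=40,
                n_species=60, n_years=1, n_rounds=1, autocorr_range=9000.0,
            )
            surveys, meta, _ = simulate_metacommunity(cfg)
            per_year = presence_by_year(surveys, plots=list(meta["plot_id"]))
            pt = build_pair_table(per_year[1], meta)
            bins = pd.cut(pt["distance_m"], edges)
            per_seed.append(
                pt.groupby(bins, observed=False)["dissimilarity"]
                .mean().to_numpy()
            )
        means = np.nanmean(per_seed, axis=0)
        # strict decay over the first four bins (d <~ 4 correlation lengths)
        assert (np.diff(means[:4]) > 0).all()
        # saturation: the two outermost bins agree within noise
        assert abs(means[4] - means[3]) < 0.02
        assert means[4] > means[0] + 0.1

    def test_rho_one_no_spatial_signal(self):
        """At rho = 1 the distance-dissimilarity correlation is null: a
        permutation test rejects at roughly its nominal 5% level."""
        from dissimogram import build_pair_table

        rng = np.random.default_rng(99)
        n_signif = 0
        n_seeds = 60
        for seed in range(200, 200 + n_seeds):
            cfg = SimConfig(seed=seed, rho=1.0, detection_p=1.0, n_regions=1,
                            n_plots=15, n_species=20, n_years=1, n_rounds=1)
            surveys, meta, _ = simulate_metacommunity(cfg)
            per_year = presence_by_year(surveys, plots=list(meta["plot_id"]))
            pt = build_pair_table(per_year[1], meta)
            d = pt["distance_m"].to_numpy()
            y = pt["dissimilarity"].to_numpy()
            obs = abs(np.corrcoef(d, y)[0, 1])
            perm = sum(
                abs(np.corrcoef(d, rng.permutation(y))[0, 1]) >= obs
                for _ in range(199)
            )
            if (perm + 1) / 200 < 0.05:
                n_signif += 1
        # Binomial(60, 0.05): more than 9 rejections has probability < 1e-4
        assert n_signif <= 9

    def test_persistence_reduces_turnover(self):
        base = dict(SMALL, n_years=5)
        lo = SimConfig(seed=17, persistence=0.0, **base)
        hi = SimConfig(seed=17, persistence=0.95, **base)
        from dissimogram import turnover_table

        def mean_turnover(cfg):
            surveys, meta, _ = simulate_metacommunity(cfg)
            per_year = presence_by_year(surveys, plots=list(meta["plot_id"]))
            return turnover_table(per_year)["turnover"].mean()

        assert mean_turnover(hi) < mean_turnover(lo)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    rho=st.floats(0.0, 1.0),
    f=st.floats(0.0, 1.0),
    pi=st.floats(0.0, 1.0),
)
def test_mixture_stays_in_unit_interval(rho, f, pi):
    """The occupancy mixture (1-rho)*f + rho*pi is convex."""
    q = (1 - rho) * f + rho * pi
    assert 0.0 <= q <= 1.0
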