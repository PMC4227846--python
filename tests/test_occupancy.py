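import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from dissimogram import (
    DetectionHistories,
    OccupancyModel,
    build_histories,
    fit_occupancy,
    multi_season_loglik,
    single_season_loglik,
    species_detectability,
    summarize_detectability,
)
from dissimogram.exceptions import ValidationError

from oracles import occupancy_likelihood_by_paths, single_season_grid_mle


def hist(data, species="sp"):
    data = np.asarray(data, float)
    if data.ndim == 2:
        data = data[:, None, :]
    years = list(range(1, data.shape[1] + 1))
    plots = [f"P{i}" for i in range(data.shape[0])]
    return DetectionHistories(data, plots, years, species)


class TestBuildHistories:
    def test_thresholding(self):
        table = pd.DataFrame(
            [
                {"plot_id": "P1", "region": "A", "year": 1, "round": r,
                 "species": "sp", "count": c}
                for r, c in [(1, 0), (2, 2), (3, 0), (4, 1), (5, 0)]
            ]
        )
        h = build_histories(table, "sp", n_rounds=5)
        assert list(h.data[0, 0]) == [0, 1, 0, 1, 0]

    def test_never_recorded_species_all_zero(self):
        table = pd.DataFrame(
            [{"plot_id": "P1", "region": "A", "year": 1, "round": 1,
              "species": "other", "count": 2}]
        )
        h = build_histories(table, "sp", n_rounds=3)
        assert (h.data == 0).all()

    def test_effort_marks_missing_occasions(self):
        table = pd.DataFrame(
            [{"plot_id": "P1", "region": "A", "year": 1, "round": 1,
              "species": "sp", "count": 1}]
        )
        effort = pd.DataFrame(
            [{"plot_id": "P1", "year": 1, "round": 1},
             {"plot_id": "P1", "year": 1, "round": 2}]
        )
        h = build_histories(table, "sp", n_rounds=3, effort=effort)
        assert h.data[0, 0, 0] == 1 and h.data[0, 0, 1] == 0
        assert math.isnan(h.data[0, 0, 2])
        # missing occasion contributes no emission term
        ll_full = single_season_loglik(hist([[1, 0]]), 0.6, 0.4)
        ll_missing = single_season_loglik(h, 0.6, 0.4)
        assert ll_missing == pytest.approx(ll_full)


class TestSingleSeasonLikelihood:
    def test_all_zero_history_closed_form(self):
        # psi*(1-p)^T + (1-psi) with T=2, psi=p=0.5 -> 0.625 per plot
        ll = single_season_loglik(hist([[0, 0]]), 0.5, 0.5)
        assert ll == pytest.approx(math.log(0.625))

    def test_detection_closed_form(self):
        ll = single_season_loglik(hist([[1]]), 1.0, 0.3)
        assert ll == pytest.approx(math.log(0.3))

    def test_impossible_event_floored(self):
        ll = single_season_loglik(hist([[1, 0]]), 0.5, 1.0)
        assert ll < -600  # floored log of an impossible history

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            single_season_loglik(hist([[0, 1]]), 1.2, 0.5)

    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_likelihood_sums_to_one_over_histories(self, T):
        psi, p = 0.37, 0.62
        total = sum(
            math.exp(single_season_loglik(hist([h]), psi, p))
            for h in product((0, 1), repeat=T)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestMultiSeasonLikelihood:
    def test_one_season_reduces_to_single(self):
        rng = np.random.default_rng(0)
        data = (rng.random((6, 1, 4)) < 0.4).astype(float)
        h = hist(data)
        assert multi_season_loglik(h, 0.55, 0.3, 0.2, 0.45) == (
            single_season_loglik(h, 0.55, 0.45)
        )

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        data = (rng.random((3, 3, 3)) < 0.4).astype(float)
        h = hist(data)
        for params in [(0.5, 0.2, 0.3, 0.6), (0.8, 0.0, 0.0, 0.4),
                       (0.3, 0.7, 0.5, 0.9)]:
            want = sum(
                math.log(occupancy_likelihood_by_paths(data[i], *params))
                for i in range(3)
            )
            assert multi_season_loglik(h, *params) == pytest.approx(
                want, abs=1e-10
            )

    def test_static_limit_equals_two_state_closed_form(self):
        # gamma = epsilon = 0: occupancy never changes, so the likelihood is
        # psi * P(data | occupied) + (1-psi) * P(data | empty)
        data = np.array([[[1, 0], [0, 0], [1, 1]]], float)  # 1 plot, 3 seasons
        h = hist(data)
        psi, p = 0.6, 0.45
        occ = (p * (1 - p)) * ((1 - p) ** 2) * (p * p)
        want = math.log(psi * occ + (1 - psi) * 0.0)
        got = multi_season_loglik(h, psi, 0.0, 0.0, p)
        assert got == pytest.approx(want, abs=1e-12)

    def test_p_zero_ignores_detection_free_data(self):
        all_zero = hist(np.zeros((4, 2, 3)))
        ll = multi_season_loglik(all_zero, 0.5, 0.3, 0.3, 0.0)
        assert ll == pytest.approx(0.0)  # every all-zero history has prob 1

    def test_sums_to_one_over_all_histories(self):
        psi1, gamma, eps, p = 0.4, 0.25, 0.35, 0.55
        total = 0.0
        for bits in product((0, 1), repeat=4):  # 2 seasons x 2 occasions
            data = np.array(bits, float).reshape(1, 2, 2)
            total += math.exp(
                multi_season_loglik(hist(data), psi1, gamma, eps, p)
            )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestFit:
    def test_mle_matches_grid_oracle_on_tiny_instance(self):
        data = np.array([[1, 0], [0, 0]], float)
        res = fit_occupancy(hist(data), model="single")
        _, psi_g, p_g = single_season_grid_mle(data, n_grid=200)
        grid_step = 1.0 / 199
        assert res.psi == pytest.approx(psi_g, abs=grid_step)
        assert res.p == pytest.approx(p_g, abs=grid_step)

    def test_all_ones_boundary(self):
        res = fit_occupancy(hist(np.ones((5, 3))), model="single")
        assert res.psi > 0.999 and res.p > 0.999
        assert res.at_boundary

    def test_no_detections_flagged_not_raised(self):
        res = fit_occupancy(hist(np.zeros((5, 3))), model="single")
        assert res.at_boundary

    def test_parameter_recovery_single_season(self):
        rng = np.random.default_rng(8)
        psi, p = 0.6, 0.5
        ests = []
        for _ in range(4):
            z = rng.random(150) < psi
            data = ((rng.random((150, 5)) < p) & z[:, None]).astype(float)
            res = fit_occupancy(hist(data), model="single")
            ests.append((res.psi, res.p))
        mean = np.mean(ests, axis=0)
        assert abs(mean[0] - psi) < 0.07 and abs(mean[1] - p) < 0.07

    def test_plot_order_invariance(self):
        rng = np.random.default_rng(9)
        data = (rng.random((30, 4)) < 0.3).astype(float)
        r1 = fit_occupancy(hist(data), model="single")
        r2 = fit_occupancy(hist(data[::-1]), model="single")
        assert r1.psi == pytest.approx(r2.psi, abs=1e-4)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-5)

    def test_mle_beats_truth(self):
        rng = np.random.default_rng(10)
        psi, p = 0.55, 0.4
        z = rng.random(80) < psi
        data = ((rng.random((80, 4)) < p) & z[:, None]).astype(float)
        model = OccupancyModel(hist(data), model="single")
        res = model.fit()
        assert res.loglik >= model.loglik((psi, p)) - 1e-9

    def test_multi_season_recovery(self):
        rng = np.random.default_rng(12)
        psi1, gamma, eps, p = 0.6, 0.3, 0.25, 0.5
        n, S, T = 200, 4, 4
        z = np.empty((n, S), bool)
        z[:, 0] = rng.random(n) < psi1
        for t in range(1, S):
            stay = rng.random(n) < 1 - eps
            col = rng.random(n) < gamma
            z[:, t] = np.where(z[:, t - 1], stay, col)
        data = ((rng.random((n, S, T)) < p) & z[:, :, None]).astype(float)
        res = fit_occupancy(hist(data), model="multi")
        assert res.psi == pytest.approx(psi1, abs=0.12)
        assert res.p == pytest.approx(p, abs=0.08)


class TestDetectabilitySummary:
    def test_mean_of_three(self):
        fits = pd.DataFrame(
            {"species": list("abc"), "psi": [0.5, 0.6, 0.64],
             "converged": True}
        )
        s = summarize_detectability(fits)
        assert s["mean_psi"] == pytest.approx(0.58)
        assert s["n_species"] == 3

    def test_single_species(self):
        fits = pd.DataFrame(
            {"species": ["a"], "psi": [0.44], "converged": [True]}
        )
        assert summarize_detectability(fits)["mean_psi"] == pytest.approx(0.44)

    def test_species_detectability_table(self):
        rng = np.random.default_rng(3)
        rows = []
        for sp in ("sp1", "sp2"):
            for plot in range(12):
                for r in range(1, 4):
                    if rng.random() < 0.3:
                        rows.append(
                            {"plot_id": f"P{plot}", "region": "A", "year": 1,
                             "round": r, "species": sp, "count": 1}
                        )
        table = pd.DataFrame(rows)
        fits = species_detectability(
            table, plots=[f"P{i}" for i in range(12)], n_rounds=3
        )
        assert set(fits["species"]) == {"sp1", "sp2"}
        assert ((fits["psi"] >= 0) & (fits["psi"] <= 1)).all()
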