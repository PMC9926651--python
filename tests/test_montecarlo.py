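"""Monte Carlo carbon-uncertainty simulation: analytic checks and scaling."""

import numpy as np
import pandas as pd
import pytest

from degratex import ACDDistribution, SimulationResult, compare, simulate


def prob_cells(p_rows, site="s"):
    df = pd.DataFrame(p_rows, columns=["p_intact", "p_logged", "p_burned"])
    df.insert(0, "site_id", site)
    return df


def point_dists(site="s", intact=100.0, logged=50.0, burned=20.0):
    return [
        ACDDistribution(site, "intact", [intact]),
        ACDDistribution(site, "logged", [logged]),
        ACDDistribution(site, "burned", [burned]),
    ]


class TestSimulate:
    def test_point_mass_analytic_expectation(self):
        cells = prob_cells([(0.6, 0.4, 0.0)])
        only = simulate(cells, point_dists(), "acd_only", n_iter=10_000, seed=1)
        plus = simulate(cells, point_dists(), "acd_plus_class", n_iter=10_000, seed=1)
        assert only.mean == 100.0 and only.sd == 0.0
        per_draw_var = 0.6 * (100 - 80) ** 2 + 0.4 * (50 - 80) ** 2
        se = np.sqrt(per_draw_var / 10_000)
        assert abs(plus.mean - 80.0) < 3 * se

    def test_multi_cell_analytic_expectation(self):
        P = [(0.5, 0.5, 0.0), (1.0, 0.0, 0.0), (0.0, 0.2, 0.8)]
        expected = np.mean([0.5 * 100 + 0.5 * 50, 100, 0.2 * 50 + 0.8 * 20])
        plus = simulate(prob_cells(P), point_dists(), "acd_plus_class",
                        n_iter=20_000, seed=3)
        assert abs(plus.mean - expected) < 4 * plus.sd / np.sqrt(20_000) + 0.2

    def test_one_hot_modes_agree_in_distribution(self):
        rng = np.random.default_rng(0)
        onehot = [tuple(np.eye(3)[rng.integers(0, 3)]) for _ in range(30)]
        dists = [
            ACDDistribution("s", c, rng.uniform(40, 120, 200))
            for c in ("intact", "logged", "burned")
        ]
        a = simulate(prob_cells(onehot), dists, "acd_only", n_iter=4000, seed=5)
        b = simulate(prob_cells(onehot), dists, "acd_plus_class", n_iter=4000, seed=6)
        se = np.sqrt(a.sd**2 + b.sd**2) / np.sqrt(4000)
        assert abs(a.mean - b.mean) < 4 * se

    def test_same_seed_identical_iteration_vectors(self):
        cells = prob_cells([(0.3, 0.3, 0.4), (0.2, 0.5, 0.3)])
        dists = [
            ACDDistribution("s", c, np.random.default_rng(1).uniform(10, 90, 50))
            for c in ("intact", "logged", "burned")
        ]
        r1 = simulate(cells, dists, "acd_plus_class", n_iter=500, seed=11)
        r2 = simulate(cells, dists, "acd_plus_class", n_iter=500, seed=11)
        assert np.array_equal(r1.iteration_means, r2.iteration_means)

    def test_sd_scales_inverse_sqrt_cells(self):
        rng = np.random.default_rng(2)
        dists = [
            ACDDistribution("s", c, rng.uniform(40, 120, 300))
            for c in ("intact", "logged", "burned")
        ]
        sds = []
        for M in (25, 100, 400):
            P = [(1 / 3, 1 / 3, 1 / 3)] * M
            res = simulate(prob_cells(P), dists, "acd_plus_class",
                           n_iter=3000, seed=M)
            sds.append(res.sd)
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.15)
        assert sds[1] / sds[2] == pytest.approx(2.0, rel=0.15)

    def test_empty_reachable_distribution_rejected(self):
        cells = prob_cells([(0.5, 0.5, 0.0)])
        dists = [ACDDistribution("s", "intact", [100.0]),
                 ACDDistribution("s", "logged", [])]
        with pytest.raises(ValueError, match="logged"):
            simulate(cells, dists, "acd_plus_class", n_iter=10, seed=0)

    def test_invalid_probability_rows_rejected(self):
        cells = prob_cells([(0.9, 0.3, 0.0)])
        with pytest.raises(ValueError, match="sum to 1"):
            simulate(cells, point_dists(), "acd_only", n_iter=10, seed=0)


class TestCompare:
    def test_identical_inputs_degenerate_report(self):
        r = SimulationResult("s", "acd_only", np.array([1.0, 2.0, 3.0, 2.0]), 4, 0)
        s = SimulationResult("s", "acd_plus_class", r.iteration_means.copy(), 4, 0)
        rep = compare(r, s)
        assert rep["mean_diff"] == 0
        assert rep["sd_ratio"] == 1
        assert rep["overlap"] == 1

    def test_disjoint_distributions_zero_overlap(self):
        a = SimulationResult("s", "acd_only", np.linspace(0, 1, 100), 100, 0)
        b = SimulationResult("s", "acd_plus_class", np.linspace(5, 6, 100), 100, 0)
        assert compare(a, b)["overlap"] == 0

    def test_site_mismatch_rejected(self):
        a = SimulationResult("s", "acd_only", np.ones(4), 4, 0)
        b = SimulationResult("t", "acd_plus_class", np.ones(4), 4, 0)
        with pytest.raises(ValueError, match="site"):
            compare(a, b)

    def test_logged_burned_confusion_lowers_mean_raises_sd(self):
        # logged cells carrying burned probability pull the mean down and
        # widen the spread relative to the hard-class simulation
        rng = np.random.default_rng(8)
        P = [(0.0, 0.8, 0.2)] * 40 + [(1.0, 0.0, 0.0)] * 60
        dists = [
            ACDDistribution("s", "intact", rng.normal(90, 5, 400).clip(0)),
            ACDDistribution("s", "logged", rng.normal(94, 8, 400).clip(0)),
            ACDDistribution("s", "burned", rng.normal(58, 20, 400).clip(0)),
        ]
        a = simulate(prob_cells(P), dists, "acd_only", n_iter=4000, seed=1)
        b = simulate(prob_cells(P), dists, "acd_plus_class", n_iter=4000, seed=2)
        rep = compare(a, b)
        assert rep["mean_diff"] < 0
        assert rep["sd_ratio"] > 1
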