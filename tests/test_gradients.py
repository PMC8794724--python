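"""Relative fitness, Robertson-Price covariance, realized-fitness gradients."""

import numpy as np
import pandas as pd
import pytest

from selfpop.gradients import (
    RealizedFitnessGradient,
    RobertsonPriceGradient,
    fitness_proxy_check,
    genetic_variance_theta,
    realized_fitness_gradient,
    relative_fitness,
)
from selfpop.io import PhenotypeTable
from selfpop.synth import freq_table_from_counts, simulate_mlg_dynamics

from conftest import make_pheno


def rp_pheno(cov, n_fam=55, n_rep=5, trait_sd_env=40.0, w_sd_env=0.4, seed=0):
    """Family design with a planted genetic (trait, fitness) covariance."""
    rng = np.random.default_rng(seed)
    sigma = np.array([[75.0**2, cov], [cov, 0.6**2]])
    g = rng.multivariate_normal([900.0, 2.0], sigma, n_fam)
    rows, pid = [], 0
    for f in range(n_fam):
        for r in range(n_rep):
            rows.append(
                dict(plant=f"P{pid:04d}", family=f"F{f:02d}", year="1987",
                     treatment="short", block=f"B{r + 1}",
                     flowering_time=g[f, 0] + rng.normal(0, trait_sd_env),
                     seeds=max(0.0, 100 * (g[f, 1] + rng.normal(0, w_sd_env))))
            )
            pid += 1
    return PhenotypeTable(pd.DataFrame(rows))


class TestRelativeFitness:
    def test_equal_seeds_all_one(self):
        pt = make_pheno(seed=1)
        pt.data["seeds"] = 50.0
        assert np.allclose(relative_fitness(pt), 1.0)

    def test_two_plant_group(self):
        df = pd.DataFrame(
            dict(plant=["a", "b"], family=["f1", "f2"], year=["1987"] * 2,
                 treatment=["short"] * 2, block=["B1", "B2"],
                 flowering_time=[900.0, 910.0], seeds=[10.0, 30.0])
        )
        w = relative_fitness(PhenotypeTable(df))
        np.testing.assert_allclose(w.to_numpy(), [0.5, 1.5])

    def test_group_means_are_one(self):
        pt = make_pheno(seed=2, years=("1987", "2009"))
        df = pt.data.assign(w=relative_fitness(pt))
        means = df.groupby(["year", "treatment"])["w"].mean()
        np.testing.assert_allclose(means.to_numpy(), 1.0)

    def test_zero_mean_group_errors(self):
        pt = make_pheno(seed=3)
        pt.data["seeds"] = 0.0
        with pytest.raises(ValueError):
            relative_fitness(pt)


class TestRobertsonPrice:
    def test_constant_fitness_zero_covariance(self):
        pt = make_pheno(seed=4)
        pt.data["seeds"] = 123.0
        res = RobertsonPriceGradient(year="1987", treatment="short").fit(pt).result_
        assert res.estimate == pytest.approx(0.0, abs=1e-9)

    def test_theta_with_itself_is_genetic_variance(self):
        pt = rp_pheno(cov=-20.0, seed=5)
        v = genetic_variance_theta(pt, "flowering_time", "1987", "short")
        assert v > 0
        # planted genetic trait variance 75^2; loose sampling band for 55 families
        assert v == pytest.approx(75.0**2, rel=0.6)

    def test_parameter_recovery_planted_negative_covariance(self):
        # w standardization divides seeds by their mean (~200), cancelling the x100 scale
        ests = []
        for seed in range(120):
            pt = rp_pheno(cov=-20.0, seed=seed)
            w_scale = pt.data["seeds"].mean() / 100.0  # relative fitness rescaling
            est = RobertsonPriceGradient(year="1987", treatment="short").fit(pt)
            ests.append(est.estimate_ * w_scale)
        ests = np.array(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - (-20.0)) < 2 * mc_se + 1.0

    def test_significance_detects_strong_covariance(self):
        pt = rp_pheno(cov=-25.0, seed=11)
        res = RobertsonPriceGradient(year="1987", treatment="short", n_perm=300,
                                     random_state=0).fit(pt).result_
        assert res.estimate < 0 and res.p_value < 0.05
        assert res.ci95[0] <= res.estimate <= res.ci95[1]
        assert res.meta["permutation_p"] < 0.1

    def test_degenerate_family_structure(self):
        pt = make_pheno(n_families=2, seed=6)
        with pytest.raises(ValueError, match="family structure"):
            RobertsonPriceGradient().fit(pt)


class TestRealizedFitness:
    def test_zero_changes_zero_slope(self):
        ft = freq_table_from_counts([5, 5, 5, 5], [5, 5, 5, 5])
        res = realized_fitness_gradient(ft, np.array([800.0, 850, 950, 1000]))
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.ci95[0] == pytest.approx(-res.ci95[1], abs=1e-9)

    def test_closed_form_three_points(self):
        ft = freq_table_from_counts([3, 3, 4], [4, 3, 3])
        # deltas exactly (+0.1, 0, -0.1) against traits (800, 900, 1000)
        res = realized_fitness_gradient(ft, np.array([800.0, 900.0, 1000.0]))
        assert res.estimate == pytest.approx(-0.001, abs=1e-12)

    def test_shift_invariance_and_scaling(self, rng):
        ft = freq_table_from_counts(rng.integers(1, 9, 8), rng.integers(1, 9, 8))
        x = rng.normal(900, 75, 8)
        base = realized_fitness_gradient(ft, x).estimate
        shifted = realized_fitness_gradient(ft, x + 500).estimate
        scaled = realized_fitness_gradient(ft, 2 * x).estimate
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base / 2, rel=1e-9)

    def test_restrict_to_year1(self):
        ft = freq_table_from_counts([4, 4, 0, 4], [3, 3, 3, 3])
        res = RealizedFitnessGradient(restrict_to_year1=True).fit(
            ft, np.array([800.0, 900, 950, 1000])
        ).result_
        assert res.n_units == 3

    def test_sign_recovery_under_planted_selection(self):
        rng = np.random.default_rng(0)
        neg = 0
        n_sims = 100
        for s in range(n_sims):
            traits = rng.normal(900, 75, 20)
            ft = simulate_mlg_dynamics(
                np.full(20, 1 / 20), traits, -0.004, 200, 22, (58, 75), seed=1000 + s
            )
            neg += realized_fitness_gradient(ft, traits).estimate < 0
        assert neg >= 0.95 * n_sims

    def test_degenerate_inputs(self):
        ft = freq_table_from_counts([5, 5], [5, 5])
        with pytest.raises(ValueError):
            realized_fitness_gradient(ft, np.array([1.0, 2.0]))
        ft3 = freq_table_from_counts([5, 5, 5], [5, 5, 5])
        with pytest.raises(ValueError, match="trait variance"):
            realized_fitness_gradient(ft3, np.array([7.0, 7.0, 7.0]))


class TestFitnessProxy:
    def test_constant_seeds_zero_slope(self):
        ft = freq_table_from_counts([5, 4, 3], [3, 4, 5])
        res = fitness_proxy_check(ft, np.array([100.0, 100.0, 100.0]))
        assert res.estimate == 0.0 and res.p_value == 1.0

    def test_planted_fitness_drives_both(self):
        rng = np.random.default_rng(1)
        traits = rng.normal(900, 75, 30)
        seeds = 500 - 0.6 * (traits - 900) + rng.normal(0, 15, 30)
        ft = simulate_mlg_dynamics(
            np.full(30, 1 / 30), traits, -0.002, 2000, 22, (200, 200), seed=42
        )
        res = fitness_proxy_check(ft, seeds)
        assert res.estimate > 0 and res.p_value < 0.05
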