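"""Thermal time, vernalization sensitivity, mixed models and heritability."""

import numpy as np
import pandas as pd
import pytest

from selfpop.io import PhenotypeTable
from selfpop.pheno import (
    degree_days_to_days,
    fit_lmm,
    h2_from_components,
    heritability,
    lrt_compare,
    thermal_time,
    variance_components_cell,
    vernalization_sensitivity,
)
from selfpop.synth import simulate_family_design

from conftest import make_pheno


class TestThermalTime:
    def test_constant_temperature(self):
        temps = pd.Series(15.0, index=range(0, 40))
        assert thermal_time(temps, 0, 10) == pytest.approx(100.0)

    def test_cold_day_contributes_zero(self):
        temps = pd.Series([15.0, 3.0, 15.0], index=[0, 1, 2])
        assert thermal_time(temps, 0, 3) == pytest.approx(20.0)

    def test_additive_and_monotone(self):
        rng = np.random.default_rng(0)
        temps = pd.Series(rng.uniform(0, 25, 60), index=range(60))
        total = thermal_time(temps, 5, 50)
        assert total == pytest.approx(thermal_time(temps, 5, 30) + thermal_time(temps, 30, 50))
        assert thermal_time(temps, 5, 51) >= total

    def test_gaps_reported(self):
        temps = pd.Series([15.0, 15.0], index=[0, 2])
        with pytest.raises(ValueError, match=r"\[1\]"):
            thermal_time(temps, 0, 3)

    def test_display_conversion(self):
        # Table-style footnote: 28.76 degree.days ~ two days at a 15 C mean ...
        assert degree_days_to_days(28.76) == pytest.approx(1.92, abs=0.01)
        # ... and ~three days dividing by the mean *effective* temperature
        assert degree_days_to_days(28.76, t_base=5) == pytest.approx(2.88, abs=0.01)


class TestVernalizationSensitivity:
    def _table(self):
        rows = []
        # family f1: short blocks B1..B5, long blocks B1..B5 (mirror pairs B1-B5 etc.)
        short = {"B1": 400.0, "B2": 410, "B3": 420, "B4": 430, "B5": 440}
        long_ = {"B1": 330.0, "B2": 325, "B3": 320, "B4": 315, "B5": 320}
        pid = 0
        for tr, vals in (("short", short), ("long", long_)):
            for b, y in vals.items():
                rows.append(dict(plant=f"P{pid}", family="f1", year="1987",
                                 treatment=tr, block=b, flowering_time=y, seeds=np.nan))
                pid += 1
        return PhenotypeTable(pd.DataFrame(rows))

    def test_arithmetic(self):
        pt = self._table()
        out = vernalization_sensitivity(pt)
        mean_diff = pt.data[pt.data.treatment == "long"].flowering_time.mean() - \
            pt.data[pt.data.treatment == "short"].flowering_time.mean()
        row = out[(out.block_short == "B1")].iloc[0]
        assert row.block_long == "B5"  # mirrored pairing
        assert row.sensitivity == pytest.approx((320 - 400) / mean_diff)

    def test_reference_values(self):
        # individual pair matching the population mean difference scores 1
        df = pd.DataFrame(
            dict(plant=["a", "b"], family=["f", "f"], year=["1987"] * 2,
                 treatment=["short", "long"], block=["B1", "B1"],
                 flowering_time=[450.0, 350.0], seeds=[np.nan] * 2)
        )
        out = vernalization_sensitivity(PhenotypeTable(df))
        assert out.sensitivity.iloc[0] == pytest.approx(1.0)

    def test_zero_mean_difference_errors(self):
        df = pd.DataFrame(
            dict(plant=["a", "b"], family=["f", "f"], year=["1987"] * 2,
                 treatment=["short", "long"], block=["B1", "B1"],
                 flowering_time=[400.0, 400.0], seeds=[np.nan] * 2)
        )
        with pytest.raises(ValueError):
            vernalization_sensitivity(PhenotypeTable(df))


class TestMixedModels:
    def test_reml_matches_moments_on_balanced_cell(self):
        pt = simulate_family_design(n_families=30, seed=1)
        fit = fit_lmm(pt, "eq3")
        mom = variance_components_cell(pt.data)
        assert fit.varcomps["family"] == pytest.approx(mom["family"], rel=1e-3)
        assert fit.varcomps["block"] == pytest.approx(mom["block"], rel=1e-3, abs=1.0)
        assert fit.resid_var == pytest.approx(mom["residual"], rel=1e-3)

    def test_zero_family_variance_detected(self):
        pt = simulate_family_design(n_families=40, vg=0.0, seed=2)
        fit = fit_lmm(pt, "eq3")
        assert fit.varcomps["family"] < 0.05 * fit.resid_var

    def test_eq1_recovers_planted_components(self):
        from selfpop.synth import generate_experiment

        pt = generate_experiment(n_families=60, vg=3000.0, vblock=90.0, vres=1500.0, seed=5)
        fit = fit_lmm(pt, "eq1")
        fam = [v for k, v in fit.varcomps.items() if k.startswith("family")]
        assert np.mean(fam) == pytest.approx(3000.0, rel=0.35)
        assert fit.resid_var == pytest.approx(1500.0, rel=0.15)
        assert fit.fixed_effects["treatment[short]"] == pytest.approx(162.84, rel=0.15)

    def test_lrt_identical_models(self):
        pt = simulate_family_design(n_families=20, seed=3)
        fit = fit_lmm(pt, "eq3", method="ml")
        res = lrt_compare(fit, fit)
        assert res["chi2"] == 0.0 and res["p_value"] == 1.0

    def test_lrt_rejects_extra_params(self):
        pt = make_pheno(n_families=20, seed=3, years=("1987", "2009"), seeds_col=False)
        full = fit_lmm(pt, "eq3", method="ml")
        # "reduced" with more parameters than the full model is not nested
        with pytest.raises(ValueError):
            lrt_compare(
                fit_lmm(pt, "eq3", method="ml", drop_fixed=("year",)), full
            )

    def test_lrt_mixed_methods_rejected(self):
        pt = simulate_family_design(n_families=20, seed=3)
        with pytest.raises(ValueError):
            lrt_compare(fit_lmm(pt, "eq3", method="reml"), fit_lmm(pt, "eq3", method="ml"))


class TestHeritability:
    def test_h2_arithmetic(self):
        # the four-component bookkeeping: VG/(VG + Vblock + Vresid)
        assert h2_from_components(2807.9, 92.34, 1500.0) == pytest.approx(0.638, abs=1e-3)

    def test_zero_genetic_variance(self):
        pt = simulate_family_design(n_families=40, vg=0.0, seed=7)
        est = heritability(pt, year="1987", treatment="short", jackknife=False)
        assert est.h2 < 0.1

    def test_planted_h2_recovered_within_two_se(self):
        pt = simulate_family_design(n_families=55, vg=3000.0, vblock=90.0, vres=1500.0, seed=8)
        est = heritability(pt, year="1987", treatment="short")
        truth = 3000.0 / (3000.0 + 90.0 + 1500.0)
        assert abs(est.h2 - truth) < 2 * est.se

    def test_scale_invariance(self):
        pt = simulate_family_design(n_families=30, seed=9)
        est1 = heritability(pt, jackknife=False)
        pt.data["flowering_time"] *= 3.7
        est2 = heritability(pt, jackknife=False)
        assert est1.h2 == pytest.approx(est2.h2, rel=1e-9)

    def test_accepts_lmm_fit(self):
        pt = simulate_family_design(n_families=25, seed=10)
        fit = fit_lmm(pt, "eq3")
        est = heritability(fit, jackknife=False)
        assert 0 <= est.h2 <= 1

    def test_eq3_is_eq1_machinery_relabelled(self):
        # regional model: population takes the place of family
        pt = simulate_family_design(n_families=30, seed=11)
        fam_fit = fit_lmm(pt, "eq3", group_col="family")
        relabeled = PhenotypeTable(
            pt.data.rename(columns={"family": "population"}).assign(
                family=lambda d: d["population"]
            )
        )
        pop_fit = fit_lmm(relabeled, "eq3", group_col="population")
        assert pop_fit.varcomps["population"] == pytest.approx(
            fam_fit.varcomps["family"], rel=1e-6
        )
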