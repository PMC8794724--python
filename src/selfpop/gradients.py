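"""Selection-gradient estimation for flowering time.

Two complementary estimates of selection on flowering time:

* the Robertson-Price identity: the expected per-generation change of a trait
  equals its (additive) genetic covariance with relative fitness.  With a
  selfed full-sib family design and negligible dominance, the broad-sense
  genetic covariance estimated from the family structure stands in for the
  additive one.
* the realized-fitness gradient: the OLS slope of the signed change in MLG
  frequency between the two sampling years on the MLG genetic value for
  flowering time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .io import PhenotypeTable
from .mlg import FrequencyChangeTable


@dataclass
class GradientEstimate:
    kind: str  # "robertson_price" | "realized_fitness" | "fitness_proxy"
    estimate: float
    ci95: tuple[float, float]
    p_value: float
    n_units: int
    statistic: float | None = None
    method: str = ""
    meta: dict | None = None


def relative_fitness(pheno: PhenotypeTable) -> pd.Series:
    """Per-plant relative seed production, standardized by the mean of the
    plant's own year x treatment group (group means of w equal 1)."""
    df = pheno.data
    if not pheno.has_seeds:
        raise ValueError("phenotype table has no seed counts")
    means = df.groupby(["year", "treatment"])["seeds"].transform("mean")
    if (means == 0).any() or means.isna().any():
        raise ValueError("a year x treatment group has zero mean seed production")
    w = df["seeds"] / means
    w.name = "relative_fitness"
    return w


def _block_adjust(df: pd.DataFrame, col: str) -> np.ndarray:
    """Residuals of ``col`` after removing block means (micro-environment)."""
    y = df[col].to_numpy(float)
    return y - df.groupby("block")[col].transform("mean").to_numpy(float) + y.mean()


def _family_cross_covariance(
    z: np.ndarray, w: np.ndarray, fam: np.ndarray
) -> tuple[float, int]:
    """Henderson-moment genetic covariance between two traits from the family
    structure: between-family mean cross-product minus the within-family one,
    scaled by the effective replicate number n0."""
    df = pd.DataFrame({"z": z, "w": w, "fam": fam})
    g = df.groupby("fam")
    nf = g.size().to_numpy(float)
    F = len(nf)
    if F < 3:
        raise ValueError("degenerate family structure (<3 families)")
    N = nf.sum()
    zm = g["z"].mean().to_numpy()
    wm = g["w"].mean().to_numpy()
    zbar = (nf * zm).sum() / N
    wbar = (nf * wm).sum() / N
    mcp_between = (nf * (zm - zbar) * (wm - wbar)).sum() / (F - 1)
    within = (
        ((df["z"] - g["z"].transform("mean")) * (df["w"] - g["w"].transform("mean"))).sum()
    )
    dof_within = N - F
    mcp_within = within / dof_within if dof_within > 0 else 0.0
    n0 = (N - (nf**2).sum() / N) / (F - 1)
    return float((mcp_between - mcp_within) / n0), int(F)


class RobertsonPriceGradient(BaseEstimator):
    """Broad-sense genetic covariance between a trait and relative fitness.

    Both variables are block-adjusted; the covariance is estimated from the
    family cross-products (method of moments).  Significance and the CI come
    from a delete-one-family jackknife; a family-pairing permutation p-value
    is stored alongside when ``n_perm > 0``.
    """

    def __init__(
        self,
        trait: str = "flowering_time",
        year: str | None = None,
        treatment: str | None = None,
        n_perm: int = 0,
        random_state: int | None = None,
    ):
        self.trait = trait
        self.year = year
        self.treatment = treatment
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, pheno: PhenotypeTable, y=None) -> "RobertsonPriceGradient":
        w_all = relative_fitness(pheno)
        df = pheno.data.assign(_w=w_all)
        if self.year is not None:
            df = df[df["year"] == str(self.year)]
        if self.treatment is not None:
            df = df[df["treatment"] == str(self.treatment)]
        df = df.dropna(subset=[self.trait, "_w"]).reset_index(drop=True)
        z = _block_adjust(df, self.trait)
        w = _block_adjust(df, "_w")
        fam = df["family"].to_numpy()
        theta, F = _family_cross_covariance(z, w, fam)

        fams = np.unique(fam)
        loo = np.empty(len(fams))
        for i, f in enumerate(fams):
            keep = fam != f
            loo[i], _ = _family_cross_covariance(z[keep], w[keep], fam[keep])
        se = float(np.sqrt((F - 1) / F * ((loo - loo.mean()) ** 2).sum()))
        tstat = theta / se if se > 0 else np.inf * np.sign(theta)
        p = float(2 * stats.t.sf(abs(tstat), df=F - 1))
        half = stats.t.ppf(0.975, df=F - 1) * se
        perm_p = None
        if self.n_perm:
            rng = np.random.default_rng(self.random_state)
            zm = pd.Series(z).groupby(fam).mean().to_numpy()
            wm = pd.Series(w).groupby(fam).mean().to_numpy()
            obs = np.cov(zm, wm)[0, 1]
            null = np.array(
                [np.cov(zm, rng.permutation(wm))[0, 1] for _ in range(self.n_perm)]
            )
            perm_p = float(((np.abs(null) >= abs(obs)).sum() + 1) / (self.n_perm + 1))
        self.estimate_ = theta
        self.se_ = se
        self.result_ = GradientEstimate(
            kind="robertson_price",
            estimate=theta,
            ci95=(theta - half, theta + half),
            p_value=p,
            n_units=F,
            statistic=float(tstat),
            method="family_moments_jackknife",
            meta={"permutation_p": perm_p, "year": self.year, "treatment": self.treatment},
        )
        return self


def robertson_price_gradient(
    pheno: PhenotypeTable,
    trait: str = "flowering_time",
    year: str | None = None,
    treatment: str | None = None,
) -> GradientEstimate:
    return RobertsonPriceGradient(trait=trait, year=year, treatment=treatment).fit(pheno).result_


def genetic_variance_theta(pheno: PhenotypeTable, trait: str, year=None, treatment=None) -> float:
    """Theta of a trait with itself = the moment estimate of its genetic variance."""
    df = pheno.cell(year, treatment).dropna(subset=[trait]).reset_index(drop=True)
    z = _block_adjust(df, trait)
    v, _ = _family_cross_covariance(z, z, df["family"].to_numpy())
    return v


def _ols_gradient(x: np.ndarray, y: np.ndarray, kind: str, meta: dict) -> GradientEstimate:
    if len(x) < 3:
        raise ValueError("need at least 3 MLGs")
    if np.ptp(x) == 0:
        raise ValueError("zero trait variance")
    X = sm.add_constant(np.asarray(x, float))
    fit = sm.OLS(np.asarray(y, float), X).fit()
    ci = fit.conf_int()[1]
    resid = fit.resid
    try:
        shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else None
    except ValueError:
        shapiro_p = None
    meta = dict(meta, residual_normality_p=shapiro_p)
    return GradientEstimate(
        kind=kind,
        estimate=float(fit.params[1]),
        ci95=(float(ci[0]), float(ci[1])),
        p_value=float(fit.pvalues[1]),
        n_units=int(len(x)),
        statistic=float(fit.tvalues[1]),
        method="ols_t_profile",
        meta=meta,
    )


class RealizedFitnessGradient(BaseEstimator):
    """Slope of signed MLG frequency change on MLG mean flowering time.

    The 95% CI is the t-based interval, which coincides with the
    profile-likelihood bounds under the Gaussian linear model.
    """

    def __init__(self, restrict_to_year1: bool = False):
        self.restrict_to_year1 = restrict_to_year1

    def fit(
        self, freq_table: FrequencyChangeTable, trait_values: np.ndarray
    ) -> "RealizedFitnessGradient":
        df = freq_table.table
        x = np.asarray(trait_values, dtype=float)
        if len(x) != len(df):
            raise ValueError("one trait value per MLG required")
        keep = df["present_in_year1"].to_numpy() if self.restrict_to_year1 else np.ones(len(df), bool)
        self.result_ = _ols_gradient(
            x[keep],
            df["delta"].to_numpy()[keep],
            kind="realized_fitness",
            meta={"restricted_to_year1": bool(self.restrict_to_year1)},
        )
        self.estimate_ = self.result_.estimate
        return self


def realized_fitness_gradient(
    freq_table: FrequencyChangeTable,
    trait_values: np.ndarray,
    restrict_to_year1: bool = False,
) -> GradientEstimate:
    return (
        RealizedFitnessGradient(restrict_to_year1=restrict_to_year1)
        .fit(freq_table, trait_values)
        .result_
    )


def fitness_proxy_check(
    freq_table: FrequencyChangeTable, mean_seeds: np.ndarray, restrict_to_year1: bool = False
) -> GradientEstimate:
    """Regression of MLG frequency change on greenhouse seed production: a
    positive slope supports frequency change as a realized-fitness proxy."""
    df = freq_table.table
    x = np.asarray(mean_seeds, dtype=float)
    if len(x) != len(df):
        raise ValueError("one seed-production value per MLG required")
    keep = df["present_in_year1"].to_numpy() if restrict_to_year1 else np.ones(len(df), bool)
    if np.ptp(x[keep]) == 0:
        # constant seed production carries no signal: flat regression, not an error
        return GradientEstimate(
            kind="fitness_proxy", estimate=0.0, ci95=(0.0, 0.0), p_value=1.0,
            n_units=int(keep.sum()), method="degenerate_constant_regressor",
            meta={"restricted_to_year1": bool(restrict_to_year1)},
        )
    return _ols_gradient(
        x[keep],
        df["delta"].to_numpy()[keep],
        kind="fitness_proxy",
        meta={"restricted_to_year1": bool(restrict_to_year1)},
    )


def mlg_trait_values(
    pheno: PhenotypeTable,
    catalog_labels: dict[str, int],
    mlg_ids: np.ndarray,
    trait: str = "flowering_time",
    treatment: str | None = None,
) -> np.ndarray:
    """Genetic value per MLG: mean trait over member plants, by default in the
    named (short-vernalization) treatment.  ``catalog_labels`` maps family id
    (one genotyped plant per family) to MLG id."""
    df = pheno.cell(treatment=treatment)
    df = df[df["family"].isin(catalog_labels)]
    vals = df.assign(mlg=df["family"].map(catalog_labels)).groupby("mlg")[trait].mean()
    out = np.array([vals.get(int(m), np.nan) for m in mlg_ids])
    if np.isnan(out).any():
        raise ValueError("missing trait value for some MLGs")
    return out
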