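"""Thermal time, vernalization sensitivity, and mixed-model quantitative genetics.

The common-garden analysis: flowering dates converted to thermal time (degree
days above a base temperature), a linear mixed model with year and treatment as
fixed effects and block, block x year and family (nested in year x treatment)
as random effects, likelihood-ratio model simplification, and broad-sense
heritability H2 = VG/VP with a delete-one-family jackknife SE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

from .io import PhenotypeTable


# ---------------------------------------------------------------------------
# thermal time
# ---------------------------------------------------------------------------

def thermal_time(
    daily_temps: pd.Series, sowing_day: int, flower_day: int, t_base: float = 5.0
) -> float:
    """Degree.days accumulated between sowing and first flower.

    Sum over days in [sowing_day, flower_day) of max(0, mean temp - t_base);
    days with mean temperature below the base contribute zero (Bonhomme
    convention).  The default base temperature is 5 degrees C.
    """
    if flower_day < sowing_day:
        raise ValueError("flower_day before sowing_day")
    days = np.arange(sowing_day, flower_day)
    missing = [int(d) for d in days if d not in daily_temps.index]
    if missing:
        raise ValueError(f"temperature series has gaps at days {missing}")
    temps = daily_temps.loc[days].to_numpy(float) if len(days) else np.array([])
    return float(np.clip(temps - t_base, 0, None).sum())


def degree_days_to_days(dd: float, mean_temp: float = 15.0, t_base: float | None = None) -> float:
    """Display conversion of a degree.day difference into calendar days.

    Divides by the mean temperature (the study's footnote convention) or, if
    ``t_base`` is given, by the mean *effective* temperature (mean - base).
    """
    denom = mean_temp if t_base is None else mean_temp - t_base
    return dd / denom


# ---------------------------------------------------------------------------
# vernalization sensitivity
# ---------------------------------------------------------------------------

def vernalization_sensitivity(
    pheno: PhenotypeTable,
    treatments: tuple[str, str] = ("short", "long"),
    pairing: str = "mirrored",
    trait: str = "flowering_time",
) -> pd.DataFrame:
    """Per-individual-pair sensitivity to vernalization.

    Replicates of a family in the two treatments are paired by greenhouse
    position; the ``mirrored`` scheme pairs the first block of one treatment
    with the last of the other (block 1 with block 5, etc.).  The sensitivity
    of a pair is its treatment difference divided by the population mean
    difference (linear reaction norm assumption).
    """
    short, long_ = treatments
    df = pheno.data
    mean_short = df.loc[df["treatment"] == short, trait].mean()
    mean_long = df.loc[df["treatment"] == long_, trait].mean()
    denom = mean_long - mean_short
    if denom == 0 or np.isnan(denom):
        raise ValueError("population mean treatment difference is zero")
    blocks = sorted(df["block"].unique())
    if pairing == "mirrored":
        partner = dict(zip(blocks, blocks[::-1]))
    elif pairing == "aligned":
        partner = dict(zip(blocks, blocks))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    rows = []
    for (fam, year), sub in df.groupby(["family", "year"]):
        s = sub[sub["treatment"] == short].set_index("block")[trait]
        l = sub[sub["treatment"] == long_].set_index("block")[trait]
        for b in blocks:
            pb = partner[b]
            if b in s.index and pb in l.index:
                rows.append(
                    (fam, year, b, pb, float((l[pb] - s[b]) / denom))
                )
    return pd.DataFrame(
        rows, columns=["family", "year", "block_short", "block_long", "sensitivity"]
    )


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    formula: str
    fixed_effects: dict[str, float]
    varcomps: dict[str, float]
    resid_var: float
    loglike: float
    n_params: int
    method: str  # "reml" | "ml"
    converged: bool
    data: PhenotypeTable = field(repr=False, default=None)
    result: object = field(repr=False, default=None)

    @property
    def total_variance(self) -> float:
        return sum(self.varcomps.values()) + self.resid_var


def _dummies(codes: pd.Series) -> np.ndarray:
    return pd.get_dummies(codes.astype(str)).to_numpy(float)


def _vc_design(df: pd.DataFrame, formula: str, group_col: str) -> tuple[list[str], list]:
    names, mats = [], []

    def add(name: str, mat: np.ndarray) -> None:
        # degenerate designs (e.g. block x year with a single year) duplicate an
        # earlier component and make the likelihood non-identifiable: skip them
        for m in mats:
            if m.shape == mat.shape and np.array_equal(m, mat):
                return
        names.append(name)
        mats.append(mat)

    add("block", _dummies(df["treatment"] + ":" + df["block"]))
    add("block_year", _dummies(df["block"] + ":" + df["year"]))
    if formula == "eq1":
        for year in sorted(df["year"].unique()):
            for tr in sorted(df["treatment"].unique()):
                cell = (df["year"] == year) & (df["treatment"] == tr)
                mat = _dummies(df[group_col])
                mat[~cell.to_numpy(), :] = 0.0
                add(f"{group_col}_{year}_{tr}", mat)
    elif formula == "eq1_nonest":
        # family not nested in year (shared genetic variance across years)
        for tr in sorted(df["treatment"].unique()):
            cell = df["treatment"] == tr
            mat = _dummies(df[group_col])
            mat[~cell.to_numpy(), :] = 0.0
            add(f"{group_col}_{tr}", mat)
    elif formula == "eq1_notreat":
        # family nested in year only (no family x treatment interaction)
        for year in sorted(df["year"].unique()):
            cell = df["year"] == year
            mat = _dummies(df[group_col])
            mat[~cell.to_numpy(), :] = 0.0
            add(f"{group_col}_{year}", mat)
    elif formula == "eq3":
        add(group_col, _dummies(df[group_col]))
    else:
        raise ValueError(f"unknown formula {formula!r}")
    return names, mats


def _fixed_design(df: pd.DataFrame, formula: str, drop_fixed: tuple) -> tuple[list[str], np.ndarray]:
    cols = {"intercept": np.ones(len(df))}
    year = _dummies(df["year"])[:, 1:]  # reference coding
    if "year" not in drop_fixed:
        for i in range(year.shape[1]):
            cols[f"year[{sorted(df['year'].unique())[i + 1]}]"] = year[:, i]
    if formula.startswith("eq1"):
        treat = _dummies(df["treatment"])[:, 1:]
        if "treatment" not in drop_fixed:
            for i in range(treat.shape[1]):
                cols[f"treatment[{sorted(df['treatment'].unique())[i + 1]}]"] = treat[:, i]
        if "year:treatment" not in drop_fixed and "year" not in drop_fixed and "treatment" not in drop_fixed:
            k = 0
            for i in range(year.shape[1]):
                for j in range(treat.shape[1]):
                    cols[f"year:treatment[{k}]"] = year[:, i] * treat[:, j]
                    k += 1
    names = list(cols)
    return names, np.column_stack([cols[c] for c in names])


def fit_lmm(
    pheno: PhenotypeTable,
    formula: str = "eq1",
    trait: str = "flowering_time",
    method: str = "reml",
    group_col: str = "family",
    drop_fixed: tuple = (),
) -> LmmFit:
    """REML/ML fit of the flowering-time mixed model.

    ``eq1``: fixed year, treatment and their interaction; random block (nested
    in treatment), block x year, and family nested in year x treatment (four
    family variance components).  ``eq1_nonest`` / ``eq1_notreat`` are the
    reduced nestings used in the likelihood-ratio comparisons, and ``eq3`` is
    the regional model (random ``group_col`` instead of nested families).
    """
    df = pheno.data.dropna(subset=[trait]).reset_index(drop=True)
    y = df[trait].to_numpy(float)
    fx_names, X = _fixed_design(df, formula, drop_fixed)
    vc_names, mats = _vc_design(df, formula, group_col)
    spec = VCSpec(
        names=vc_names,
        colnames=[[f"{nm}{i}" for i in range(m.shape[1])] for nm, m in zip(vc_names, mats)],
        mats=[[m] for m in mats],
    )
    groups = np.zeros(len(df), dtype=int)
    model = MixedLM(y, X, groups=groups, exog_vc=spec)
    # no random intercept for the single umbrella group
    model.k_re = 0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=(method == "reml"), method=["powell", "nm"], maxiter=3000)
    fixed = dict(zip(fx_names, np.asarray(res.fe_params, float)))
    vcomps = {nm: float(res.vcomp[i]) for i, nm in enumerate(vc_names)}
    n_params = len(fx_names) + len(vc_names) + 1
    return LmmFit(
        formula=formula,
        fixed_effects=fixed,
        varcomps=vcomps,
        resid_var=float(res.scale),
        loglike=float(res.llf),
        n_params=n_params,
        method=method,
        converged=bool(res.converged),
        data=pheno,
        result=res,
    )


def lrt_compare(fit_full: LmmFit, fit_reduced: LmmFit) -> dict:
    """Likelihood-ratio test between two nested fits on the same data.

    Fixed-effect comparisons must use ML fits; REML likelihoods are comparable
    only when the fixed part is identical.
    """
    if fit_full.method != fit_reduced.method:
        raise ValueError("fits use different likelihood types")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    chi2 = max(0.0, 2.0 * (fit_full.loglike - fit_reduced.loglike))
    p = 1.0 if df == 0 and chi2 == 0 else float(stats.chi2.sf(chi2, max(df, 1)))
    if df == 0:
        p = 1.0 if chi2 == 0 else 0.0
    return {"chi2": float(chi2), "df": int(df), "p_value": p}


# ---------------------------------------------------------------------------
# per-cell variance components (Henderson moments) and heritability
# ---------------------------------------------------------------------------

def variance_components_cell(
    df: pd.DataFrame, trait: str = "flowering_time"
) -> dict[str, float]:
    """Moment (Henderson III) estimates of family, block and residual variance
    within one year x treatment cell.  Negative component estimates are
    truncated at zero."""
    df = df.dropna(subset=[trait])
    y = df[trait].to_numpy(float)
    fam = _dummies(df["family"])
    blk = _dummies(df["block"])
    N = len(y)
    F, B = fam.shape[1], blk.shape[1]

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    ones = np.ones((N, 1))
    X_full = np.column_stack([ones, fam[:, 1:], blk[:, 1:]])
    X_blk = np.column_stack([ones, blk[:, 1:]])
    X_fam = np.column_stack([ones, fam[:, 1:]])
    rank_full = np.linalg.matrix_rank(X_full)
    rss_full = rss(X_full)
    ve = rss_full / (N - rank_full)
    ms_fam = (rss(X_blk) - rss_full) / (F - 1)
    ms_blk = (rss(X_fam) - rss_full) / (B - 1)
    nf = fam.sum(axis=0)
    nb = blk.sum(axis=0)
    k_f = (N - (nf**2).sum() / N) / (F - 1)
    k_b = (N - (nb**2).sum() / N) / (B - 1)
    vg = max(0.0, (ms_fam - ve) / k_f)
    vb = max(0.0, (ms_blk - ve) / k_b)
    return {"family": float(vg), "block": float(vb), "residual": float(ve)}


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    year: str | None
    treatment: str | None
    components: dict[str, float]


def heritability(
    data: PhenotypeTable | LmmFit,
    year: str | None = None,
    treatment: str | None = None,
    trait: str = "flowering_time",
    jackknife: bool = True,
) -> HeritabilityEstimate:
    """Broad-sense heritability H2 = VG / (VG + Vblock + Vresidual) for one
    year x treatment cell, with a delete-one-family jackknife SE.

    Accepts either the phenotype table or an eq1 :class:`LmmFit` (whose data
    are reused); the jackknife always goes through the closed-form moment
    estimator so that resampling 50+ families stays cheap.
    """
    pheno = data.data if isinstance(data, LmmFit) else data
    cell = pheno.cell(year, treatment)
    if cell.empty:
        raise ValueError("empty year x treatment cell")

    def h2_of(df: pd.DataFrame) -> float:
        comp = variance_components_cell(df, trait)
        vp = comp["family"] + comp["block"] + comp["residual"]
        if vp == 0:
            raise ValueError("zero phenotypic variance")
        return comp["family"] / vp

    comp = variance_components_cell(cell, trait)
    point = h2_of(cell)
    se = float("nan")
    if jackknife:
        fams = cell["family"].unique()
        loo = np.array([h2_of(cell[cell["family"] != f]) for f in fams])
        F = len(fams)
        se = float(np.sqrt((F - 1) / F * ((loo - loo.mean()) ** 2).sum()))
    return HeritabilityEstimate(
        h2=float(point), se=se, year=year, treatment=treatment, components=comp
    )


def h2_from_components(vg: float, vblock: float, vresid: float) -> float:
    """H2 = VG / VP with VP = VG + Vblock + Vresidual."""
    vp = vg + vblock + vresid
    if vp <= 0:
        raise ValueError("zero phenotypic variance")
    return vg / vp
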