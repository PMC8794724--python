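"""Single-locus diversity summaries under the assumption of locus independence.

Expected heterozygosity (Nei's unbiased estimator), Hurlbert rarefied allelic
richness, the Weir & Cockerham within-population inbreeding coefficient FIS
with a bootstrap-over-loci confidence interval, between-year paired tests, and
an equilibrium selfing-rate proxy derived from FIS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import GenotypeMatrix


def _locus_year_calls(gm: GenotypeMatrix, year: str, locus: int) -> np.ndarray:
    calls = gm.calls[gm.year_array == str(year), locus, :]
    return calls[(calls > 0).all(axis=1)]


def expected_heterozygosity(
    gm: GenotypeMatrix, year: str, unbiased: bool = True
) -> pd.Series:
    """Per-locus expected heterozygosity He for one sampling year.

    Default is Nei's unbiased estimator (n/(n-1))(1 - sum p^2) with n the
    number of sampled gene copies; ``unbiased=False`` gives the plug-in
    1 - sum p^2.  Loci with fewer than two gene copies return NaN.
    """
    out = {}
    for j, locus in enumerate(gm.loci):
        calls = _locus_year_calls(gm, year, j)
        n = 2 * len(calls)
        if n < 2:
            out[locus] = np.nan
            continue
        _, counts = np.unique(calls.ravel(), return_counts=True)
        p = counts / n
        he = 1.0 - np.sum(p**2)
        if unbiased:
            he *= n / (n - 1)
        out[locus] = float(he)
    return pd.Series(out, name=f"He_{year}")


def _hurlbert(counts: np.ndarray, g: int) -> float:
    # sum_a [1 - C(N - N_a, g) / C(N, g)], computed on the log scale
    N = counts.sum()
    def logc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    terms = []
    for na in counts:
        if N - na < g:
            terms.append(1.0)
        else:
            terms.append(1.0 - np.exp(logc(N - na, g) - logc(N, g)))
    return float(np.sum(terms))


def rarefied_richness(gm: GenotypeMatrix, year: str, g: int | None = None) -> pd.Series:
    """Hurlbert rarefied allelic richness per locus at ``g`` gene copies.

    Default g is the smallest non-missing gene-copy count over all loci and
    all years (the ADZE convention), so values are comparable across years.
    """
    if g is None:
        g = min(
            2 * len(_locus_year_calls(gm, y, j))
            for y in gm.year_labels
            for j in range(gm.n_loci)
        )
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    out = {}
    for j, locus in enumerate(gm.loci):
        calls = _locus_year_calls(gm, year, j)
        if 2 * len(calls) < g:
            out[locus] = np.nan
            continue
        _, counts = np.unique(calls.ravel(), return_counts=True)
        out[locus] = _hurlbert(counts, g)
    return pd.Series(out, name=f"Na_rar_{year}")


def fis_components(gm: GenotypeMatrix, year: str) -> pd.DataFrame:
    """Per-locus Weir & Cockerham within-population variance components.

    For each allele with sample frequency p and heterozygote frequency h in a
    sample of n individuals:
        b = n/(n-1) * (p(1-p) - h(2n-1)/(4n))   between individuals
        c = h/2                                  within individuals
    FIS = 1 - sum(c) / sum(b + c), combined over alleles and loci.
    """
    rows = []
    for j, locus in enumerate(gm.loci):
        calls = _locus_year_calls(gm, year, j)
        n = len(calls)
        if n < 2:
            rows.append((locus, np.nan, np.nan))
            continue
        alleles = np.unique(calls.ravel())
        b_sum = c_sum = 0.0
        for a in alleles:
            carrier = calls == a
            p = carrier.mean()
            h = (carrier.sum(axis=1) == 1).mean()
            b_sum += n / (n - 1) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
            c_sum += h / 2
        rows.append((locus, b_sum, c_sum))
    return pd.DataFrame(rows, columns=["locus", "b", "c"]).set_index("locus")


def fis_estimate(
    gm: GenotypeMatrix,
    year: str,
    n_boot: int = 5000,
    seed: int | None = None,
) -> dict:
    """Multilocus FIS (ratio of summed variance components) with a percentile
    bootstrap-over-loci 95% CI.  With a single polymorphic locus the CI is
    returned as (nan, nan)."""
    comp = fis_components(gm, year).dropna()
    denom = (comp["b"] + comp["c"]).sum()
    if denom <= 0:
        raise ValueError("no within-year genetic variation; FIS undefined")
    point = 1.0 - comp["c"].sum() / denom
    poly = comp[(comp["b"] + comp["c"]) > 0]
    if len(poly) < 2 or n_boot < 1:
        ci = (float("nan"), float("nan"))
    else:
        rng = np.random.default_rng(seed)
        b = comp["b"].to_numpy()
        c = comp["c"].to_numpy()
        idx = rng.integers(0, len(comp), size=(n_boot, len(comp)))
        bs = b[idx].sum(axis=1)
        cs = c[idx].sum(axis=1)
        ok = (bs + cs) > 0
        vals = 1.0 - cs[ok] / (bs[ok] + cs[ok])
        ci = tuple(np.percentile(vals, [2.5, 97.5]).tolist())
    return {"fis": float(point), "ci95": ci, "n_loci": int(len(comp))}


def selfing_from_fis(fis: float) -> float:
    """Equilibrium selfing-rate proxy s = 2 FIS / (1 + FIS), clamped to [0, 1].

    At inbreeding equilibrium FIS = s/(2-s); this inverts that relation.  A
    crude stand-in for likelihood-based selfing estimation, which is out of
    scope here.
    """
    if fis <= -1:
        raise ValueError("FIS must exceed -1")
    return float(min(1.0, max(0.0, 2.0 * fis / (1.0 + fis))))


def compare_years(stat_year1: pd.Series, stat_year2: pd.Series) -> dict:
    """Wilcoxon signed-rank test of paired per-locus statistics between years
    (exact when feasible, two-sided)."""
    x = np.asarray(stat_year1, dtype=float)
    y = np.asarray(stat_year2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("per-locus vectors must share the locus list")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 paired loci")
    if np.allclose(x, y):
        return {"statistic": 0.0, "p_value": 1.0, "n": int(len(x))}
    res = stats.wilcoxon(x, y, zero_method="wilcox", method="auto")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n": int(len(x))}


def diversity_summary(
    gm: GenotypeMatrix, n_boot: int = 5000, seed: int | None = None
) -> dict:
    """Per-year diversity report: per-locus He and rarefied richness, FIS with
    bootstrap CI, selfing proxy, and between-year Wilcoxon comparisons."""
    years = gm.year_labels
    g = min(
        2 * len(_locus_year_calls(gm, y, j)) for y in years for j in range(gm.n_loci)
    )
    per_year = {}
    for y in years:
        he = expected_heterozygosity(gm, y)
        na = rarefied_richness(gm, y, g)
        fis = fis_estimate(gm, y, n_boot=n_boot, seed=seed)
        per_year[y] = {
            "He": he,
            "Na_rar": na,
            "fis": fis,
            "selfing_proxy": selfing_from_fis(fis["fis"]),
        }
    out = {"per_year": per_year, "rarefaction_g": g}
    if len(years) == 2:
        y1, y2 = years
        out["tests"] = {
            "He": compare_years(per_year[y1]["He"], per_year[y2]["He"]),
            "Na_rar": compare_years(per_year[y1]["Na_rar"], per_year[y2]["Na_rar"]),
        }
    return out
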