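import numpy as np
import pandas as pd
import pytest

from selfpop.io import GenotypeMatrix, PhenotypeTable


def make_gm(calls, years=None, loci=None):
    """Build a GenotypeMatrix from a (n, L, 2) array-like of calls."""
    calls = np.asarray(calls, dtype=int)
    n, L, _ = calls.shape
    individuals = [f"I{i:02d}" for i in range(n)]
    if years is None:
        years = ["1987" if i < n // 2 else "2009" for i in range(n)]
    return GenotypeMatrix(
        individuals=individuals,
        years=dict(zip(individuals, map(str, years))),
        loci=loci or [f"L{j:02d}" for j in range(L)],
        calls=calls,
    )


def homozygous_gm(allele_rows, years=None):
    """GenotypeMatrix of fully homozygous individuals from an (n, L) allele array."""
    a = np.asarray(allele_rows, dtype=int)
    return make_gm(np.repeat(a[:, :, None], 2, axis=2), years=years)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_year_gm(rng):
    """Random two-year diploid matrix, 20 individuals x 6 loci, no missing data."""
    calls = np.sort(rng.integers(1, 6, size=(20, 6, 2)), axis=2)
    return make_gm(calls)


def make_pheno(n_families=12, n_blocks=5, treatments=("short", "long"), seed=0,
               vg=2000.0, vblock=100.0, vres=1000.0, years=("1987",), seeds_col=True):
    rng = np.random.default_rng(seed)
    rows, pid = [], 0
    fam_per_year = max(1, n_families // len(years))
    for fi in range(n_families):
        year = years[min(fi // fam_per_year, len(years) - 1)]
        g = rng.normal(900, np.sqrt(vg))
        for tr_i, tr in enumerate(treatments):
            for b in range(n_blocks):
                ft = g - 150 * tr_i + rng.normal(0, np.sqrt(vblock + vres))
                rows.append(
                    dict(plant=f"P{pid:04d}", family=f"F{fi:03d}", year=year,
                         treatment=tr, block=f"B{b + 1}", flowering_time=ft,
                         seeds=(max(0.0, 200 - 0.3 * (ft - 900) + rng.normal(0, 30))
                                if seeds_col else np.nan))
                )
                pid += 1
    return PhenotypeTable(pd.DataFrame(rows))
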