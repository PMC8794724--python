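"""Synthetic data with the statistical structure the analysis pipeline assumes.

Three generators:

* :func:`simulate_population` — an individual-based forward simulator of a
  predominantly selfing annual: divergent fully homozygous founder MLGs at
  unequal frequencies, fertility selection on a flowering-time genetic value,
  partial selfing, microsatellite mutation (KAM), and two temporal samples.
* :func:`simulate_temporal_drift` — the idealized independent-locus drift model
  behind the temporal-FST -> Ne inversion: a population of effective size
  ``ne`` diploid selfers is (1 + FIS) * ne independent selfing lineages whose
  frequencies drift multinomially.
* :func:`generate_experiment` — the greenhouse design (families x treatments x
  blocks) with planted variance components or a planted heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PhenotypeTable
from .mlg import FrequencyChangeTable


@dataclass
class SimConfig:
    n_census: int = 300
    ne_target: float | None = None  # diploid Ne < census via offspring-number variance
    selfing_rate: float = 1.0
    n_loci: int = 16
    n_founders: int = 12
    k_alleles: int = 10
    mu: float = 5e-4  # per allele per generation, within the microsatellite range
    t_generations: int = 22
    trait_mean: float = 900.0  # degree.days
    trait_sd: float = 75.0
    selection_coef: float = 0.0  # linear fitness-trait coefficient per degree.day
    sample_sizes: tuple[int, int] = (64, 81)
    year_labels: tuple[str, str] = ("1987", "2009")
    founder_alpha: float = 0.5  # Dirichlet concentration: small -> dominant MLGs
    # per-locus allele-frequency skew among founders; 0.4 gives locus He ~ 0.4-0.6,
    # the range observed for microsatellites in highly selfing populations
    founder_allele_alpha: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.selfing_rate <= 1:
            raise ValueError("selfing_rate must lie in [0, 1]")
        if max(self.sample_sizes) > self.n_census:
            raise ValueError("sample sizes must not exceed the census size")

    @property
    def fis_equilibrium(self) -> float:
        s = self.selfing_rate
        return s / (2.0 - s)

    @property
    def ne(self) -> float:
        """Diploid effective size: the target if set, else census/(1+FIS)."""
        if self.ne_target is not None:
            return float(self.ne_target)
        return self.n_census / (1.0 + self.fis_equilibrium)

    @property
    def _dirichlet_conc(self) -> float | None:
        """Concentration of the per-generation fertility Dirichlet that makes
        the lineage-effective number of parents equal (1+FIS)*ne_target.

        For Dirichlet-multinomial offspring numbers the effective trial count
        is N(1+c)/(N+c); solving for c targets M = (1+FIS)*ne lineages.
        """
        if self.ne_target is None:
            return None
        M = (1.0 + self.fis_equilibrium) * self.ne_target
        N = self.n_census
        if not 1 < M < N:
            raise ValueError("ne_target must satisfy 1 < (1+FIS)*ne < n_census")
        return N * (M - 1.0) / (N - M)


@dataclass
class GroundTruth:
    ne: float
    selfing_rate: float
    founder_traits: np.ndarray
    selection_coef: float
    lineage_freqs: np.ndarray  # (t+1, n_founders) founder-lineage trajectory
    sample_lineages: dict[str, np.ndarray] = field(default_factory=dict)


def _gametes(geno: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    n, L = len(parents), geno.shape[1]
    pick = rng.integers(0, 2, size=(n, L))
    return np.take_along_axis(geno[parents], pick[:, :, None], axis=2)[:, :, 0]


def simulate_population(cfg: SimConfig) -> dict:
    """Forward-simulate the population and return the two temporal samples.

    Fitness acts on the probability of being drawn as a parent (fertility
    selection): w = max(0, 1 + coef * (trait - mean trait)).  Generations are
    non-overlapping and there is no seed bank.
    """
    rng = np.random.default_rng(cfg.seed)
    N, L, k = cfg.n_census, cfg.n_loci, cfg.k_alleles

    # skewed per-locus allele spectra: each locus has its own founder allele
    # frequencies drawn from a Dirichlet, so locus He matches field microsats
    founder_alleles = np.empty((cfg.n_founders, L), dtype=int)
    for j in range(L):
        q = rng.dirichlet(np.full(k, cfg.founder_allele_alpha))
        founder_alleles[:, j] = rng.choice(np.arange(1, k + 1), size=cfg.n_founders, p=q)
    founder_traits = rng.normal(cfg.trait_mean, cfg.trait_sd, size=cfg.n_founders)
    p0 = rng.dirichlet(np.full(cfg.n_founders, cfg.founder_alpha))
    lineage = rng.choice(cfg.n_founders, size=N, p=p0)
    geno = np.repeat(founder_alleles[lineage][:, :, None], 2, axis=2)
    trait = founder_traits[lineage]
    next_lineage_id = cfg.n_founders

    traj = np.zeros((cfg.t_generations + 1, cfg.n_founders))

    def record(gen: int) -> None:
        for f in range(cfg.n_founders):
            traj[gen, f] = (lineage == f).mean()

    record(0)
    n1, n2 = cfg.sample_sizes
    idx1 = rng.choice(N, size=n1, replace=False)
    sample1 = geno[idx1].copy()
    lin1 = lineage[idx1].copy()

    for gen in range(cfg.t_generations):
        w = np.clip(1.0 + cfg.selection_coef * (trait - trait.mean()), 0.0, None)
        if w.sum() == 0:
            raise RuntimeError("all fitnesses zero: population extinct (retry with a new seed)")
        prob = w / w.sum()
        conc = cfg._dirichlet_conc
        if conc is not None:
            # overdispersed fertility: census stays N but drift runs at ne_target
            prob = rng.dirichlet(conc * prob)
        p1 = rng.choice(N, size=N, p=prob)
        selfed = rng.random(N) < cfg.selfing_rate
        p2 = np.where(selfed, p1, rng.choice(N, size=N, p=prob))
        g1 = _gametes(geno, p1, rng)
        g2 = _gametes(geno, p2, rng)
        geno = np.stack([g1, g2], axis=2)
        trait = (trait[p1] + trait[p2]) / 2.0
        new_lineage = np.where(
            selfed & (lineage[p1] == lineage[p2]), lineage[p1], -1
        )
        outx = new_lineage == -1
        if outx.any():
            new_lineage[outx] = next_lineage_id + np.arange(outx.sum())
            next_lineage_id += int(outx.sum())
        lineage = new_lineage
        if cfg.mu > 0:
            mut = rng.random(geno.shape) < cfg.mu
            if mut.any():
                shift = rng.integers(1, k, size=int(mut.sum()))
                geno[mut] = 1 + (geno[mut] - 1 + shift) % k
                lineage[mut.any(axis=(1, 2))] = -1
        geno = np.sort(geno, axis=2)
        record(gen + 1)

    idx2 = rng.choice(N, size=n2, replace=False)
    sample2 = geno[idx2].copy()
    lin2 = lineage[idx2].copy()

    y1, y2 = cfg.year_labels
    individuals = [f"{y1}_{i:03d}" for i in range(n1)] + [f"{y2}_{i:03d}" for i in range(n2)]
    years = {ind: (y1 if i < n1 else y2) for i, ind in enumerate(individuals)}
    gm = GenotypeMatrix(
        individuals=individuals,
        years=years,
        loci=[f"L{j:02d}" for j in range(L)],
        calls=np.concatenate([sample1, sample2]),
    )
    truth = GroundTruth(
        ne=cfg.ne,
        selfing_rate=cfg.selfing_rate,
        founder_traits=founder_traits,
        selection_coef=cfg.selection_coef,
        lineage_freqs=traj,
        sample_lineages={y1: lin1, y2: lin2},
    )
    return {"genotypes": gm, "truth": truth, "config": cfg}


def simulate_temporal_drift(
    ne: float,
    n_loci: int = 16,
    t: int = 22,
    sample_sizes: tuple[int, int] = (64, 81),
    fis: float = 1.0,
    k_alleles: int = 5,
    alpha: float = 1.0,
    year_labels: tuple[str, str] = ("1987", "2009"),
    seed: int | None = None,
) -> GenotypeMatrix:
    """Idealized neutral temporal data: loci drift independently.

    A diploid effective size ``ne`` under inbreeding coefficient ``fis``
    corresponds to M = (1 + fis) * ne independent selfing lineages; each locus
    starts at Dirichlet(alpha) frequencies over ``k_alleles`` alleles and
    drifts as Multinomial(M) for ``t`` generations.  Samples of fully
    homozygous individuals are drawn at generations 0 and t.
    """
    rng = np.random.default_rng(seed)
    M = int(round((1.0 + fis) * ne))
    n1, n2 = sample_sizes
    calls = np.zeros((n1 + n2, n_loci, 2), dtype=int)
    for j in range(n_loci):
        p = rng.dirichlet(np.full(k_alleles, alpha))
        c1 = rng.multinomial(n1, p)
        alleles1 = np.repeat(np.arange(1, k_alleles + 1), c1)
        rng.shuffle(alleles1)
        for _ in range(t):
            p = rng.multinomial(M, p) / M
        c2 = rng.multinomial(n2, p)
        alleles2 = np.repeat(np.arange(1, k_alleles + 1), c2)
        rng.shuffle(alleles2)
        col = np.concatenate([alleles1, alleles2])
        calls[:, j, 0] = col
        calls[:, j, 1] = col
    y1, y2 = year_labels
    individuals = [f"{y1}_{i:03d}" for i in range(n1)] + [f"{y2}_{i:03d}" for i in range(n2)]
    years = {ind: (y1 if i < n1 else y2) for i, ind in enumerate(individuals)}
    return GenotypeMatrix(
        individuals=individuals,
        years=years,
        loci=[f"L{j:02d}" for j in range(n_loci)],
        calls=calls,
    )


def simulate_mlg_dynamics(
    init_freqs: np.ndarray,
    traits: np.ndarray,
    coef: float,
    n_lineages: int,
    t: int,
    sample_sizes: tuple[int, int],
    seed: int | None = None,
) -> FrequencyChangeTable:
    """Superlocus MLG dynamics with optional linear fertility selection,
    returning the observed two-sample frequency-change table."""
    rng = np.random.default_rng(seed)
    p = np.asarray(init_freqs, float)
    p = p / p.sum()
    n1, n2 = sample_sizes
    counts1 = rng.multinomial(n1, p)
    for _ in range(t):
        w = np.clip(1.0 + coef * (traits - np.average(traits, weights=p)), 0.0, None)
        q = p * w
        q = q / q.sum()
        p = rng.multinomial(n_lineages, q) / n_lineages
    counts2 = rng.multinomial(n2, p)
    return freq_table_from_counts(counts1, counts2)


def freq_table_from_counts(
    counts1: np.ndarray,
    counts2: np.ndarray,
    year1: str = "1987",
    year2: str = "2009",
) -> FrequencyChangeTable:
    """Assemble a FrequencyChangeTable directly from per-MLG sample counts."""
    c1 = np.asarray(counts1, int)
    c2 = np.asarray(counts2, int)
    n1, n2 = int(c1.sum()), int(c2.sum())
    df = pd.DataFrame(
        {
            "mlg": np.arange(len(c1)),
            "count1": c1,
            "count2": c2,
            "freq1": c1 / n1,
            "freq2": c2 / n2,
        }
    )
    df["delta"] = df["freq2"] - df["freq1"]
    df["present_in_year1"] = df["count1"] > 0
    return FrequencyChangeTable(
        table=df,
        year1=year1,
        year2=year2,
        n_year1=n1,
        n_year2=n2,
        homozygous_only=True,
        restricted_to_year1=False,
    )


# ---------------------------------------------------------------------------
# greenhouse experiment
# ---------------------------------------------------------------------------

def generate_temperature_series(
    n_days: int = 250, mean: float = 15.0, amplitude: float = 5.0, noise_sd: float = 1.5,
    seed: int | None = None,
) -> pd.Series:
    rng = np.random.default_rng(seed)
    days = np.arange(n_days)
    temps = mean + amplitude * np.sin(2 * np.pi * days / 365.0) + rng.normal(0, noise_sd, n_days)
    return pd.Series(temps, index=days)


def generate_experiment(
    family_values: pd.DataFrame | None = None,
    n_families: int = 110,
    n_blocks: int = 5,
    treatments: tuple[str, str] = ("short", "long"),
    treatment_effect: float = -162.84,
    vg: float | None = None,
    vblock: float = 90.0,
    vres: float | None = None,
    h2_plot: float | None = None,
    trait_mean: float = 900.0,
    seed_base: float = 200.0,
    seed_slope: float = -0.3,
    seed_sd: float = 60.0,
    year_labels: tuple[str, str] = ("1987", "2009"),
    seed: int | None = None,
) -> PhenotypeTable:
    """Simulate the greenhouse design: families x 2 treatments x blocks.

    Family genetic values are either supplied (``family_values`` with columns
    family, year, gvalue) or drawn with variance ``vg``.  The residual
    variance is either explicit (``vres``) or scaled so the within-cell
    heritability VG/(VG + Vblock + Vres) equals ``h2_plot``.  Seed production
    declines linearly with flowering time (late flowering is penalized).
    """
    rng = np.random.default_rng(seed)
    if family_values is None:
        if vg is None:
            vg = 3000.0
        half = n_families // 2
        fams = [f"F{i:03d}" for i in range(n_families)]
        years = [year_labels[0]] * half + [year_labels[1]] * (n_families - half)
        gvals = rng.normal(trait_mean, np.sqrt(vg), n_families)
        family_values = pd.DataFrame({"family": fams, "year": years, "gvalue": gvals})
    else:
        vg = float(np.var(family_values["gvalue"], ddof=1)) if vg is None else vg
    if vres is None:
        if h2_plot is None:
            vres = 1500.0
        else:
            if not 0 < h2_plot < 1:
                raise ValueError("h2_plot must lie in (0, 1)")
            vres = vg * (1 - h2_plot) / h2_plot - vblock
            if vres <= 0:
                raise ValueError("h2_plot too high for the given block variance")
    blocks = [f"B{b + 1}" for b in range(n_blocks)]
    block_eff = rng.normal(0, np.sqrt(vblock), n_blocks)
    rows = []
    pid = 0
    for rec in family_values.itertuples(index=False):
        for tr_i, tr in enumerate(treatments):
            for b_i, b in enumerate(blocks):
                ft = (
                    rec.gvalue
                    + (treatment_effect if tr_i == 1 else 0.0)
                    + block_eff[b_i]
                    + rng.normal(0, np.sqrt(vres))
                )
                seeds = max(
                    0.0,
                    seed_base + seed_slope * (ft - trait_mean) + rng.normal(0, seed_sd),
                )
                rows.append(
                    {
                        "plant": f"P{pid:05d}",
                        "family": rec.family,
                        "year": rec.year,
                        "treatment": tr,
                        "block": b,
                        "flowering_time": max(0.0, ft),
                        "seeds": round(seeds),
                    }
                )
                pid += 1
    return PhenotypeTable(pd.DataFrame(rows))


def simulate_family_design(
    n_families: int = 55,
    n_blocks: int = 5,
    vg: float = 3000.0,
    vblock: float = 90.0,
    vres: float = 1500.0,
    mu: float = 900.0,
    year: str = "1987",
    treatment: str = "short",
    seed: int | None = None,
) -> PhenotypeTable:
    """One year x treatment cell with planted variance components (balanced:
    one plant per family per block)."""
    rng = np.random.default_rng(seed)
    fam_eff = rng.normal(0, np.sqrt(vg), n_families)
    blk_eff = rng.normal(0, np.sqrt(vblock), n_blocks)
    rows = []
    pid = 0
    for f in range(n_families):
        for b in range(n_blocks):
            y = mu + fam_eff[f] + blk_eff[b] + rng.normal(0, np.sqrt(vres))
            rows.append(
                {
                    "plant": f"P{pid:05d}",
                    "family": f"F{f:03d}",
                    "year": year,
                    "treatment": treatment,
                    "block": f"B{b + 1}",
                    "flowering_time": y,
                    "seeds": np.nan,
                }
            )
            pid += 1
    return PhenotypeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str, seed: int = 0) -> dict:
    """Deterministic seeded datasets used across the test suite.

    ``tiny_clones``: 20 individuals from 3 clonal MLGs with one injected
    mis-read locus.  ``drift_null``: a pure-drift frequency-change table plus
    unrelated trait values.  ``selected``: MLG dynamics with a planted
    negative fitness-trait coupling.  ``biased_superlocus``: one fully selfing
    neutral forward replicate for locus-wise vs superlocus FST comparison.
    """
    rng = np.random.default_rng(seed)
    if name == "tiny_clones":
        L, k = 16, 8
        clones = rng.integers(1, k + 1, size=(3, L))
        labels = np.repeat([0, 1, 2], [8, 7, 5])
        calls = np.repeat(clones[labels][:, :, None], 2, axis=2)
        calls[0, 3, :] = (clones[0, 3] % k) + 1  # one mis-read locus
        individuals = [f"I{i:02d}" for i in range(20)]
        years = {ind: ("1987" if i % 2 == 0 else "2009") for i, ind in enumerate(individuals)}
        gm = GenotypeMatrix(individuals, years, [f"L{j:02d}" for j in range(L)], calls)
        return {"genotypes": gm, "true_labels": labels}
    if name == "drift_null":
        k, ne, t = 10, 19, 22
        init = rng.dirichlet(np.full(k, 0.6))
        traits = rng.normal(900, 75, k)
        ft = simulate_mlg_dynamics(init, traits, 0.0, ne, t, (58, 75), seed=seed + 1)
        return {"freq_table": ft, "traits": traits, "ne": ne, "t": t}
    if name == "selected":
        k, ne, t = 30, 100, 22
        init = np.full(k, 1.0 / k)
        traits = rng.normal(900, 75, k)
        ft = simulate_mlg_dynamics(init, traits, -0.004, ne, t, (58, 75), seed=seed + 1)
        return {"freq_table": ft, "traits": traits, "ne": ne, "t": t, "coef": -0.004}
    if name == "biased_superlocus":
        cfg = SimConfig(n_census=200, selfing_rate=1.0, mu=0.0, seed=seed)
        return simulate_population(cfg)
    raise ValueError(f"unknown fixture {name!r}")
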