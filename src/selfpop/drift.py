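"""Multinomial drift simulation and the MLG-frequency neutrality test.

The null model: under complete selfing the whole genome behaves as a single
superlocus, so the vector of MLG frequencies drifts as a Wright-Fisher
multinomial with Ne trials per generation (one lineage per selfing
individual), one generation per year and no seed bank.  After t generations a
final sample of individuals is drawn, the change in simulated MLG frequencies
is regressed on the MLG genetic values for flowering time, and the observed
selection-gradient slope is compared with the simulated null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .mlg import FrequencyChangeTable


@dataclass
class DriftConfig:
    ne: int
    t: int = 22
    n_reps: int = 10_000
    n_sample_final: int = 75
    init_mode: str = "sample_year1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.t < 1 or self.n_reps < 1:
            raise ValueError("t and n_reps must be >= 1")


def simulate_drift(
    init_freqs: np.ndarray, cfg: DriftConfig, presample: bool = False
) -> np.ndarray:
    """Simulate ``cfg.n_reps`` drift trajectories of a frequency vector.

    Each generation draws counts ~ Multinomial(ne, current frequencies); after
    ``t`` generations a final sample of ``n_sample_final`` individuals is
    drawn.  Returns the (n_reps, k) matrix of final sample frequencies, or the
    pre-sampling population frequencies when ``presample`` is True.
    """
    p0 = np.asarray(init_freqs, dtype=float)
    if (p0 < 0).any() or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial frequencies must be non-negative and sum to 1")
    rng = np.random.default_rng(cfg.seed)
    freqs = np.tile(p0, (cfg.n_reps, 1))
    for _ in range(cfg.t):
        counts = rng.multinomial(cfg.ne, freqs)
        freqs = counts / cfg.ne
    if presample:
        return freqs
    sample = rng.multinomial(cfg.n_sample_final, freqs)
    return sample / cfg.n_sample_final


def initialize_frequencies(
    freq_table: FrequencyChangeTable,
    mode: str = "sample_year1",
    epsilon: float | None = None,
) -> np.ndarray:
    """Starting frequency vector for the drift simulation.

    ``sample_year1``: observed first-year sample frequencies (MLGs unseen in
    year 1 start, and stay, at zero).  ``pooled``: combined two-year counts.
    ``floor``: year-1 frequencies with ``epsilon`` (default 1/(2 n_year1))
    added to zero-count MLGs, then renormalised — lets year-2-only MLGs drift.
    """
    df = freq_table.table
    if mode == "sample_year1":
        p = df["freq1"].to_numpy(float)
    elif mode == "pooled":
        tot = (df["count1"] + df["count2"]).to_numpy(float)
        p = tot / tot.sum()
    elif mode == "floor":
        eps = 1.0 / (2 * freq_table.n_year1) if epsilon is None else epsilon
        p = df["freq1"].to_numpy(float).copy()
        p[p == 0] = eps
        p = p / p.sum()
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    if p.sum() == 0:
        raise ValueError("all-zero initial frequency vector")
    return p / p.sum()


def _ols_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS slope of each row of y on x (closed form)."""
    xc = x - x.mean()
    sxx = (xc**2).sum()
    if sxx == 0:
        raise ValueError("zero trait variance: slope undefined")
    return (y @ xc) / sxx


def null_slope_distribution(
    sim_final_freqs: np.ndarray,
    init_freqs: np.ndarray,
    trait_values: np.ndarray,
) -> np.ndarray:
    """Per-replicate OLS slope of simulated frequency change on trait value."""
    x = np.asarray(trait_values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 MLGs")
    deltas = np.asarray(sim_final_freqs) - np.asarray(init_freqs)
    return _ols_slopes(x, deltas)


def drift_pvalue(
    observed_slope: float, null_slopes: np.ndarray, alternative: str = "lesser"
) -> float:
    """Permutation-convention p-value of the observed slope against the null.

    ``lesser`` (default): a more negative slope is more extreme,
    p = (#{null <= observed} + 1)/(n + 1).  ``greater`` and ``two_sided`` are
    also available.
    """
    null = np.asarray(null_slopes, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    n = null.size
    p_less = ((null <= observed_slope).sum() + 1) / (n + 1)
    p_greater = ((null >= observed_slope).sum() + 1) / (n + 1)
    if alternative == "lesser":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "two_sided":
        return float(min(1.0, 2 * min(p_less, p_greater)))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class DriftTestResult:
    observed_slope: float
    null_slopes: np.ndarray
    p_value: float
    alternative: str
    config: DriftConfig

    def to_dict(self) -> dict:
        return {
            "observed_slope": self.observed_slope,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "ne": self.config.ne,
            "t": self.config.t,
            "n_reps": self.config.n_reps,
            "n_sample_final": self.config.n_sample_final,
            "init_mode": self.config.init_mode,
            "seed": self.config.seed,
        }


class DriftNeutralityTest(BaseEstimator):
    """Test whether observed MLG frequency changes exceed pure-drift expectation.

    ``fit(freq_table, trait_values)`` computes the observed selection-gradient
    slope (frequency change on MLG mean flowering time), simulates the null
    slope distribution under multinomial drift at ``ne``, and stores
    ``observed_slope_``, ``null_slopes_``, ``p_value_`` and ``result_``.
    """

    def __init__(
        self,
        ne: int = 19,
        t: int = 22,
        n_reps: int = 10_000,
        n_sample_final: int = 75,
        init_mode: str = "sample_year1",
        alternative: str = "lesser",
        random_state: int | None = None,
    ):
        self.ne = ne
        self.t = t
        self.n_reps = n_reps
        self.n_sample_final = n_sample_final
        self.init_mode = init_mode
        self.alternative = alternative
        self.random_state = random_state

    def fit(
        self, freq_table: FrequencyChangeTable, trait_values: np.ndarray
    ) -> "DriftNeutralityTest":
        cfg = DriftConfig(
            ne=self.ne,
            t=self.t,
            n_reps=self.n_reps,
            n_sample_final=self.n_sample_final,
            init_mode=self.init_mode,
            seed=self.random_state,
        )
        x = np.asarray(trait_values, dtype=float)
        if len(x) != len(freq_table.table):
            raise ValueError("one trait value per MLG required")
        init = initialize_frequencies(freq_table, cfg.init_mode)
        observed = float(_ols_slopes(x, freq_table.deltas[None, :])[0])
        finals = simulate_drift(init, cfg)
        null = null_slope_distribution(finals, init, x)
        p = drift_pvalue(observed, null, self.alternative)
        self.observed_slope_ = observed
        self.null_slopes_ = null
        self.p_value_ = p
        self.result_ = DriftTestResult(observed, null, p, self.alternative, cfg)
        return self


@dataclass
class NeSensitivityCurve:
    grid: np.ndarray
    p_values: np.ndarray
    threshold_ne: float | None  # smallest grid ne with p < 0.05
    table: pd.DataFrame = field(repr=False, default=None)


def ne_sensitivity(
    freq_table: FrequencyChangeTable,
    trait_values: np.ndarray,
    ne_grid: np.ndarray,
    t: int = 22,
    n_reps: int = 10_000,
    n_sample_final: int = 75,
    init_mode: str = "sample_year1",
    alternative: str = "lesser",
    seed: int | None = None,
) -> NeSensitivityCurve:
    """Re-run the neutrality test over a grid of assumed effective sizes
    (the study scanned 10 <= Ne <= 500) with independent per-grid-point seeds."""
    grid = np.sort(np.asarray(ne_grid, dtype=int))
    if grid.size == 0:
        raise ValueError("empty ne grid")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid))
    ps = []
    for ne, child in zip(grid, children):
        test = DriftNeutralityTest(
            ne=int(ne),
            t=t,
            n_reps=n_reps,
            n_sample_final=n_sample_final,
            init_mode=init_mode,
            alternative=alternative,
            random_state=int(child.generate_state(1)[0] % (2**31)),
        ).fit(freq_table, trait_values)
        ps.append(test.p_value_)
    ps = np.array(ps)
    below = grid[ps < 0.05]
    return NeSensitivityCurve(
        grid=grid,
        p_values=ps,
        threshold_ne=float(below[0]) if below.size else None,
        table=pd.DataFrame({"ne": grid, "p_value": ps}),
    )
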