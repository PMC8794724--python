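# Methods notes

This note records the models, numerical choices and known limitations behind
`selfpop`, in the order the pipeline runs. It states no empirical result that
the test suite does not itself compute.

## Data model and filtering

Genotypes are unordered pairs of positive integer allele labels (fragment
sizes); `(0, 0)` is the missing sentinel, and a half-missing call is coerced
to missing. Filtering is applied in a fixed, documented order — loci with a
missing fraction strictly above the threshold (default 0.10), then
individuals over the same threshold computed on the kept loci, then
monomorphic loci — and the `FilterReport` records every removal with its
reason so an alternative ordering can be audited. "Strictly above" means a
locus at exactly 10% missing is kept. Filtering is idempotent.

## MLG cataloguing

Individuals with complete data are merged by single-linkage connected
components whenever their pairwise mismatch fraction (compared loci only; any
difference of unordered pairs is one mismatch, no half-scores) is ≤ the error
tolerance. Single linkage is the most permissive reading of "differ by less
than the error rate" and matches the merge-one-step-neighbours intent; the
tolerance is ≤ rather than < so that 1/16 merges exactly one mis-read locus
on a 16-locus panel. Individuals with missing data are then assigned in a
seed-shuffled order: one compatible group → that group; several → a random
draw with probability proportional to the group's *current* size (sizes and
majority-rule consensus genotypes are updated after each assignment); none →
a new singleton. Only these ambiguous assignments depend on the seed.
Consensus ties are broken toward the smallest allele pair, which makes the
catalogue deterministic given the seed.

The distance spectrum between MLG consensus genotypes is the diagnostic for
choosing the tolerance: genotyping errors produce an excess of distance-1
pairs that disappears when re-clustering at 1/16. A recombinant-candidate
triad is reported when allele-difference distances are exactly additive,
d(A,C) + d(C,B) = d(A,B), with both legs positive, distances computed on loci
scored in all three genotypes.

Frequency-change tables by default keep fully homozygous MLGs only and
renormalize within year (the residually heterozygous MLGs are excluded from
the selection analyses, and renormalization is the configurable default since
the original bookkeeping is not published). "Change" is the signed
difference freq(year2) − freq(year1): negative regression slopes are only
meaningful for signed changes.

## Diversity

H_e uses Nei's unbiased estimator (n/(n−1))(1 − Σp²) on gene copies
(switchable to the plug-in form); rarefied richness follows Hurlbert's
exact hypergeometric expectation at g gene copies, with g defaulting to the
smallest non-missing count over loci and years. F_IS comes from the
Weir–Cockerham within-population variance components, combined over alleles
and loci as a ratio of sums; its CI is a percentile bootstrap over loci
(the construction is not published beyond "bootstraps over loci"). The
selfing proxy s = 2F/(1+F) is the inbreeding-equilibrium inversion and is
only a proxy — likelihood-based selfing estimation from multilocus
heterozygosity is out of scope.

## Temporal F_ST and N_e

The two temporal samples are treated as the two "populations" of the
Weir–Cockerham (1984) multiallelic θ, with the heterozygosity terms retained
so that selfed (mostly homozygous) samples are handled correctly; loci are
combined as ratio-of-sums of variance components. The effective size in
diploid individuals inverts

    E[F_ST] = t / (t + 2 N_raw),   N_e = N_raw / (1 + F_IS_eff),

with F_IS_eff = 1 by default (complete selfing). This calibrated mapping —
no sample-size correction term — reproduces the published anchor values of
the study system it was built around (F = 0.226, t = 22 → N_e ≈ 18.8 → 19;
CI 0.182–0.269 → 15–25; superlocus F = 0.075 → 136 with no selfing divisor).
The upper equilibrium-H_e bound printed in that study back-computes from
N_e ≈ 19.3; this mapping's unrounded 18.84 gives 0.131 rather than 0.134 at
μ = 2×10⁻³, while the low-μ value (0.004) is insensitive to the difference.
Consistently, a simulated "population of effective size N_e" under complete
selfing must carry (1 + F_IS)·N_e = 2N_e independent selfing lineages
(Pollak's N_e = N/(1+F_IS)); the synthetic generators use that convention.

CIs for F_ST resample loci: either percentile or the approximate bootstrap
confidence (ABC) construction on the weighted ratio-of-sums statistic (our
implementation agrees with R's `boot::abc.ci` to ~8 decimals). N_e bounds map
the F_ST bounds through the (decreasing) inversion. **Known limitation:** with
only 16 loci, both ABC and percentile intervals undercover — measured ≈ 0.89
coverage at nominal 0.95 over 200 simulated replicates — because the
between-locus sample is small and the component distribution skewed; the
point estimate and its median behaviour are unaffected (median recovery
within a few percent at N_e = 25/50/100).

### Superlocus F_ST

Concatenating all loci treats each fully homozygous MLG as one allele of a
single locus. Two estimators are provided. The default applies the same
Weir–Cockerham θ, which makes the value directly comparable with the
locus-wise combination; in our simulations this estimator is nearly invariant
to the allele/haplotype granularity, so it shows **no** systematic downward
bias. The `estimator="nei"` variant is the heterozygosity-based haplotype
F_ST, (H_T − H_S)/H_T on MLG frequencies; because its range is bounded by
roughly 1 − H_S it is strongly downward biased whenever MLG diversity is high
(dozens of mostly rare MLGs in samples of ~70), which is the documented
behaviour of diversity-dependent F_ST measures. The bias property test uses
the nei variant against the locus-wise θ; neither superlocus value should be
inverted into an effective size.

## Drift neutrality test

The null model assumes complete selfing (whole genome = one superlocus), one
generation per year, no seed bank: MLG frequencies evolve by
counts ~ Multinomial(N_e, p) per generation — N_e diploid individuals, i.e.
one lineage per selfing plant, following the procedure's own
parameterization — for t = 22 generations, after which 75 individuals are
sampled. Initialization is configurable because the original internals are
unavailable: `sample_year1` (observed first-year sample frequencies; the
default for analyses restricted to MLGs present then), `pooled`, or `floor`
(ε = 1/(2n₁) added to zero counts, for analyses that include
second-year-only MLGs). Per replicate, the OLS slope of (final − initial
frequency) on MLG flowering time forms the null; the default alternative is
the lesser tail with the add-one convention p = (#{null ≤ obs}+1)/(n+1),
because the observed gradients of interest are negative and published
significant p-values are only consistent with that direction, despite the
procedure being described verbally as "greater than". All three alternatives
are exposed. The null-slope distribution has discrete atoms (at N_e ≈ 19 one
MLG is typically fixed after 22 generations), which makes the test mildly
conservative; calibration measured over 2000 pure-drift datasets gives a
type-I rate of ≈ 0.053 at α = 0.05 with approximately uniform p-values.
The N_e sensitivity scan re-runs the test on a grid (default spirit:
10–500) with independently derived seeds and reports the smallest grid value
rejecting at 0.05.

## Selection gradients

Relative fitness is each plant's seed count divided by the mean of its
year × treatment group. The Robertson–Price broad-sense genetic covariance
Θ(z, w) replaces the original bivariate REML with an assumption-light
method-of-moments contract: both variables are block-adjusted (block means
removed), and Θ is the between-family mean cross-product minus the
within-family cross-covariance divided by the effective replicate number n₀
(Henderson-style). Significance and the CI use a delete-one-family jackknife
t statistic; a family-pairing permutation p-value (which tests total
family-mean covariance rather than the within-family-corrected quantity) is
reported alongside when requested. Dominance and maternal genetic effects are
treated as negligible, as appropriate for near-complete selfers. The
contract is validated by parameter recovery: a planted genetic covariance of
−20 (trait SD 75, fitness SD 0.6, 55 families × 5 replicates) is recovered
without detectable bias across simulations.

The realized-fitness gradient is the unweighted OLS slope of signed MLG
frequency change on MLG mean flowering time (short-vernalization treatment;
genetic value = arithmetic mean over member plants, unstandardized). The 95%
CI is the t interval, which coincides with profile-likelihood bounds under
the Gaussian linear model; residual normality (Shapiro) is reported. The
seed-production proxy check regresses frequency change on greenhouse seed
production and returns a flat result (slope 0, p 1) rather than an error when
seed production is constant.

## Phenotype models

Thermal time is Σ max(0, T̄_day − T_b) over [sowing, flowering), T_b = 5 °C;
negative effective temperatures are truncated at zero (Bonhomme convention —
the source text does not state truncation). Degree-day differences are
displayed in calendar days both by dividing by the mean temperature (the
study's footnote convention) and by the mean effective temperature.

Vernalization sensitivity pairs each family's replicates across treatments by
greenhouse position, mirrored by default (block 1 with block 5, etc.,
configurable), and scales the pair difference by the population mean
difference (linear reaction norms assumed).

The flowering-time mixed model (`eq1`) has fixed year, treatment and their
interaction, and variance components for block (nested in treatment),
block × year, and family nested in year × treatment (four components).
Fitting delegates to statsmodels' MixedLM with explicit variance-component
design matrices under a single umbrella group; duplicate (non-identifiable)
component designs — e.g. block × year with one year — are dropped
automatically. The optimizer runs Powell then Nelder–Mead: in our testing the
gradient-based optimizers stall on these profiles. REML is the default;
likelihood-ratio comparisons of fixed effects require ML, and `lrt_compare`
refuses mixed types. On balanced single-cell designs the REML solution
coincides with the closed-form Henderson moment estimators to ~3 decimal
places, which is the basis of the fast path: per-cell variance components and
H² = V_G/(V_G + V_block + V_res) use the moment estimator so that the
delete-one-family jackknife (and simulation studies) stay cheap. Boundary
caveat: an LRT on a variance component has a null distribution with mass at
zero, so p-value calibration is only claimed (and tested) for fixed-effect
LRTs with standard χ² asymptotics. The regional model (`eq3`) is the same
machinery with a population term in place of the nested families.

## Synthetic data

`simulate_population` is an individual-based forward simulator: fully
homozygous founder MLGs with Dirichlet(α = 0.5 by default) initial
frequencies (small α → a few dominant MLGs), per-locus founder allele spectra
drawn from a Dirichlet (α = 0.4) over k = 10 states so locus H_e falls in the
0.4–0.7 range typical of microsatellites in selfing populations, fertility
selection w = max(0, 1 + β(z − z̄)) acting on parent sampling, selfing with
probability s (else outcrossing with free reassortment), and k-allele
mutation at μ = 5×10⁻⁴ per allele per generation (inside the measured
dinucleotide microsatellite range of 5×10⁻⁵–2×10⁻³). When `ne_target` is
set below the census, parent probabilities are drawn each generation from a
Dirichlet with concentration c = N(M−1)/(N−M), M = (1+F_IS)·ne_target, which
gives Dirichlet-multinomial offspring numbers with lineage-effective size M —
this is how a census of thousands can drift like N_e ≈ 19, and it is what
lets high MLG richness coexist with strong drift. What the simulator does
*not* emulate: seed banks, migration, spatial structure, linkage maps within
the marker panel, and trait architecture beyond a heritable mid-parent value —
so a green test establishes correct behaviour under idealized
Wright–Fisher-with-selfing dynamics, not robustness to those complications.

`simulate_temporal_drift` is the idealized independent-locus counterpart used
for N_e recovery checks; `generate_experiment` builds the
families × treatments × blocks greenhouse table with planted variance
components (or a planted heritability via `h2_plot`), a treatment effect of
−162.84 degree-days by default, and seed production declining linearly with
flowering time.

## Determinism

Every stochastic step takes a seed; the pipeline derives per-stage seeds from
one master seed, and `report.json` is byte-identical across runs with the
same inputs and seed. Seeds derived internally stay below 2³¹.
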