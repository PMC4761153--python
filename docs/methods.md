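# Methods

## The problem

Watterson's estimator of the population-scaled mutation rate,
θ_W = S / a_n (with S the number of segregating sites and
a_n = Σ_{i<n} 1/i), is unbiased only for neutrally evolving samples from a
constant-size population. Exponential population growth and purifying
selection both push variants toward very low frequencies, and rare variants
are only observed when enough genomes are sampled. The consequence is a
systematic, sample-size-dependent underestimation of θ_W that is stronger
for selectively constrained sequence than for neutral sequence — and that
propagates into every statistic built on θ-type estimators: Tajima's D,
Fu–Li D*, the McDonald–Kreitman Neutrality Index (NI) and the adaptive
fraction α. This package quantifies that effect on exome-shaped data and
with a forward population-genetic simulation.

## Statistics (module `popgen`, `mk`)

All polymorphism statistics operate on a *folded* site frequency spectrum
(minor-allele counts; no outgroup or ancestral call), the substrate being a
`SiteFrequencySpectrum(n_seq, counts, n_sites, site_class)`. Sample size is
always counted in sequences (haploids); diploid inputs are converted as
n_seq = 2s and the native unit is reported in sweep metadata.

- θ_W per site = (S / a_n) / n_sites.
- π per site = [Σ_m counts[m] · m(n−m) / C(n,2)] / n_sites, identical to
  the mean pairwise Hamming distance per site.
- Tajima's D = (k − S/a1) / √(e1·S + e2·S(S−1)), with the full Tajima
  (1989) variance constants (b1, b2, c1, c2, e1, e2).
- Fu–Li D* = ((n/(n−1))·η − a_n·η_s) / √(u* η + v* η²), the no-outgroup
  variant, with η = S and η_s = minor-allele singletons as proxies and the
  *corrected* u*, v* constants (Simonsen, Churchill & Aquadro 1995; the
  original 1993 printing contains typos). n = 3 is degenerate (every folded
  segregating site is a singleton, u* = v* = 0) and is rejected.
- MK statistics are computed on counts pooled over genes *before* taking
  ratios (per-gene ratios are mostly undefined at small n):
  NI = (P_n/P_s)/(D_n/D_s), α = 1 − (D_s·P_n)/(D_n·P_s).

Statistics that do not exist for an input (S = 0; P_s or D_n = 0; n too
small) raise a tagged `StatisticUndefinedError` and appear as `.`/NaN in
tabular output — never as a silent 0, since a zero would masquerade as
evidence of neutrality.

## Subsampling sweep (module `sweep`)

The empirical procedure partitions the panel uniformly at random into
*disjoint* groups of 16, 32, 64, 128, 256 and 512 individuals (several
independent redraws; results reported as mean ± SD across redraws, default
10). For each group and site class the SFS is pooled across genes and all
statistics computed; genes are additionally binned by dN/dS in ten
half-open bins [0,0.1) … [0.9,1.0] (values ≥ the last edge join the top
bin) to grade the effect by constraint. Series are summarised by:

- OLS slope of log2(statistic) on log2(sample size), with its SE,
- δ(512,16) = value(512) − value(16) and the ratio value(512)/value(16)
  (the ratio is oriented large/small to match fold-increase statements),
- Pearson correlation on log2–log2 values and Kendall's τ on raw values.

Low-frequency polymorphisms are not pruned before the MK table: the
sample-size dependence of rare nonsynonymous polymorphism is the object of
study, and no pruning is part of the analysed procedure.

## Forward simulation (modules `simulate`, `coalescent`)

A 5 kb non-recombining locus evolves through a discrete-time Wright–Fisher
model: multinomial resampling of 2N haplotypes weighted by fitness,
Poisson(2N·μ·L) new mutations per generation placed by infinite-sites rules
on the 5,000-site grid (recurrent hits at an occupied site are redrawn).
Selection is genic: a haplotype carrying mutations with coefficients s_i
has weight Π(1 − s_i/2), the random-mating equivalent of semidominant
(h = 0.5) diploid selection and consistent with the γ = 2Ns
parameterisation. Deleterious coefficients are drawn from a gamma
distribution with shape 0.206 and mean s̄ = γ̄/(2N_e); γ̄ ("mean_gamma")
is varied from 2 to 2000. After rescaling, s is capped at 1 and the cap
frequency logged (capped mutations are effectively lethal either way).

Demography: an ancestral population of N_e = 10,000 splits into two
daughters of 5,000 that grow at the same slow rate to N_e = 9,210 over
2,040 generations; afterwards the sampled branch either stays at 9,210
("constant growth") or grows exponentially to N_e = 512,210 over 920
generations. The split is mass-conserving and the pre-split (merged)
population forms the ancestral tail; the unsampled branch exchanges no
migrants and is not simulated. The two phase *durations* are a
reconstruction from the two-epoch human-growth literature — the endpoints
(10,000; 9,210; 512,210) do not determine them — and are exposed in
`growth_schedule(...)`. The 920-generation fast phase reproduces the
neutral exponential excess of rare variants (≈ 84–89% more θ_W at n = 512
than at n = 16); substantially shorter fast phases (e.g. ~140–205
generations as in some inference studies) predict only ~35–40% and are
inconsistent with that observable.

Desk-scale execution uses the standard θ-preserving rescaling λ:
N → N/λ, μ → μλ, s → sλ, durations → durations/λ. λ is chosen per branch
so that the largest sample (512 haplotypes) stays ≤ ~11% of the smallest
sampled population and every final size exceeds 1,024 haplotypes:
λ = 4 for constant-branch scenarios (9,210/4 → 2,303 diploids) and λ = 100
for exponential-branch scenarios (512,210/100 → 5,122 diploids). Forward
runs at λ ∈ {4, 8, 16} give statistically indistinguishable slopes and
folds, and a discrete Poisson-Random-Field computation of E[θ_W(n)]
confirms λ-invariance analytically, so rescaling is not a materially
biasing choice at these factors.

Each replicate is an independent locus; replicate r of a run with seed s
draws all randomness from `default_rng([s, r])`, making runs
bit-reproducible. Burn-in is `burn_in_factor × N_anc` generations
(default 10, i.e. 2.5× the expected n→2 coalescent depth).

`expected_theta_neutral` is the validation oracle: it integrates the
lineage-count death process (rates k(k−1)/(4N(t)) backwards in time)
through the schedule with a stiff ODE solver, closes the constant
ancestral tail analytically (4N·a_k from k lineages), and returns
μ·L·E[T_total]/a_n. For an all-constant schedule it reduces exactly to
4NμL. It is cross-checked in the test suite against Monte-Carlo coalescent
simulation with msprime, which plays no role in the implementation.

## Synthetic exome generator (module `synth`)

The generator emulates the *shape* of a large exome panel: 1,008 diploid
individuals (so the 16+32+64+128+256+512 partition is exact), genes with
300 synonymous / 900 nonsynonymous sites, per-gene dN/dS drawn uniformly
on [0,1) (chosen so all ten constraint bins are populated; not a claim
about the human dN/dS distribution), dN = (dN/dS)·dS with
dS ~ U(0.1, 0.6) so dN, dS ≤ 0.8 survive the load filter by construction,
and Poisson divergence counts D_n ~ Pois(dN·sites), D_s ~ Pois(dS·sites).

SNV population frequencies follow a 1/i law over population allele counts,
optionally tilted toward singletons: a fraction t of the mass at counts
≥ 2 is moved to the singleton bin, with t = base_skew for synonymous sites
and t = base_skew + constraint_skew·(1 − dN/dS) for nonsynonymous sites
(defaults 0.15 and 0.35). This one-parameter tilt is a modelling
convenience that reproduces the qualitative rare-variant excess created by
growth and purifying selection; it asserts no particular DFE-to-SFS map,
and passing the directional tests on this generator shows the *pipeline*
responds correctly to class-dependent rarity, not that real exomes have
these parameters. Genotypes are Hardy–Weinberg binomial draws: no linkage,
no inbreeding, no population structure — features of real panels the
generator deliberately omits.

`planted_sfs_table` builds a deterministic panel whose pooled SFS equals a
given spectrum exactly, for construct-then-recover tests of the whole
pipeline.

## Problem sizes used in the shipped runs

The packaged test suite and the acceptance script run the simulation
scenarios at 150–500 replicates (analysis scripts default to 200,
configurable), sample sizes 16–512, and the rescaling factors above; the
empirical sweep runs on 600–1,000 synthetic genes with 3–5 redraws. These
sizes were chosen to keep Monte-Carlo SEs small relative to the effects
under study while remaining single-CPU friendly; all counts are exposed as
parameters.

## Numerical choices and edge cases

- Tie-break for "minor" at exactly n/2: the folded count is min(c, n−c);
  sites at exactly half frequency fold to n/2.
- Sites with any missing genotype are dropped listwise (from counts *and*
  n_sites); real-data mode only.
- Non-positive values are excluded from log–log regressions (with fewer
  than 3 usable points the slope is undefined); constant series make
  correlations undefined rather than 0.
- The ODE oracle uses BDF with an analytic sparsity pattern,
  rtol 1e-10 / atol 1e-14; probabilities are clipped at 0 before the tail
  closure.
- The dN/dS > 0.8 gene filter is applied at load time (maximum-likelihood
  divergence estimates above 0.8 are dominated by multiple-hit
  overcorrection).

## Known limitations

- The constant-growth branch under strong purifying selection
  (γ̄ = 2000) yields a θ_W-vs-n slope of ≈ 0.10 and a 512/16 fold of
  ≈ 1.4 in this implementation — materially smaller than some published
  simulation-based figures (~0.21 / ~2.1). Both our forward simulator and
  an independent diffusion-theory (PRF) calculation agree on the ~0.10 /
  ~1.4 values for this DFE, which bounds the equilibrium constant-N effect
  whenever a gamma DFE with shape ~0.2 leaves substantial nearly-neutral
  mass. The discrepancy therefore appears to trace to unrecoverable
  details of the original simulation configuration rather than to
  Monte-Carlo error; the acceptance machinery reports our computed values
  unchanged.
- No recombination within a locus and no linkage between loci; no
  migration after the split; purifying selection only (no beneficials).
- The synthetic exome generator is a test instrument, not a model of human
  genetic variation (see above).
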