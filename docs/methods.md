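# Methods

## Model overview

`coansel` simulates a closed diploid breeding program in three phases.

**Base population.** A Wright–Fisher-style forward simulation with
non-overlapping generations, separate sexes, symmetric per-copy mutation
(each allele copy flips 0↔1 with probability `mutation_rate` per
generation) and Poisson recombination: crossover counts per chromosome are
Poisson with mean equal to the chromosome length in Morgans, positions
uniform, starting haplotype uniform, chromosomes independent. Loci are
equally spaced. Every generation all parents are mutated first, then each
offspring draws a sire and a dam uniformly with replacement. Initial
haplotypes are i.i.d. Bernoulli(½), so initial heterozygosity is 0.5; under
burn-in the population relaxes to the symmetric two-allele mutation–drift
equilibrium, whose expected heterozygosity is `H* = ½ − ½/(1 + θ)` with
`θ = 8Nμ` (derived from the coalescent identity `E[(1−2μ)^{2T}]`,
`T ~ Geom(1/2N)`; the package's own burn-in runs confirm it).

**Replicate construction.** Each replicate draws, from one shared base:
`n_qtl` QTLs uniformly among loci with allele-1 frequency strictly inside
(0.05, 0.95); standard-normal allele effects; and N founder sires + N
founder dams without replacement (pedigree generation 0, unknown parents).
Six recorded random-mating generations follow. `σ²_a` is the sample variance
(n−1) of the TBVs over the full base population; `σ²_e = σ²_a (1−h²)/h²`.
Every individual receives one phenotype `y = μ + TBV + e` at birth
(`μ = 100`).

**Selection phase.** For each of the `n_selection_generations` rounds: build
the driving relationship matrix over *all* recorded individuals (a
`mme_records_window` option restricts the mixed-model equations to the last
W cohorts; default is all), estimate `(σ²_a, σ²_e)` by MCEM REML under that
matrix (or use the calibrated truth when `use_true_variances` is set), solve
Henderson's equations with a single overall mean, select the top
`select_fraction` of each sex of the current cohort by EBV (ties broken by
lower id), and mate the selected parents uniformly at random to produce N
male and N female offspring. During the recorded phases mutation is applied
to gametes at birth rather than by re-mutating parents, so recorded genomes
(and hence phenotypes and matrices already computed from them) are
immutable; the marginal per-copy rate is identical.

## Relationship matrices

All four are stored as relationships = 2 × coancestry; inbreeding is
uniformly `F_i = K_ii − 1`, which equals the classical pedigree inbreeding
for A, the marker homozygosity fraction for G, the own-gamete ROH fraction
for R, and the VanRaden diagonal excess for V.

- **A**: tabular recursion (`a_ii = 1 + a_sd/2`, `a_ij = (a_js + a_jd)/2`),
  founders non-inbred and unrelated. Validated against Wright's
  path-counting method.
- **G** (IBS): the four-ordered-gamete-pair average. Closed form over
  genotype counts: `2f_G = (XX' + (2−X)(2−X)')/(2M)`. Note the exact
  identity `G = V + 11'` at `p = 0.5`, which the paired behaviour of G- and
  V-driven selection reflects.
- **R** (shared segments): maximal runs of contiguous identical markers per
  gamete pair, within chromosomes only; runs of ≥ `roh_min_run` markers
  (default 100 at every panel density) contribute their length in markers;
  the genome length L is the total marker count, so threshold and metric
  share units at every density. With `roh_min_run = 1` R degenerates
  exactly to G. Genetic-distance units would change only the weighting of
  runs, not which runs qualify, and are not implemented.
- **V** (VanRaden): centred cross-product with all reference frequencies
  fixed at 0.5. The gene-frequency code is g = (copies of allele 1)/2; with
  p = ½ the opposite coding (1, 0.5, 0) only flips the sign of both centred
  factors and leaves every product unchanged, so the two conventions are
  equivalent here.

## Variance components (MCEM REML)

Model `y = 1μ + Zu + e`, `u ~ N(0, K σ²_a)`, `e ~ N(0, I σ²_e)`. One Gibbs
sweep per EM iteration samples μ and u from their full conditionals, then
updates `σ²_a ← u'K⁻¹u/q` and `σ²_e ← e'e/n`; estimates are means of the
post-burn-in iterates (default 6000/1000; the test suite and desk-scale
scenarios use 600/100). K is eigendecomposed once per call (eigenvalues
floored at 1e-8 after a 1e-6 ridge); in the eigenbasis the full conditional
of u is diagonal for balanced designs, so each iteration is O(n) with no
per-iteration refactorisation. A variance floor of 1e-8 prevents absorption
at zero. At the population sizes this package targets (a few hundred
records, shallow pedigrees), the REML likelihood is very flat: an exact
eigenbasis REML optimiser is unbiased over repeated simulations but single
realisations scatter widely (and can hit the zero boundary). The MCEM
estimates inherit this sampling noise; selection outcomes are driven by EBV
*rankings*, which are far less sensitive to the variance ratio than the
variances themselves.

## BLUP

Henderson's equations with X = 1, Z = I (one record per individual), solved
densely. K is inverted from a Cholesky factorisation of K + 1e-6·I; the
segment-based matrix R need not be positive semi-definite, in which case the
inverse is taken on the eigenvalue-clipped (≥ 1e-6) surrogate. Equivalence
with the closed-form GLS/BLUP solution is asserted in the tests to 1e-8.

## Metrics

Per generation, over the current cohort of 2N candidates: mean TBV, mean
phenotype, genome-wide observed heterozygosity, and for each matrix kind the
mean off-diagonal pairwise coancestry and mean inbreeding — recorded under
*every* selection mode (the cross-performance design). Gains are reported as
`Δ TBV` from the last pre-selection generation; coancestry trajectories as
`log[(1−f_t)/(1−f_base)]` with the baseline at the last pre-selection
cohort. (With 6 random-mating generations and selected cohorts 7..21, the
baseline is generation 6 — the cohort in hand when the first selection event
happens.) Histogram summaries use the sample variance (ddof = 1) of the
off-diagonal coancestries.

## Scaled-down study conditions

Full-scale defaults (10 chromosomes × 10,100 loci, base 1000 for 10,000
generations, N = 50, 15 selection rounds, 100 replicates) are available but
not desk-scale. The shipped end-to-end comparison uses: genome 2 × 1000
loci (full-density panel), base population 1000 individuals with the
standard mutation rate 2.5e-3 burnt in for 300 generations — this keeps
θ = 20 and hence the equilibrium heterozygosity (≈ 0.48) and LD regime of
the full-scale base, shrinking only the genome — N = 10, h² = 0.25,
n_qtl = 100 (5% of loci; the same order of QTL-per-locus density as full
scale while keeping the trait reasonably polygenic), 10 selection rounds,
30 paired replicates, REML 600/100. Replicate r uses seed `base_seed + r`
independent of the selection mode, so modes are compared on identical QTL
draws, founders and pre-selection history.

## What the scaled-down comparison shows — and does not

Reproduced robustly at this scale: pedigree-driven BLUP achieves gains
within 20% of the genome-driven modes; pedigree-driven BLUP inflates
*genealogical* coancestry f_A fastest (and well above a mass-selection
control, confirming the family-co-selection mechanism); all four coancestry
measures rise monotonically under every mode.

Not reproduced at this scale: the ordering of *molecular* diversity loss.
In these desk-scale runs each BLUP inflates its own similarity measure
fastest — IBS/VanRaden-driven selection erodes marker heterozygosity faster
than pedigree-driven selection, not slower. Two compounding mechanisms are
visible in the instrumented runs: selected parents under G-driven BLUP are
measurably more homozygous than their cohort (the uncentred IBS/VanRaden
diagonal, 1 + homozygosity, shrinks homozygous candidates' EBVs less), and
hitchhiking around the comparatively dense QTLs of a 2-Morgan genome is
strong. At full scale (10 Morgans, 101,000 markers, deeper replication) the
genome-wide drift cost of pedigree family co-selection is expected to
dominate instead; reaching that regime is outside a desk-scale budget, and
this divergence was insensitive to every configuration axis we probed
(genome length 2–10 Morgans, marker density 1000–5050 per chromosome, base
Nₑ 100–1000, h² 0.10–0.50, QTL count 20–500, REML-estimated vs known
variances, cumulative vs current-cohort records). Conclusions about
molecular-diversity orderings from this package should therefore be drawn
only at, or near, full scale.

## Numerical and design choices

- Offspring sex is assigned deterministically (first N male, next N female);
  with parents drawn at random this matches random assignment in
  distribution.
- Truncation keeps ⌊fraction × count⌋ per sex and errors if a sex class
  would empty.
- QTLs live on the full-density panel; thinned panels stride without regard
  to QTL status.
- The base-population burn-in length is configuration, not a stopping rule:
  heterozygosity trajectories are reportable and equilibrium can be judged
  from them (both H = 0 and H = 1 starts converge to the same plateau, as
  the property tests assert).
- Degenerate inputs raise typed errors (`InvalidArgumentError`,
  `InvalidStateError`, `PedigreeError`, `NumericalError`, `ConfigError`)
  rather than propagating numpy failures.

## Known limitations

- No dominance/epistasis, no overlapping generations, no optimum-contribution
  selection, no marker-effect (SNP-BLUP) estimation, no HMM-based ROH calling.
- The MCEM standard errors reported per chain are naive (no autocorrelation
  correction).
- The synthetic genomes use equally spaced biallelic loci and a high,
  uniform mutation rate; real SNP data have irregular spacing, allele-
  frequency ascertainment and far lower per-site mutation rates, so absolute
  diversity levels here are not calibrated to any real population.
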