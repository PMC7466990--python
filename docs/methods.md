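# Methods

This note records the models, estimators and numerical choices behind
`goosepop`, and what the synthetic-data tests do and do not establish.

## Data model

Genotypes are diploid ALT-allele dosages (0/1/2, or missing) over
biallelic SNPs; phase is ignored and half-calls are treated as missing.
Positions stay 1-based as in VCF. Individuals belong to populations,
populations to one of three groups (wild, European domestic, Chinese
domestic). All per-population statistics are computed over non-missing
genotypes only; no imputation is done anywhere except PCA (below).

## Filters and site accounting

Site filters run in a fixed order — indel, multi-allelic, within-dataset
invariant, observed heterozygosity H_O > 0.75 — so that each removed locus
is attributed to exactly one rule and per-rule counts are deterministic.
Thresholds are strict inequalities (H_O > 0.75 removed, H_O = 0.75 kept;
individual missingness > 20% removed). "Invariant" means no alternate
allele segregates among non-missing calls; an optional flag retains loci
fixed for a non-reference allele, which carry cross-species divergence
information when the mapping reference is a related species.

The SFS denominator follows the bookkeeping the composite likelihood
needs: from the callable base-pair total, sites removed by identity-based
filters (indel, multi-allelic, heterozygosity excess) are subtracted
outright; invariant loci are *not* subtracted (they remain callable,
monomorphic sites); and the loss of SNPs to the missing-data completeness
requirement removes the same *proportion* of callable sites. Kept SNPs
form the polymorphic class, everything else the monomorphic class, and
`monomorphic + polymorphic = total` holds exactly.

## Diversity and differentiation

Expected heterozygosity uses the small-sample-corrected gene diversity
H_E = 2n/(2n−1)·(1 − p² − q²) with n non-missing diploids (the naive 2pq
form is available for cross-checks). Loci monomorphic within a population
contribute H_E = 0 to its mean rather than being dropped; only cells with
no call at all are excluded. The wild/domestic comparison is a two-sided
Welch *t*-test whose sampling unit is the population (per-population mean
H_E): populations, not loci, are the independent replicates, and only this
choice produces fractional degrees of freedom of the order seen with a
handful of populations per group.

Pairwise F_ST is the Weir–Cockerham (1984) estimator with multi-locus
combining as a ratio of sums (Σa / Σ(a+b+c)); loci monomorphic across a
pair, or uncallable in either member, are skipped and counted. Small
negative estimates are legitimate and not truncated.

The AMOVA treats each called diploid as two binary allele copies, so
per-stratum sums of squares reduce to allele-count arithmetic, and
partitions variance into among-group, among-population-within-group and
within-population components with unequal-size coefficients computed per
locus (locus-by-locus mode: components are estimated per locus and
summed). Each fixation index has its own permutation scheme — whole
populations among groups (F_CT), individuals among populations within
groups (F_SC), individuals among all populations (F_ST) — with the +1
correction p = (#{perm ≥ obs} + 1)/(B + 1). The reference default is
16,000 permutations; tests use fewer.

## f3 admixture test

The statistic is the mean over loci of (ĉ−â)(ĉ−b̂) minus the unbiased
estimate of the target-frequency sampling variance, ĉ(1−ĉ)/(n_C−1). The
correction applies to the target only: sampling noise in the source
frequencies is independent of the target and cancels in expectation.
(A correction of 2ĉ(1−ĉ)/(n_C−1) — reading "heterozygosity" as 2pq —
over-corrects by a factor of two and pushes pure-drift targets to strongly
negative f3; this was verified on synthetic data and is why the 1×
variance form is used.) Standard errors come from a weighted delete-one
block jackknife over contiguous blocks of 500 loci in genome order — no
genetic map exists for these GBS loci, so locus-count blocks stand in for
map-distance blocks — and Z = f3/SE with Z < −3 as the conventional
admixture call. Loci monomorphic across all three populations are dropped
before blocking.

## PCA, Tracy–Widom and trees

Loci are centered by mean dosage and scaled by √(p̂(1−p̂)); missing
dosages are mean-imputed for the decomposition only. Axis significance
tests the largest remaining eigenvalue against the Tracy–Widom (β=1) law,
sequentially, stopping at the first non-significant axis. The effective
marker count uses the eigenvalue-dispersion estimator capped at the true
locus count: on unlinked data the dispersion estimator overshoots the real
marker number (verified on null matrices), while correlated loci pull it
down, which is the regime the correction exists for. The TW1 CDF itself
is evaluated through Chiani's shifted-gamma approximation
(Γ(k=46.446, θ=0.18605) − 9.84801), accurate to about 10⁻⁴, rather than an
interpolated quantile table.

Individual distances are allele-sharing distances: mean |dosage
difference| over co-called loci, divided by the ploidy, so values live in
[0, 1]. Neighbor joining is the Saitou–Nei agglomeration with
deterministic tie-breaking (lowest index pair) and negative branch
lengths clamped to zero with the deficit moved to the sister edge (the
pair's summed length is preserved). On additive matrices the algorithm is
exact, which the tests exploit.

## Demographic model and inference

Three nested two-population histories are considered, all backward in
time from the present: wild and domestic demes of constant diploid sizes
N_WILD and N_DOM merge into an ancestor of size ANCSIZE at T1 generations;
migration is piecewise constant with one matrix in the recent epoch
[0, T2) and another in [T2, T1). `no_migration` fixes all rates at zero
(4 free parameters), `constant_migration` ties the epochs (6), and
`changing_migration` frees them all (9). Rates follow the forward
convention: M_XY is the per-generation fraction of deme Y replaced by
migrants from X, so N_Y·M_XY is the expected migrant count into Y — the
convention under which the fitted history's printed migrant numbers
(0.41, 1.34, 1.65 per generation) reproduce exactly. Backward in time a
lineage in Y therefore jumps to X at rate M_XY, and a pair in a deme of
size N coalesces at rate 1/(2N); the continuous-time approximation to
discrete generations is used throughout (its error at these sizes is far
below Monte-Carlo noise).

The expected folded joint SFS is estimated by simulating genealogies of
22 wild + 30 domestic chromosomes and accumulating, for every branch, the
generations it spends subtending each (wild, domestic) leaf
configuration: under infinite sites the expected density of sites in cell
(i, j) is μ·E[L_ij] per site. This is the exact expectation of Poisson
mutation dropping with much lower variance per replicate. The simulator
is numba-compiled with O(1) event handling (deme-partitioned lineage
array) and runs ~10⁵ genealogies per second at study-scale parameters;
msprime serves as an independent oracle for the same model in the tests.
"Sampled" mode draws site counts multinomially around the expectation.
Folding merges each cell with its complement by pooled minor allele;
exact ties split their mass in half.

The likelihood is the multinomial composite log-likelihood over folded
cells *including the monomorphic class* — with μ fixed at 1.38×10⁻⁷ per
site per generation (a pedigree-scale estimate from a closely related
goose) the polymorphic fraction of the 1,681,316 callable sites is what
identifies absolute sizes and times. Expected-cell probabilities of zero
under observed support are floored at 10⁻¹⁰.

Maximization combines three ingredients, all under common random numbers
(one coalescent seed per comparison set, so Monte-Carlo noise cancels):

1. **Screening.** A cloud of log-uniform candidate parameter vectors,
   plus warm starts derived from a fit of the nested simpler model
   (grids over the epoch-switch time, rate contrast, and split-time
   rescalings — a migration-free fit absorbs gene flow into a shorter
   split, so longer-T1 candidates are seeded deliberately). Candidates
   are scored cheaply with a smoothed likelihood: 1% of the expected
   polymorphic mass is spread uniformly over the cells, removing the
   finite-simulation bias that otherwise penalizes exactly the
   broad-spectrum (migration-rich) models. Final scoring is always exact.
2. **Conditional maximization.** Cycles of block-coordinate ascent over
   {sizes}, {times}, {rates} with a two-stage geometric line search per
   parameter.
3. **Simplex refinement.** Nelder–Mead over all free log-parameters with
   a wide initial simplex, in annealed rounds whose replicate counts
   double (and iteration budgets shrink) so late rounds see low-noise,
   low-bias likelihoods. The smoothed objective is used only in the early
   rounds; the final rounds maximize the exact likelihood, otherwise the
   search converges to the smoothed optimum, which at megabase site
   counts is measurably displaced from the true one.

Restart starting points are chosen for diversity — distinct split-time
scales first, then distinct migration-shift times — because screening
rank predicts within-basin quality but not which basin wins after
refinement. Every restart's endpoint is scored under one shared
high-replicate seed and the best wins.

For the changing-migration model an optional epoch-refinement pass
(``FitSettings.refine_epoch``) profiles the winner over a grid of
epoch-switch times T2: each candidate re-polishes *all* parameters, warm
started along the T2·M2 ridge (a shorter recent epoch needs
proportionally stronger recent gene flow), and candidates are compared
under the shared exact scoring seed. T2 is the weakest-identified
parameter — rival (T2, M2) modes can sit within ~10 log-likelihood units
of each other at megabase site counts — and this pass is what reliably
separates them at desk-scale effort.

Model selection refits all candidate models (each warm-started from the
previous, nested one), re-evaluates every optimum under a single shared
seed at high replicate count, enforces the nesting floor (a richer model
can never score below the embedded optimum of a model it contains), and
converts AIC = 2k − 2·lnCL to Akaike weights. The parametric bootstrap
simulates B spectra at the MLE in sampled mode, refits each with
scaled-down settings, and reports 2.5–97.5 percentile intervals; at least
20 replicates are required, with 100 as the reference scale (50
independent runs per replicate at full scale).

**Effort profiles.** Likelihood evaluations and optimization effort are
set by a `FitSettings` object. The `desk` profile (5,000 coalescent
replicates per evaluation, 10 conditional-maximization cycles, 20
restarts) is the working default; `paper` (100,000 / 40 / 100) is the
full-scale reference effort for faithful reproduction. The recovery
study in the tests and acceptance script uses 3,000 replicates with 4
diverse restarts, 4 annealed refinement rounds and the epoch-refinement
pass; the model-selection study uses 1,000 replicates with 3 restarts per
fit and 100,000 sites per simulated dataset — sizes chosen so a complete
run stays desk-scale while the checked contrasts (times inside their
reported intervals, the correct generating model winning the Akaike
weights) remain decisively resolved. Simulated "observed" datasets are
drawn from a 120,000-replicate expected spectrum: at lower generation
precision the Monte-Carlo error of the generating spectrum acts as model
misspecification that the richest model chases, distorting model
selection.

## Synthetic data

The generator emulates the study design: three diverged gene pools (wild
graylag-like, European-domestic-like, Chinese-domestic-like), populations
of 5–15 diploids that are either pure draws or α:(1−α) mixtures of two
pools, ~10⁴ biallelic SNPs over ~10⁶ callable sites, and i.i.d.
per-genotype missingness (defaults 5%). Pool frequencies follow a
Balding–Nichols model around a Uniform(0.05, 0.95) ancestral frequency.
The drift parameters are calibrated to the study system's observed
differentiation: pool-level F = (wild 0.06, European 0.11, Chinese 0.32)
and within-pool population drift (wild 0.09, breeds 0.17) reproduce mean
pairwise F_ST of ≈0.20 between wild populations and breeds, ≈0.09 among
wild populations and ≈0.17 among breeds — breeds drift far more than wild
flocks, the breed-formation signature. Crossbred (admixed) populations
get only F = 0.03 of post-mixing drift: they are recent, and heavy target
drift would genuinely mask the f3 signal (a known failure mode of the
statistic, not something the generator emulates by default). A coalescent
mode draws wild/domestic frequencies from the fitted divergence model
instead. Ground truth (all frequencies, mixture weights, config) is
serialized with every dataset.

What passing tests on this generator do show: the estimators recover
planted signals (admixture, divergence, diversity contrasts) at realistic
sample sizes and marker counts, with correct nulls (no false admixture on
pure targets, uniform permutation p-values, calibrated Tracy–Widom
statistics). What they do not show: robustness to features of real GBS
data the generator omits — linkage between tags, allele-frequency
ascertainment from the discovery panel, individual- or locus-biased
missingness, mapping bias against divergent alleles, and genotyping error.
The uniform ancestral-frequency choice makes synthetic H_E levels higher
than the study's (~0.3 vs ~0.1–0.15); contrasts between groups, not
absolute levels, are what the tests assert.

## Degenerate inputs and edge policies

Zero-record VCFs, all-missing locus/population cells, pairs with no
shared loci, single groups in the AMOVA (F_CT undefined, reported as
such), fewer than two jackknife blocks, and folding an already-folded
spectrum all raise explicit errors or flagged undefined values rather
than silent numbers. Equal-distance NJ joins resolve to the lowest index
pair; exact-tie SFS cells split; permutation p-values can never be zero.

## Known limitations

* The composite likelihood ignores linkage; standard errors from it are
  not interpreted, and only the parametric bootstrap is offered for
  uncertainty.
* The coalescent simulator covers exactly the two-deme, three-model
  family (no growth, no recombination, no additional demes).
* T2 and the recent migration rates are weakly identified at GBS scale:
  likelihood differences between rival (T2, M2) modes are of order 10
  log-units on 1.7 Mb of sites, which is why the optimizer invests in
  mode-diverse restarts and high-replicate final scoring.
* The Tracy–Widom calibration is validated for unlinked markers; for
  dense linked data the dispersion-based effective marker count is a
  heuristic.
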