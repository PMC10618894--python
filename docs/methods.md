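# Methods

This note records the models and estimators clonalpop implements, the
numerical and design choices made where the literature leaves them open, and
what the synthetic-data tests do and do not establish.

## Dataset model

A `MicrosatDataset` is a samples × loci array of unordered diploid allele
pairs (fragment sizes, positive integers), with site and period labels per
sample and optional projected coordinates in meters. A locus call is either
complete or missing; half calls are coerced to missing on input with a
warning, since a single scored allele cannot distinguish homozygote from
dropout. Pairs are stored canonically as (min, max). Missing is encoded as
`0/0` in the GenAlEx dialect and `0000` in genepop, those formats'
conventions; genepop cannot carry ids, periods or coordinates, so writes add
a sidecar CSV that makes the round trip lossless.

## MLG assignment and clonal identity

Samples with complete genotypes are grouped by exact allele matches at all
loci. A sample with missing loci merges into an existing MLG only if it
matches it at every co-scored locus, shares at least `min_scored_loci`
(default 7 of 10) scored loci with it, and exactly one MLG is compatible;
with two or more compatible MLGs the sample stays its own MLG and is flagged
for review, and with fewer than `min_scored_loci` scored loci it is left
unassigned. This is a deterministic surrogate for the manual curation such
data normally receive: conservative (never merges on ambiguous evidence) and
order-independent up to relabeling (incomplete samples are processed in
fewest-missing-first, then lexicographic, order).

psex uses pgen = Π over scored loci of f_a·f_b·2^h (h = 1 iff heterozygous)
and the binomial upper tail P(X ≥ n_obs), X ~ Bin(N, pgen). Allele
frequencies for pgen are round-robin clone-corrected: for each locus, MLGs
are re-identified with that locus excluded and one representative per
reduced MLG contributes to that locus's counts. This avoids letting a large
clone vote for its own allele frequencies. Frequencies are per-site by
default with a pooled option, since clonal identity is usually judged within
sites. No F_is correction enters pgen; in populations with strong
heterozygote excess (common under clonality) pgen is then conservative for
heterozygous genotypes — a documented limitation. The clone threshold
psex < 0.01 is configuration, not hard-coded.

Clone correction keeps, per MLG per scope unit (site by default), the
representative with fewest missing loci, ties broken by sample id.

## Genotypic diversity

GD = (G−1)/(N−1). The effective-number variants apply the same scaling to
E_Shannon = exp(−Σp ln p) (natural log) and E_Simpson = 1/Σp². The
(E−1)/(N−1) form was chosen because it preserves the [0, 1] range, equals GD
exactly when all MLGs are singletons, and reproduces the monotone ordering
GD ≥ GD_Shannon ≥ GD_Simpson that effective numbers guarantee for any
abundance vector; a plain E/N definition does none of these. No small-sample
bias correction is applied to the Simpson index.

## Permutation engine

The two-group statistic is |mean₁ − mean₂|. With C(n, n₁) ≤ 100,000 the test
enumerates all splits; otherwise it samples label permutations. p is the
proportion of permuted statistics strictly greater than the observed one,
matching the convention "proportion of permuted values larger than
observed"; an inclusive (≥, +1-corrected) variant is available because the
strict form can return p = 0. Equality is judged with a 1e-12 guard so
floating-point ties count as ties. Exhaustive p-values are deterministic;
Monte-Carlo runs are reproducible under a seed.

## Genetic diversity

Rarefied allelic richness uses the hypergeometric expectation of distinct
alleles in 2g genes drawn without replacement from the 2N scored genes at a
locus (log-gamma evaluation), averaged over loci with ≥ g scored
individuals; the default g = 5 reflects rarefying to the smallest usable
site. H_e is the uncorrected 1 − Σp² (GenAlEx convention); Nei's unbiased
factor 2N/(2N−1) is a flag. F_is is Weir & Cockerham's small-sample f with
variance components summed over alleles and loci (weighted combination);
per-locus b and c components are b = n/(n−1)[p(1−p) − (2n−1)h/(4n)],
c = h/2, f = 1 − Σc/Σ(b+c). Its significance comes from permuting alleles
among individuals within the stratum, each locus separately, with p_gt and
p_lt both reported under the (count+1)/(n+1) convention. Allele accumulation
curves draw samples without replacement and report the mean and SD of the
distinct-allele count (summed over loci) at each depth.

## Data quality

The HWE test is a Monte-Carlo exact test: gene copies are shuffled into
genotype tables conditional on allele counts, and p is the fraction of
tables whose conditional probability (n! 2^H Πm_a! / (2n)! Πn_ij!) is ≤ the
observed table's — the probability-ordering criterion. The index of
association uses per-locus genotype distances 0/0.5/1 (both, one, no shared
alleles): Ī_A = V_O/V_E − 1 and r̄_d = (V_O − V_E)/(2Σ_{l<m}√(V_l V_m)),
with pair variances taken as population variances over sample pairs.
Null-allele estimators are r_C = (H_e−H_o)/(H_e+H_o) and
r_B1 = (H_e−H_o)/(1+H_e); negative values are floored at zero and flagged.

## Bottleneck test

Heq conditional on the observed allele count k is simulated by a single-locus
coalescent without recombination: the genealogy of 2×(scored individuals)
gene copies is generated root-to-tips, mutations are Poisson on branch
lengths at rate θ/2 per lineage, and each mutation steps the repeat count by
±1 with probability p_smm or by a ± geometric magnitude otherwise. The
geometric success probability solves var = (1−q)/q², so the default
var_geom = 0.36 gives q ≈ 0.781 (mean multi-step ≈ 1.28 repeats). θ is tuned
by bisection (log scale, 14 iterations on batches of 300) until the mean
simulated allele count matches k, then replicates with exactly k alleles are
retained by rejection until the requested count; a `ConditioningError` is
raised if fewer than 5% of the target can be collected. Both observed and
simulated heterozygosities use the unbiased n/(n−1) gene diversity. The
site-level test is a one-tailed Wilcoxon signed-rank (scipy, exact for small
locus counts) on the per-locus standardized differences
(He_obs − mean Heq)/sd Heq, alternative "greater". The mode-shift test bins
pooled allele frequencies into ten width-0.1 classes; the spectrum is
L-shaped iff the (0, 0.1] class is maximal, so a spectrum whose rare class
is empty (e.g. one locus at 0.5/0.5) classifies as shifted by construction.
Defaults p_smm = 0, var_geom = 0.36 are the standard microsatellite TPM
settings; multiple-testing thresholds are configuration.

## LD effective size

For every inter-locus allele pair (individuals scored at both loci), the
Burrows composite disequilibrium Δ̂ = (n/(n−1))[mean(xy)/2 − 2p̂q̂] over
allele dosages x, y is squared and divided by
[p̂(1−p̂)+D̂_A][q̂(1−q̂)+D̂_B], the Hardy–Weinberg-disequilibrium-adjusted
variances — i.e. the squared dosage correlation with Weir's small-sample
correction. This is the estimator whose pure-sampling expectation matches
the Waples corrections used downstream (1/S + 3.19/S² for S ≥ 30,
0.0018 + 0.907/S + 4.44/S² below); the plain p(1−p)q(1−q) denominator has
null mean ≈ 1/S and visibly under-recovers drift signal in simulation.
Comparisons are weighted by their sample size; S is the harmonic mean over
comparisons; degrees of freedom for the CI sum (k₁−1)(k₂−1) over locus
pairs, since only k−1 alleles per locus are free. Ne comes from the
quadratic inversion of E[r′²] (random-mating branch for S ≥ 30 and the
S < 30 variant); r′² ≤ 0 is reported as infinite — the data contain no
detectable drift signal. The parametric CI treats n·r̄²/r²_true as χ²(n).
pcrit screens alleles with frequency ≤ pcrit (default 0: only fixed alleles
drop); a screen near 1/(2S) is advisable when loci carry many low-copy
alleles, and the parameter-recovery test uses 0.05 at S = 50 for that
reason. Random mating only; the mixed-mating/monogamy corrections and
jackknife CIs are out of scope.

## Differentiation and ordination

Per-locus Jost's D between two sites uses Nei–Chesser unbiased estimators
with harmonic-mean sample size ñ: Ĥ_S = ñ/(ñ−1)(H_S,raw − H_o/2ñ),
Ĥ_T = H_T,raw + Ĥ_S/(ñs) − H_o/(2ñs), D = (s/(s−1))(Ĥ_T−Ĥ_S)/(1−Ĥ_S) with
s = 2. Loci combine by arithmetic mean by default; the harmonic variant
transforms each locus to (1+D)/(1−D), takes the harmonic mean, and
back-transforms. Significance permutes individuals between the pair;
negative combined estimates display as 0 in the matrix.

AMOVA uses the squared allele-count (dosage) distance, which reproduces the
standard codominant genotype distances (identical 0, one shared allele 1,
none shared 4, etc.); missing calls are interpolated as the stratum's
expected dosage 2p̂ (flag to use pooled expectations). Variance components
follow the classical sums-of-squares decomposition with unequal-size
coefficients; one-level runs report F_st, hierarchical runs (sites within
periods) report F_ct, F_sg and F_st = (σ_a+σ_b)/σ_total. Permutation
schemes: individuals among sites for F_st and F_sg, whole sites among
groups for F_ct; single-individual sites are dropped with a warning.

Nei's 1972 distance sums identities over loci, D = −ln(J_xy/√(J_x J_y)),
infinite (flagged) when no alleles are shared. PCoA is Gower
double-centering plus symmetric eigendecomposition; eigenvalues are sorted
stably (ties keep label order), coordinates are scaled by √λ, and percent
explained is computed over positive eigenvalues only, so negative
eigenvalues from non-Euclidean genetic distances neither appear as axes nor
inflate the denominator.

## Spatial distances

Least-cost distances run Dijkstra (scipy sparse csgraph; exact, no
heuristic) on the 8-neighbor graph of water cells, edge weights cell_size
orthogonally and cell_size·√2 diagonally. Points snap to their containing
cell center, or to the nearest water cell within 5 cells (deterministic
tie-break by cell index) if they fall on land. Two points in one cell get
distance 0 and near pairs are quantized to cell multiples — this
underestimate is kept deliberately, because the site-distance rule takes the
element-wise max of cost and Euclidean matrices, letting the Euclidean value
win exactly where quantization bites. Raster input is the ESRI ASCII grid
(any value above a threshold is water; NODATA is land); cost surfaces can
also be built directly from arrays. River distances densify the midline to
~1 m vertices (shapely arc-length interpolation), snap points to the nearest
vertex, and difference cumulative arc lengths, so they are accurate to one
densification step and invariant to line direction.

## Synthetic data

The generator is a forward Wright–Fisher simulation: demes of `true_ne`
diploids on a 1-D stepping-stone chain, each offspring drawing two parents
(each parent from a neighboring deme with probability migration/2 per side,
reduced across an optional mid-chain barrier), loci assorting independently,
and repeat-count mutation (stepwise by default; two-phase with geometric
steps available). Burn-in is `burn_in_factor`×Ne generations from a
monomorphic start. Transect sampling places shoots along two parallel lines
at 5–15 m spacing; with probability c (per-site clonality) a shoot repeats a
genet already placed within 50 m, otherwise it draws an unsampled genet, so
the distinct-genet count is 1 + Binomial(n−1, 1−c) by construction. Missing
calls are injected at the configured rate.

The `paper_like` scenario fixes, once: 13 sites (5 labeled pre, 8 post) of
20–33 shoots, 10 loci, Ne = 100 per deme, mutation 1.25×10⁻³ (θ = 0.5,
giving mostly 2–4 alleles per locus), migration 0.12 with a 0.02 barrier
after the fifth deme (two regional clusters, among-site F_st ≈ 0.10–0.16),
site clonality spanning 0.1–0.88 (site GD from ~0.05 to ~0.9), and 0.3%
missing data. Burn-in uses 5×Ne generations — spot checks against 10×Ne
showed no material difference in diversity or F_st for these parameters.

What passing tests on this generator show: the estimators recover known
truth under the model's own assumptions (neutral unlinked loci, discrete
demes, equilibrium or a single clean crash). What they do not show:
robustness to null alleles, scoring error, selection, overlapping
generations, continuous spatial structure within sites, or real mutation
processes — on real data those remain the analyst's responsibility
(the data-quality module exists to catch the first two).

## Problem sizes used in the test suite

Simulation-backed checks run at deliberately modest sizes chosen as the
smallest that make the statistical assertions stable: LD-Ne recovery uses
20 replicates of Ne = 50 with all 50 individuals sampled; bottleneck
calibration/power uses 20 equilibrium and 20 crashed populations (8 loci,
20 individuals, 300 retained Heq replicates per locus); permutation
calibration uses 1000 exhaustive 5v5 datasets; pipeline runs use a 6-site
scenario with reduced permutation counts. The full published-scale settings
(10,000 randomizations, 9999 permutations) remain the library defaults.

## Known limitations

- pgen has no inbreeding correction; psex is conservative under
  heterozygote excess.
- The missing-data MLG merge rule is a stated surrogate for manual
  curation, not a reconstruction of any particular curator's decisions.
- LD-Ne assumes discrete random-mating populations; continuous distribution
  of individuals biases it downward (a property of the method, noted so
  before/after comparisons rely on the bias canceling).
- Heq conditioning by rejection can fail for extreme k/n combinations; the
  error is explicit rather than silently approximated.
- GeoTIFF rasters are not read; use ESRI ASCII grids or in-memory arrays.
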