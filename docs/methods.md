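# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `lekstruct`, and what its synthetic-data tests do and do
not establish about real data.

## The dosage model

Shallow-coverage genotyping (a few reads per locus per individual) cannot
support hard genotype calls: a heterozygote covered by three reads shows
all-reference reads 1/8 of the time. The package therefore works throughout
with *composite genotypes* (dosages), posterior mean allele counts in
[0, 2], estimated per locus under the hierarchical model

    q ~ Beta(1, 1)
    g_i | q ~ HWE(q) = ((1-q)^2, 2q(1-q), q^2),  i = 1..n
    alt reads_i | g_i ~ Binomial(depth_i, pi_g),  pi_g = (g/2)(1-e) + (1-g/2)e

where q is the population alternate-allele frequency and e the per-read
miscall probability. The frequency acts as a prior on each individual's
genotype, so poorly covered individuals borrow strength from the rest of
the sample, and individuals with *no* reads receive the prior-mean dosage
2·q̄ rather than being dropped.

**Sampler.** Both full conditionals are exact: g_i is a three-way
categorical proportional to likelihood × HWE, and q | g is
Beta(1 + Σg, 1 + Σ(2−g)) by conjugacy. The Gibbs sampler needs no tuning
and mixes in a few sweeps. Genotype probabilities are accumulated as
Rao–Blackwellized averages of the conditional P(g_i | q, reads) at retained
iterations, not as empirical state frequencies — lower Monte-Carlo variance
for the same chain length. Default schedule: 10,000 sweeps after a
6,000-sweep burn-in, thinned by 2 (5,000 retained samples). The acceptance
tests and script use 2,000/500/2; with exact conditionals the posterior
means are pinned to ~1e-3 by a few hundred retained samples, and the two
schedules agree to well under the 0.02 chain-agreement tolerance the test
suite enforces.

Loci are conditionally independent, so the sampler runs in fixed blocks of
2,048 loci with per-block seeds fanned out from the user seed; results do
not depend on block processing order. Measured recovery at study
conditions (140 individuals × 1,000 loci, 5.7X mean coverage, sd 1.7,
e = 0.01): RMSE of q̄ against the realized sample allele frequency
0.012–0.018, dosage–genotype correlation ≈ 0.955. Note the *realized*
frequency is the estimand: comparing q̄ to the Beta parameter that
generated the sample adds the irreducible binomial noise of 2N = 280
sampled gene copies (RMSE floor ≈ 0.026 even with perfect genotypes).

**Filtering cascade** (defaults, applied before the sampler): loci with
reads in ≥ 90 % of individuals; single alternate allele; minor allele
frequency ≥ 5 % on a flat-prior frequency estimate (the boundary is kept —
the rule excludes strictly below-threshold loci); one randomly chosen SNP
per contig. The MAF filter can be re-applied post hoc on posterior means.

## Ordination and geographic structure

PCA is column-centered, never variance-scaled; axis variance fractions are
relative to total variance. The Procrustes correlation between the first
two genetic PCs and lek coordinates uses the symmetric form: both
configurations centered, scaled to unit sum of squares, optimal rotation
(reflection allowed) from the SVD of the cross-product; the statistic is
t = sqrt(1 − m²) = sum of singular values, symmetric in its arguments.
Significance comes from permuting configuration rows (999 permutations).

DAPC retains a chosen number of PCs, then fits a linear discriminant
analysis with *equal group priors* (lek sample sizes here are nearly
balanced). The retained-PC count is chosen by the α-score: observed
group-mean reassignment minus reassignment under randomized labels,
averaged over 20 fresh randomizations, evaluated at *every* candidate PC
count (no spline smoothing — feasible at this scale and one fewer free
parameter). The cluster search runs K-means (seeded, multi-restart) on
retained PC scores and scores each K by BIC(K) = n·ln(WSS_K/n) + K·ln(n),
taking the minimizing K. This BIC only turns upward when additional splits
stop reducing the noise-dimension WSS, which is why the search is run on a
PC space wide enough to include noise axes.

PERMANOVA partitions squared Euclidean distances of the first two
ordination axes: SS_total = (1/n)Σ_{i<j}d²; SS_within = Σ_g(1/n_g)Σ_{i<j∈g}d²;
pseudo-F = (SS_between/(k−1))/(SS_within/(n−k)); p by permuting individual
labels. RDA regresses the centered dosage matrix on predictors (with
intercept) and decomposes the fitted values by SVD; axis fractions are
relative to total response variance. Predictor pairs with |r| > 0.7 warn
but do not fail.

**Pair-sharing relatedness test.** Statistic: mean Euclidean distance (two
score axes) over all pairs sharing a group, lower-tailed. Two nulls are
exposed. The default shuffles the sharing indicator across the pair list
holding the sharing-pair count fixed; because distances of pairs sharing an
individual are positively dependent, this null slightly *overstates* the
null variance and the test errs conservative (measured type-I 0.029–0.038
at n = 30–140). The `labels` alternative permutes individual group labels,
preserving the clique structure of the sharing set; it is exact under
exchangeability (measured type-I 0.045–0.055) and is what the calibration
test asserts. Substantive conclusions from the default null are therefore
conservative, never inflated.

All permutation p-values use the add-one convention
p = (extreme + 1)/(n_perm + 1) and can never be exactly zero.

## Differentiation

Weir–Cockerham θ uses the two-population diploid variance components
(a: among populations, b: among individuals within, c: within individuals)
computed from *fractional* expected genotype counts — per-population sums
of posterior genotype probabilities — so genotype uncertainty propagates
into allele and heterozygote frequencies. A hard-call mode (rounded
dosages) exists for comparison. The multi-locus estimate is the ratio of
sums Σa/Σ(a+b+c) over loci with a nonzero denominator; a pair monomorphic
at every locus is an error, not a zero. Permutation significance pools the
two populations and repartitions individuals at the original sizes.

Nei's (1972) standard distance for biallelic loci: J_X = mean(x²+(1−x)²),
J_XY = mean(xy+(1−x)(1−y)), D = −ln(J_XY/√(J_X·J_Y)); identity zero
(opposite fixation everywhere) is an error since D is infinite. NJ trees
follow Saitou–Nei agglomeration; negative branch lengths are reported as
computed, since clamping is a presentation choice. Outlier trimming removes
a locus if its θ exceeds the chosen quantile of the per-locus θ
distribution in *any* population pair (per-pair thresholds, not pooled).

## Landscape resistance

Habitat suitability s in (0, 1] becomes resistance by the reciprocal 1/s,
rescaled linearly onto [1, R_max] (default R_max = 100) for numeric
stability; the complement 1 − s is available since "inverse" is ambiguous
for a selection surface — the reciprocal is the default because it
penalizes near-zero suitability much harder than linear complementing,
which matches how movement cost is usually modeled. Barrier features are
buffered (default 100 m): buffered cells take the surface maximum
(permeable) or 10⁴ × the maximum (low-permeable).

Least-cost distances run on an 8-connected grid graph with edge cost =
mean of the two cell resistances × cell size (× √2 diagonally), the
convention of GIS least-cost toolboxes; points snap to containing cell
centers. On a uniform surface this overestimates straight-line distance by
at most ~8 % (octagonal metric), and axis-aligned paths are exact. Lek
coordinates in lat/lon are projected to planar km by an equirectangular
projection about the centroid — adequate for a study area tens of km
across.

Mantel r is the Pearson correlation of lower-triangle entries, with
simultaneous row/column permutation of one matrix; MRM regresses the
unfolded response triangle on unfolded predictor triangles with intercept,
permuting the *response* matrix and refitting per replicate. The model
p-value is upper-tailed on R²; coefficient p-values are two-sided on
magnitude from the same replicates. A single-predictor MRM R² equals the
Mantel r² exactly (OLS identity, enforced in tests). Note that distance
predictors derived from the same surface (e.g. habitat LCP and
barrier-surface LCP) can be nearly collinear; MRM warns on condition
numbers above 1e8 and coefficient tests remain valid under the response
permutation scheme.

## Synthetic data: what it does and does not emulate

The generator draws, per locus, an ancestral frequency uniform on the MAF
range (random allele orientation), then complex frequencies from the
Balding–Nichols parameterization Beta(mean p, variance F·p·(1−p)) at
`f_complex`, then lek frequencies likewise at `f_lek` around their complex
frequency; genotypes are Hardy–Weinberg draws at the lek frequency. The
two-level F-model gives the F parameters a direct F_ST interpretation
(recovery enforced: θ̂ ∈ [0.015, 0.025] at F = 0.02 in ≥ 18/20 seeds).
Isolation by distance enters as a shift of complex means along
standardized latitude (`ibd_strength`). Coverage is a locus-level
Normal(mean_coverage, coverage_sd) rate truncated at zero with Poisson
individual depths, reproducing a per-locus mean/sd coverage summary;
missingness arises only mechanically from zero depth.

Defaults are the study conditions: 5 complexes × 2 leks × 14 males = 140
individuals, 27,866 loci, coverage 5.7X (sd 1.7), e = 0.01, with
`f_complex` = 0.02 > `f_lek` = 0.005 and `ibd_strength` = 0.02 — chosen
once so that complex-level differentiation dominates lek-level
differentiation and pairwise θ stays in the small range typical of
fine-scale avian structure. Tests run at reduced locus counts (800–8,000)
chosen as the package's own desk-scale conditions.

Deliberately not emulated: linkage disequilibrium between loci (loci are
independent, so subsampling curves here are slightly optimistic about the
effective information per SNP), read-level errors beyond a symmetric
per-read miscall, reproductive skew within leks (relatedness structure
arises only through drift at the lek level), sex differences, and temporal
structure. Passing tests therefore establish that the *statistics recover
the generating process they assume* and that the pipeline's qualitative
orderings are reproduced under that process — not that any particular
empirical dataset satisfies those assumptions.

## Numerical and degenerate-input conventions

- Beta parameterizations are clamped to means in [0.001, 0.999] before
  drawing; frequencies never hit 0 or 1 exactly.
- Likelihood triples are computed in log space and rescaled to max 1, so
  depth-5000 sites cannot underflow; flat triples mark read absence.
- Zero-variance configurations (Procrustes), constant predictors (RDA),
  singleton groups (DAPC), monomorphic pairs (F_ST), opposite fixation
  (Nei's D), and sub-3-taxon NJ inputs raise errors rather than returning
  NaN.
- Per-stage seeds are fanned out by hashing the stage name into a
  SeedSequence with the master seed, so adding a pipeline stage never
  perturbs other stages' draws; every seed stays below 2^31.
- K-means uses seeded multi-restart (default 10); SVDs come from LAPACK via
  numpy and are deterministic.

## Subsampling analysis

`run_subsampling` draws loci uniformly without replacement per size ×
replicate (default 10 replicates), recomputing PCA → Procrustes-to-geography
and DAPC (lek and complex labels) per subset. Retained PCs per subset
default to min(cap = 20, subset size, n − k − 1); per-subset α-score
re-optimization is possible but not default, since re-tuning per subset is
slow and changes little. `plateau_size` reports the smallest size whose
mean is within a relative tolerance of the largest-size mean. On an
8,000-locus default-signal simulation the replicate sd of the Procrustes
correlation at 250 SNPs exceeds that at 4,000 SNPs and assignment accuracy
rises monotonically with size, the qualitative precision-plateau pattern.

## Known limitations

- The dosage sampler assumes Hardy–Weinberg proportions within the
  population whose frequency is being estimated; pooling strongly
  differentiated groups into one estimation panel biases heterozygote
  probabilities upward (Wahlund effect). The pipeline estimates per dataset,
  matching the single-panel convention of shallow-GBS workflows.
- MRM assumes a linear relation between distance matrices; no transform
  options are built in.
- The least-cost engine keeps the full grid graph in memory; rasters beyond
  a few thousand cells per side would need tiling.
- PERMANOVA and the pair-sharing test operate on the first two ordination
  axes by construction, inheriting whatever structure those axes omit.
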