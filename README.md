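# lekstruct

Fine-scale population-genomic structure analysis for lek-breeding birds.

Lek-mating species such as the greater sage-grouse (*Centrocercus
urophasianus*) combine strong breeding-site fidelity with skewed male mating
success, conditions under which genetic structure can emerge over
surprisingly small geographic scales. Detecting that structure requires
thousands of SNPs genotyped at shallow coverage, statistics that respect
genotype uncertainty, and permutation-based inference at every step.
`lekstruct` implements that analysis chain as a tested, reusable library:

- **Genotype dosages from likelihoods.** A per-locus Gibbs sampler for the
  hierarchical model q ~ Beta(1,1), g_i | q ~ HWE(q), reads | g_i ~
  Binomial(depth, π_g) with π_g = (g/2)(1−ε) + (1−g/2)ε. Genotype
  probabilities are Rao–Blackwellized averages of the exact conditionals;
  the posterior mean genotype ("composite genotype" or dosage) lies in
  [0, 2]. Standard SNP filters (read presence ≥ 90 %, biallelic sites,
  MAF ≥ 5 %, one SNP per contig) are provided.
- **Ordination and geography.** PCA of the dosage matrix; symmetric
  Procrustes correlation t = √(1 − m²) of genetic PCs against lek
  coordinates with a 999-permutation test; DAPC with α-score selection of
  retained PCs and a K-means/BIC cluster search
  (BIC(K) = n·ln(WSS/n) + K·ln n); RDA with geographic predictors;
  PERMANOVA on ordination scores; and a pair-sharing relatedness test.
- **Differentiation.** Pairwise Weir–Cockerham θ from variance components
  (a, b, c) with fractional genotype counts, ratio-of-sums multi-locus
  combination, permutation significance, Nei's standard distance
  D = −ln( J_XY / √(J_X J_Y) ), neighbor-joining trees, and per-pair
  high-F_ST quantile trimming.
- **Landscape resistance.** Habitat-suitability inversion onto [1, R_max],
  100 m barrier buffering at two permeability tiers (max resistance, or
  10⁴ × max), least-cost distances on an 8-connected grid graph, Mantel
  tests, and multiple regression on distance matrices (MRM).
- **Subsampling power analysis.** Precision curves (mean ± sd of the
  Procrustes correlation and DAPC assignment) over random SNP subsets of
  increasing size, with plateau detection.
- **Synthetic data.** A hierarchical lek / lek-complex generator
  (Balding–Nichols F-model at each level, latitudinal frequency gradient,
  locus-level Normal × individual-level Poisson coverage) so the whole
  chain is testable without any data download.

## Worked example

Simulate a study-like population (140 males, 10 leks in 5 complexes),
estimate dosages from 5.7X reads, and measure how well geography explains
genetic structure:

```python
import numpy as np
from lekstruct import SimulationConfig, simulate_dataset, estimate_dosages, McmcSettings
from lekstruct.ordination import run_pca, procrustes_permutation_test, dapc_fit
from lekstruct._utils import project_equirectangular

truth, reads = simulate_dataset(SimulationConfig(n_loci=2000, seed=11))
dosage = estimate_dosages(reads, McmcSettings(n_steps=2000, burn_in=500, thin=2, seed=1))

pcs = run_pca(dosage, n_axes=2)
coords = truth.samples.individual_coordinates()
geo = project_equirectangular(coords[:, 0], coords[:, 1])
proc = procrustes_permutation_test(pcs.scores, geo, n_perm=999, seed=2)
dapc = dapc_fit(dosage, truth.samples.complexes, n_pcs=20)

print(f"PC1/PC2 variance: {pcs.axis_variance_fraction.round(3)}")
print(f"Procrustes t = {proc.observed:.3f}, p = {proc.p_value:.4f}")
print(f"complex-level DAPC assignment: {dapc.reassignment_overall:.1%}")
```

Output:

```
PC1/PC2 variance: [0.019 0.016]
Procrustes t = 0.819, p = 0.0010
complex-level DAPC assignment: 100.0%
```

The first two PCs each carry only ~2 % of the total genotypic variance —
fine-scale structure is subtle at the locus level — yet the Procrustes
correlation of 0.82 shows the 2-D genetic configuration mirrors lek
geography far beyond chance (p = 1/1000), and discriminant analysis
reassigns every bird to its correct lek complex.

A configuration-driven CLI wraps the same stages
(`lekstruct all --config run.yaml --seed 1 --out results/`), writing scores,
distance matrices, newick trees, and JSON test records per stage plus a run
manifest for reproducibility.

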