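"""Genotype likelihoods, SNP filtering, and Bayesian dosage estimation.

The centrepiece is :func:`estimate_dosages`, a per-locus Gibbs sampler for
the hierarchical model in which the population allele frequency q acts as a
prior on genotypes:

    q ~ Beta(1, 1)
    g_i | q ~ HWE(q) = ((1-q)^2, 2q(1-q), q^2)
    reads_i | g_i ~ Binomial with allele-sampling probability
                    pi_g = (g/2)(1-e) + (1-g/2)e

Both conditionals are exact (the Beta prior is conjugate to the genotype
allele counts), so the sampler needs no tuning. Genotype probabilities are
accumulated by Rao–Blackwellized averaging of the per-iteration conditional
P(g_i | q, reads) rather than empirical state frequencies, which lowers
Monte-Carlo variance for a fixed number of retained samples. The posterior
mean genotype ("composite genotype" or dosage) lies in [0, 2]; individuals
with no reads at a locus get a flat likelihood and hence a prior-driven
dosage of approximately 2·q̄.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeLikelihoodTable",
    "DosageMatrix",
    "McmcSettings",
    "genotype_likelihoods_from_counts",
    "filter_presence",
    "filter_biallelic",
    "filter_maf",
    "thin_one_snp_per_contig",
    "estimate_dosages",
]

# Loci are conditionally independent, so the sampler runs in fixed-size
# blocks with seeds fanned out per block: results do not depend on the order
# in which blocks are processed.
_LOCUS_BLOCK = 2048


@dataclass
class GenotypeLikelihoodTable:
    """Per-individual, per-locus likelihoods of the three diploid genotypes.

    ``likelihoods`` has shape (individuals, loci, 3) in the order
    (hom-reference, heterozygote, hom-alternate); triples are relative (any
    common positive scale). ``has_read`` is False where an individual had no
    reads, in which case the triple is flat.
    """

    likelihoods: np.ndarray
    has_read: np.ndarray
    contig_id: np.ndarray
    locus_id: np.ndarray
    alleles: np.ndarray
    n_alt_alleles: np.ndarray
    individual_id: np.ndarray
    read_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if self.likelihoods.ndim != 3 or self.likelihoods.shape[2] != 3:
            raise ValueError("likelihoods must be (individuals, loci, 3)")
        if np.any(self.likelihoods.sum(axis=2) <= 0):
            raise ValueError("a likelihood triple is all zero")

    @property
    def n_individuals(self) -> int:
        return self.likelihoods.shape[0]

    @property
    def n_loci(self) -> int:
        return self.likelihoods.shape[1]

    def subset_loci(self, idx: np.ndarray) -> "GenotypeLikelihoodTable":
        idx = np.asarray(idx)
        return GenotypeLikelihoodTable(
            likelihoods=self.likelihoods[:, idx],
            has_read=self.has_read[:, idx],
            contig_id=self.contig_id[idx],
            locus_id=self.locus_id[idx],
            alleles=self.alleles[idx],
            n_alt_alleles=self.n_alt_alleles[idx],
            individual_id=self.individual_id,
            read_depth=None if self.read_depth is None else self.read_depth[:, idx],
        )

    def flat_prior_allele_freq(self) -> np.ndarray:
        """Quick per-locus alternate-allele frequency from normalized likelihoods.

        Mean of (P1 + 2·P2)/2 across individuals with the triple normalized
        to sum 1 (a flat genotype prior). Used by the MAF filter, which runs
        before the MCMC.
        """
        lik = self.likelihoods
        norm = lik / lik.sum(axis=2, keepdims=True)
        return (norm[:, :, 1] + 2 * norm[:, :, 2]).mean(axis=0) / 2.0


@dataclass
class DosageMatrix:
    """Posterior-mean composite genotypes and genotype probabilities.

    ``dosage[i, l] = P(het) + 2·P(hom-alt)`` in [0, 2];
    ``genotype_probs`` sums to 1 over the last axis;
    ``allele_freq_posterior_mean`` is the posterior mean of q per locus.
    """

    dosage: np.ndarray
    genotype_probs: np.ndarray
    allele_freq_posterior_mean: np.ndarray
    individual_id: np.ndarray = field(default=None)
    locus_id: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if np.any(self.dosage < -1e-9) or np.any(self.dosage > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def subset_loci(self, idx: np.ndarray) -> "DosageMatrix":
        idx = np.asarray(idx)
        return DosageMatrix(
            self.dosage[:, idx],
            self.genotype_probs[:, idx],
            self.allele_freq_posterior_mean[idx],
            self.individual_id,
            None if self.locus_id is None else self.locus_id[idx],
        )

    @classmethod
    def from_genotypes(cls, genotypes: np.ndarray, individual_id=None, locus_id=None):
        """Exact dosages from known integer genotypes (probability 1 calls)."""
        g = np.asarray(genotypes)
        probs = np.zeros(g.shape + (3,))
        for k in range(3):
            probs[..., k] = g == k
        return cls(g.astype(float), probs, g.mean(axis=0) / 2.0, individual_id, locus_id)


@dataclass
class McmcSettings:
    """Gibbs-sampler schedule. Defaults: 10,000 steps after a 6,000-step
    burn-in, thinning every other step (5,000 retained samples)."""

    n_steps: int = 10000
    burn_in: int = 6000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if self.burn_in >= self.n_steps:
            raise ValueError("burn_in must be smaller than n_steps")


def genotype_likelihoods_from_counts(ref_reads, alt_reads, error_rate: float) -> np.ndarray:
    """Binomial-read-model likelihood triple for genotypes 0/1/2.

    L(g) ∝ pi_g^alt · (1 − pi_g)^ref with pi_g = (g/2)(1−e) + (1−g/2)e.
    The binomial coefficient is constant across g and dropped. Zero total
    reads gives a flat triple. Broadcasts over array inputs; the result has
    shape ``broadcast(ref, alt).shape + (3,)``.
    """
    ref = np.asarray(ref_reads, dtype=float)
    alt = np.asarray(alt_reads, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be nonnegative")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    ref, alt = np.broadcast_arrays(ref, alt)
    pis = np.array([error_rate, 0.5, 1.0 - error_rate])
    # work in log space to avoid underflow at high depth, then rescale
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = alt[..., None] * np.log(pis) + ref[..., None] * np.log(1.0 - pis)
    loglik = np.where((ref + alt)[..., None] == 0, 0.0, loglik)
    loglik -= loglik.max(axis=-1, keepdims=True)
    return np.exp(loglik)


def filter_presence(
    table: GenotypeLikelihoodTable, min_fraction: float = 0.9
) -> GenotypeLikelihoodTable:
    """Retain loci where at least ``min_fraction`` of individuals have a read."""
    frac = table.has_read.mean(axis=0)
    keep = np.flatnonzero(frac >= min_fraction)
    if keep.size == 0:
        warnings.warn("presence filter removed every locus", stacklevel=2)
    return table.subset_loci(keep)


def filter_biallelic(table: GenotypeLikelihoodTable) -> GenotypeLikelihoodTable:
    """Drop loci with more than one alternate allele."""
    keep = np.flatnonzero(table.n_alt_alleles <= 1)
    return table.subset_loci(keep)


def filter_maf(obj, min_maf: float = 0.05, dosage: DosageMatrix | None = None):
    """Retain loci with minor allele frequency ≥ ``min_maf``.

    The boundary is kept: the exclusion rule is frequencies strictly below
    the threshold. For a likelihood table the frequency is the flat-prior
    estimate (the filter runs before the MCMC); for a DosageMatrix the
    posterior mean is used.
    """
    if isinstance(obj, GenotypeLikelihoodTable):
        q = obj.flat_prior_allele_freq()
    elif isinstance(obj, DosageMatrix):
        q = obj.allele_freq_posterior_mean
    else:
        raise TypeError("expected GenotypeLikelihoodTable or DosageMatrix")
    maf = np.minimum(q, 1.0 - q)
    keep = np.flatnonzero(maf >= min_maf - 1e-12)
    return obj.subset_loci(keep)


def thin_one_snp_per_contig(table: GenotypeLikelihoodTable, seed: int = 0):
    """Keep exactly one SNP per contig, chosen uniformly at random.

    Deterministic given the seed; the retained loci keep their original
    relative order.
    """
    rng = np.random.default_rng(seed)
    chosen = []
    order = {}
    for j, contig in enumerate(table.contig_id):
        order.setdefault(contig, []).append(j)
    for contig in order:
        idx = order[contig]
        chosen.append(idx[rng.integers(len(idx))])
    return table.subset_loci(np.sort(chosen))


def _gibbs_block(
    lik: np.ndarray, settings: McmcSettings, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Run the Gibbs sampler on a (individuals, loci, 3) likelihood block.

    Returns (genotype_probs, q_posterior_mean) for the block. All loci in the
    block advance together; randomness is vectorized across individuals and
    loci each sweep.
    """
    rng = np.random.default_rng(seed)
    n, nl, _ = lik.shape
    # initialize q from the flat-prior frequency estimate
    norm = lik / lik.sum(axis=2, keepdims=True)
    q = np.clip((norm[:, :, 1] + 2 * norm[:, :, 2]).mean(axis=0) / 2.0, 0.01, 0.99)

    prob_accum = np.zeros((n, nl, 3))
    q_accum = np.zeros(nl)
    n_kept = 0
    total = settings.burn_in + settings.n_steps
    hwe = np.empty((nl, 3))
    for step in range(total):
        hwe[:, 0] = (1 - q) ** 2
        hwe[:, 1] = 2 * q * (1 - q)
        hwe[:, 2] = q**2
        post = lik * hwe[None, :, :]
        post /= post.sum(axis=2, keepdims=True)
        u = rng.random((n, nl))
        g = (u > post[:, :, 0]).astype(np.int64) + (
            u > post[:, :, 0] + post[:, :, 1]
        ).astype(np.int64)
        alt_count = g.sum(axis=0)
        q = rng.beta(1.0 + alt_count, 1.0 + 2 * n - alt_count)
        kept = step >= settings.burn_in and (step - settings.burn_in) % settings.thin == 0
        if kept:
            prob_accum += post  # Rao-Blackwellized conditional
            q_accum += q
            n_kept += 1
    return prob_accum / n_kept, q_accum / n_kept


def estimate_dosages(
    table: GenotypeLikelihoodTable, settings: McmcSettings | None = None
) -> DosageMatrix:
    """Posterior genotype probabilities and composite dosages per locus.

    Per-locus Gibbs sampler alternating (i) genotype draws proportional to
    likelihood × HWE(q) and (ii) the conjugate update
    q ~ Beta(1 + Σg, 1 + Σ(2−g)). Loci are processed in fixed blocks with
    per-block seeds fanned out from ``settings.seed``, so results are
    independent of processing order.
    """
    if settings is None:
        settings = McmcSettings()
    nl = table.n_loci
    n_blocks = (nl + _LOCUS_BLOCK - 1) // _LOCUS_BLOCK
    block_seeds = np.random.SeedSequence(settings.seed).generate_state(max(n_blocks, 1))
    probs = np.empty((table.n_individuals, nl, 3))
    qbar = np.empty(nl)
    for b in range(n_blocks):
        sl = slice(b * _LOCUS_BLOCK, min((b + 1) * _LOCUS_BLOCK, nl))
        probs[:, sl], qbar[sl] = _gibbs_block(
            table.likelihoods[:, sl], settings, int(block_seeds[b])
        )
    dosage = probs[:, :, 1] + 2 * probs[:, :, 2]
    return DosageMatrix(
        dosage, probs, qbar, table.individual_id, table.locus_id
    )
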