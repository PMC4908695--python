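import numpy as np
import pytest

from lekstruct.genotypes import DosageMatrix, GenotypeLikelihoodTable
from lekstruct.simulate import SimulationConfig, simulate_hierarchical_frequencies


@pytest.fixture(scope="session")
def hierarchical_truth():
    """Small hierarchical population: 4 complexes x 2 leks x 10 individuals."""
    cfg = SimulationConfig(
        n_complexes=4,
        leks_per_complex=2,
        individuals_per_lek=10,
        n_loci=800,
        f_complex=0.03,
        f_lek=0.008,
        ibd_strength=0.02,
        seed=42,
    )
    return simulate_hierarchical_frequencies(cfg)


@pytest.fixture(scope="session")
def hierarchical_dosage(hierarchical_truth):
    """Exact dosages built from the true genotypes (probability-1 calls)."""
    t = hierarchical_truth
    return DosageMatrix.from_genotypes(
        t.genotypes, individual_id=t.samples.individuals
    )


def make_likelihood_table(likelihoods, has_read=None, contigs=None, n_alt=None):
    """Hand-built GenotypeLikelihoodTable for filter tests."""
    lik = np.asarray(likelihoods, dtype=float)
    n, nl, _ = lik.shape
    if has_read is None:
        has_read = ~np.all(np.abs(lik - lik[:, :, [0]]) < 1e-12, axis=2)
    if contigs is None:
        contigs = np.array([f"c{j}" for j in range(nl)])
    if n_alt is None:
        n_alt = np.ones(nl, dtype=int)
    return GenotypeLikelihoodTable(
        likelihoods=lik,
        has_read=np.asarray(has_read),
        contig_id=np.asarray(contigs),
        locus_id=np.array([f"s{j}" for j in range(nl)]),
        alleles=np.array([("A", "G")] * nl, dtype=object),
        n_alt_alleles=np.asarray(n_alt),
        individual_id=np.array([f"i{k}" for k in range(n)]),
    )
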