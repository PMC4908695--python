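"""Pairwise differentiation: Weir–Cockerham F_ST, Nei's D, NJ trees.

F_ST uses the two-population diploid Weir–Cockerham variance components
(a: among populations, b: among individuals within populations, c: within
individuals), with the multi-locus estimate taken as the ratio of sums
Σa / Σ(a+b+c) over loci with a defined denominator. Genotype uncertainty
enters through fractional expected genotype counts computed from posterior
genotype probabilities; a hard-call mode (rounded dosages) is available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .containers import PairwiseLekMatrix, PermutationTestResult
from .genotypes import DosageMatrix

__all__ = [
    "LocusFstTable",
    "genotype_prob_array",
    "weir_cockerham_fst",
    "pairwise_fst_matrix",
    "fst_permutation_test",
    "locus_fst_table",
    "nei_distance",
    "nei_distance_matrix",
    "neighbor_joining",
    "outlier_trim",
]


def genotype_prob_array(obj, mode: str = "fractional") -> np.ndarray:
    """(individuals, loci, 3) genotype probabilities from dosages or calls.

    ``fractional`` keeps posterior probabilities; ``hard`` rounds the dosage
    to the nearest integer genotype (probability-1 calls). Plain integer
    genotype arrays are accepted directly.
    """
    if isinstance(obj, DosageMatrix):
        if mode == "fractional":
            return obj.genotype_probs
        g = np.clip(np.rint(obj.dosage), 0, 2).astype(int)
    else:
        g = np.asarray(obj)
        if g.ndim == 3 and g.shape[2] == 3:
            return np.asarray(g, dtype=float)
        g = np.clip(np.rint(g), 0, 2).astype(int)
    probs = np.zeros(g.shape + (3,))
    for k in range(3):
        probs[..., k] = g == k
    return probs


def _wc_components(probs1: np.ndarray, probs2: np.ndarray):
    """Per-locus Weir–Cockerham variance components a, b, c for two populations.

    ``probs*`` are (individuals, loci, 3) genotype probabilities; expected
    genotype counts are their per-population sums (fractional counts).
    """
    r = 2
    n_i = np.array([probs1.shape[0], probs2.shape[0]], dtype=float)
    # allele frequency and heterozygote frequency per population per locus
    p = np.stack(
        [
            (probs1[:, :, 1].sum(0) + 2 * probs1[:, :, 2].sum(0)) / (2 * n_i[0]),
            (probs2[:, :, 1].sum(0) + 2 * probs2[:, :, 2].sum(0)) / (2 * n_i[1]),
        ]
    )  # (2, loci)
    h = np.stack([probs1[:, :, 1].mean(0), probs2[:, :, 1].mean(0)])

    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p).sum(0) / (r * nbar)
    s2 = (n_i[:, None] * (p - pbar) ** 2).sum(0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h).sum(0) / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


@dataclass
class LocusFstTable:
    """Per-locus theta and variance components for a set of population pairs."""

    pairs: list  # list of (label_a, label_b)
    theta: np.ndarray  # (n_pairs, loci), NaN where the denominator is zero
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def multilocus_theta(self, pair_index: int) -> float:
        denom = (self.a + self.b + self.c)[pair_index]
        ok = denom != 0
        return float(self.a[pair_index, ok].sum() / denom[ok].sum())


def weir_cockerham_fst(obj, pop_labels, pair, mode: str = "fractional"):
    """Per-locus and multi-locus Weir–Cockerham theta for one population pair.

    Returns ``(theta_per_locus, theta_multilocus)``; per-locus values are NaN
    where a + b + c = 0 (monomorphic in the pair), and such loci are skipped
    in the ratio-of-sums multi-locus estimate.
    """
    probs = genotype_prob_array(obj, mode=mode)
    pop_labels = np.asarray(pop_labels)
    m1, m2 = pop_labels == pair[0], pop_labels == pair[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("both populations need at least two individuals")
    a, b, c = _wc_components(probs[m1], probs[m2])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    ok = denom != 0
    if not ok.any():
        raise ValueError(f"pair {pair} is monomorphic at every locus; theta undefined")
    return theta, float(a[ok].sum() / denom[ok].sum())


def pairwise_fst_matrix(obj, pop_labels, mode: str = "fractional") -> PairwiseLekMatrix:
    """Symmetric matrix of multi-locus theta for all population pairs."""
    pop_labels = np.asarray(pop_labels)
    uniq = list(dict.fromkeys(pop_labels))
    n = len(uniq)
    vals = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        _, th = weir_cockerham_fst(obj, pop_labels, (uniq[i], uniq[j]), mode=mode)
        vals[i, j] = vals[j, i] = th
    return PairwiseLekMatrix(uniq, vals, kind="fst")


def fst_permutation_test(
    obj, pop_labels, pair, n_perm: int = 999, seed: int = 0, mode: str = "fractional"
) -> PermutationTestResult:
    """Upper-tail permutation test of multi-locus theta for one pair.

    Individuals of the two populations are pooled and randomly repartitioned
    at the original sample sizes each replicate.
    """
    probs = genotype_prob_array(obj, mode=mode)
    pop_labels = np.asarray(pop_labels)
    m1, m2 = pop_labels == pair[0], pop_labels == pair[1]
    idx = np.flatnonzero(m1 | m2)
    n1 = int(m1.sum())
    sub = probs[idx]

    def theta_of(split):
        a, b, c = _wc_components(sub[split], sub[~split])
        denom = a + b + c
        ok = denom != 0
        return a[ok].sum() / denom[ok].sum() if ok.any() else np.nan

    obs_split = np.isin(idx, np.flatnonzero(m1))
    obs = theta_of(obs_split)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    base = np.zeros(len(idx), dtype=bool)
    base[:n1] = True
    for p in range(n_perm):
        null[p] = theta_of(rng.permutation(base))
    return PermutationTestResult.from_null(obs, null, tail="upper")


def locus_fst_table(obj, pop_labels, mode: str = "fractional") -> LocusFstTable:
    """Per-locus theta and components for every population pair."""
    probs = genotype_prob_array(obj, mode=mode)
    pop_labels = np.asarray(pop_labels)
    uniq = list(dict.fromkeys(pop_labels))
    pairs = list(combinations(uniq, 2))
    nl = probs.shape[1]
    a = np.empty((len(pairs), nl))
    b = np.empty((len(pairs), nl))
    c = np.empty((len(pairs), nl))
    theta = np.empty((len(pairs), nl))
    for k, (pa, pb) in enumerate(pairs):
        aa, bb, cc = _wc_components(probs[pop_labels == pa], probs[pop_labels == pb])
        a[k], b[k], c[k] = aa, bb, cc
        denom = aa + bb + cc
        with np.errstate(invalid="ignore", divide="ignore"):
            theta[k] = np.where(denom != 0, aa / denom, np.nan)
    return LocusFstTable(pairs, theta, a, b, c)


def nei_distance(freq_x: np.ndarray, freq_y: np.ndarray) -> float:
    """Nei's (1972) standard genetic distance from per-locus alternate-allele
    frequencies of two populations.

    With biallelic frequencies x and 1−x: J_X = mean(x² + (1−x)²), J_XY =
    mean(x·y + (1−x)(1−y)); identity I = J_XY / sqrt(J_X·J_Y); D = −ln I.
    """
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    jx = np.mean(x**2 + (1 - x) ** 2)
    jy = np.mean(y**2 + (1 - y) ** 2)
    jxy = np.mean(x * y + (1 - x) * (1 - y))
    i = jxy / np.sqrt(jx * jy)
    if i <= 0:
        raise ValueError("genetic identity is zero; D is infinite")
    return float(-np.log(min(i, 1.0)))


def nei_distance_matrix(pop_freqs: np.ndarray, labels) -> PairwiseLekMatrix:
    """Pairwise Nei's D from a (populations, loci) frequency array."""
    labels = list(labels)
    n = len(labels)
    vals = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        vals[i, j] = vals[j, i] = nei_distance(pop_freqs[i], pop_freqs[j])
    return PairwiseLekMatrix(labels, vals, kind="nei_d")


def neighbor_joining(matrix: PairwiseLekMatrix) -> str:
    """Neighbor-joining tree (Saitou–Nei) serialized as newick.

    Negative branch lengths are reported as computed, not clamped.
    """
    if matrix.n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    dm = DistanceMatrix(matrix.values, ids=[str(l) for l in matrix.labels])
    tree = _skbio_nj(dm, neg_as_zero=False)
    return str(tree).strip()


def outlier_trim(locus_fst: LocusFstTable, quantile: float) -> np.ndarray:
    """Indices of loci retained after per-pair high-F_ST quantile trimming.

    For each population pair the threshold is the given quantile of that
    pair's per-locus theta distribution (NaNs ignored); a locus is removed
    if it exceeds the threshold in ANY pair.
    """
    if not (0 <= quantile <= 1):
        raise ValueError("quantile must be in [0, 1]")
    nl = locus_fst.theta.shape[1]
    remove = np.zeros(nl, dtype=bool)
    if quantile < 1.0:
        for k in range(locus_fst.theta.shape[0]):
            row = locus_fst.theta[k]
            ok = ~np.isnan(row)
            if not ok.any():
                continue
            thr = np.quantile(row[ok], quantile)
            remove |= ok & (row > thr)
    return np.flatnonzero(~remove)
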