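"""Ordination and multivariate structure tests.

PCA on composite genotypes, symmetric Procrustes rotation of genetic axes
onto geography, DAPC with alpha-score selection of retained PCs and a
K-means/BIC cluster search, redundancy analysis with geographic predictors,
PERMANOVA on ordination scores, and a pair-sharing relatedness permutation
test. All permutation p-values use the add-one convention
(p = (extreme + 1)/(n_perm + 1)) and are therefore never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import PermutationTestResult
from .genotypes import DosageMatrix

__all__ = [
    "OrdinationResult",
    "DapcModel",
    "run_pca",
    "procrustes_correlation",
    "procrustes_permutation_test",
    "pair_sharing_distance_test",
    "dapc_fit",
    "optimize_a_score",
    "find_clusters",
    "rda_fit",
    "permanova",
]


def _as_matrix(obj) -> np.ndarray:
    if isinstance(obj, DosageMatrix):
        return obj.dosage
    return np.asarray(obj, dtype=float)


@dataclass
class OrdinationResult:
    """Individual scores with per-axis variance fractions."""

    scores: np.ndarray
    axis_variance_fraction: np.ndarray
    loadings: np.ndarray | None = None
    method: str = "PCA"

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


@dataclass
class DapcModel:
    """Discriminant analysis of retained principal components."""

    n_pcs_retained: int
    discriminant_functions: np.ndarray  # (n_pcs, n_df) scalings
    df_scores: np.ndarray  # (n, n_df)
    assignment_probs: np.ndarray  # (n, k)
    eigenvalue_fractions: np.ndarray  # per DF share of discriminable variance
    group_labels: np.ndarray
    predicted: np.ndarray = field(repr=False, default=None)
    pc_scores: np.ndarray = field(repr=False, default=None)

    @property
    def reassignment_overall(self) -> float:
        return float(np.mean(self.predicted == self._true_labels))

    def reassignment_per_group(self) -> dict:
        out = {}
        for g in self.group_labels:
            mask = self._true_labels == g
            out[g] = float(np.mean(self.predicted[mask] == g))
        return out

    # set by dapc_fit
    _true_labels: np.ndarray = field(repr=False, default=None)


def run_pca(dosage, n_axes: int = 2) -> OrdinationResult:
    """PCA of the individuals × loci matrix (columns mean-centered, unscaled).

    Axes are ordered by decreasing variance; the variance fraction of an
    axis is its variance over the total variance of the centered matrix.
    Requesting more axes than ``min(n - 1, loci)`` truncates with a warning.
    """
    x = _as_matrix(dosage)
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    max_axes = min(n, x.shape[1])
    if n_axes > max_axes:
        warnings.warn(
            f"requested {n_axes} axes but only {max_axes} available; truncating",
            stacklevel=2,
        )
        n_axes = max_axes
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float(np.sum(s**2))
    scores = u[:, :n_axes] * s[:n_axes]
    frac = (s[:n_axes] ** 2 / total) if total > 0 else np.zeros(n_axes)
    if total == 0:
        scores = np.zeros((n, n_axes))
    return OrdinationResult(scores, frac, loadings=vt[:n_axes].T, method="PCA")


def _center_scale(config: np.ndarray) -> np.ndarray:
    c = config - config.mean(axis=0)
    norm = np.sqrt(np.sum(c**2))
    if norm == 0:
        raise ValueError("degenerate (zero-variance) configuration")
    return c / norm


def _sum_singular_2x2(m: np.ndarray) -> np.ndarray:
    """Sum of singular values of stacked 2x2 matrices (..., 2, 2).

    Uses (s1 + s2)^2 = ||M||_F^2 + 2|det M|.
    """
    fro2 = np.sum(m**2, axis=(-2, -1))
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    return np.sqrt(np.maximum(fro2 + 2 * np.abs(det), 0.0))


def procrustes_correlation(genetic_config, geo_config) -> float:
    """Symmetric Procrustes correlation t = sqrt(1 − m²) of two 2-D configurations.

    Both configurations are centered and scaled to unit sum of squares; the
    optimal rotation (reflection allowed) comes from the SVD of the
    cross-product, giving m² = 1 − (Σ singular values)². Symmetric in its
    arguments.
    """
    x = _center_scale(np.asarray(genetic_config, dtype=float))
    y = _center_scale(np.asarray(geo_config, dtype=float))
    if x.shape != y.shape or x.shape[1] != 2:
        raise ValueError("configurations must be matching (n, 2) arrays")
    t = float(_sum_singular_2x2(x.T @ y))
    return min(t, 1.0)


def procrustes_permutation_test(
    genetic_config, geo_config, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Upper-tail permutation test of the Procrustes correlation.

    Each replicate permutes the rows of one configuration (row permutation
    leaves centering and scale intact, so only the cross-product changes).
    """
    x = _center_scale(np.asarray(genetic_config, dtype=float))
    y = _center_scale(np.asarray(geo_config, dtype=float))
    obs = min(float(_sum_singular_2x2(x.T @ y)), 1.0)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    yp = y[perms]  # (P, n, 2)
    m = np.einsum("ni,pnj->pij", x, yp)
    null = np.minimum(_sum_singular_2x2(m), 1.0)
    return PermutationTestResult.from_null(obs, null, tail="upper")


def pair_sharing_distance_test(
    scores, labels, n_perm: int = 1000, seed: int = 0, null_method: str = "pairs"
) -> PermutationTestResult:
    """Do individuals sharing a group sit closer in score space than chance?

    Statistic: mean Euclidean distance (first two score axes) over all
    individual pairs that share a group. The default null (``pairs``)
    reassigns the sharing indicator at random among pairs, holding the
    number of sharing pairs fixed. Because pair distances sharing an
    individual are dependent, ``labels`` is offered as an alternative that
    permutes individual group labels instead (preserving the clique
    structure of the sharing set). The test is lower-tailed: elevated
    within-group relatedness means smaller distances.
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    d = pdist(scores)
    n = len(labels)
    ii, jj = np.triu_indices(n, k=1)
    share = labels[ii] == labels[jj]
    k = int(share.sum())
    if k == 0:
        raise ValueError("no pairs share a group")
    obs = float(d[share].mean())
    rng = np.random.default_rng(seed)
    if null_method == "pairs":
        m = len(d)
        picks = np.argsort(rng.random((n_perm, m)), axis=1)[:, :k]
        null = d[picks].mean(axis=1)
    elif null_method == "labels":
        null = np.empty(n_perm)
        for p in range(n_perm):
            lp = rng.permutation(labels)
            null[p] = d[lp[ii] == lp[jj]].mean()
    else:
        raise ValueError("null_method must be 'pairs' or 'labels'")
    return PermutationTestResult.from_null(obs, null, tail="lower")


def _check_groups(labels: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        bad = uniq[counts < 2]
        raise ValueError(f"groups with a single member: {list(bad)}")
    return uniq


def dapc_fit(dosage, labels, n_pcs: int) -> DapcModel:
    """DAPC: PCA reduction to ``n_pcs`` axes, then linear discriminant analysis.

    Group assignment probabilities come from the discriminant densities with
    equal group priors. Reassignment proportions (overall and per group) are
    available on the returned model.
    """
    x = _as_matrix(dosage)
    labels = np.asarray(labels)
    uniq = _check_groups(labels)
    max_pcs = min(x.shape[0] - 1, x.shape[1])
    if n_pcs > max_pcs or n_pcs < 1:
        raise ValueError(f"n_pcs must be in [1, {max_pcs}]")
    pca = run_pca(x, n_axes=n_pcs)
    k = len(uniq)
    lda = LinearDiscriminantAnalysis(
        solver="eigen", priors=np.full(k, 1.0 / k), n_components=min(k - 1, n_pcs)
    )
    lda.fit(pca.scores, labels)
    df_scores = lda.transform(pca.scores)
    probs = lda.predict_proba(pca.scores)
    evr = getattr(lda, "explained_variance_ratio_", np.ones(df_scores.shape[1]))
    model = DapcModel(
        n_pcs_retained=n_pcs,
        discriminant_functions=lda.scalings_[:, : df_scores.shape[1]],
        df_scores=df_scores,
        assignment_probs=probs,
        eigenvalue_fractions=np.asarray(evr)[: df_scores.shape[1]],
        group_labels=lda.classes_,
        predicted=lda.predict(pca.scores),
        pc_scores=pca.scores,
    )
    model._true_labels = labels
    return model


def _mean_group_reassignment(model_predicted, labels, uniq) -> float:
    vals = [np.mean(model_predicted[labels == g] == g) for g in uniq]
    return float(np.mean(vals))


def optimize_a_score(
    dosage,
    labels,
    candidates=None,
    n_replicates: int = 20,
    seed: int = 0,
) -> dict:
    """Choose the number of retained PCs by the alpha-score.

    For each candidate PC count, alpha = (group-mean observed reassignment)
    − (group-mean reassignment with randomized labels), averaged over
    ``n_replicates`` fresh randomizations. Every candidate is evaluated
    directly (no smoothing). Returns the argmax candidate with the replicate
    mean and sd of its alpha-score and the full per-candidate table.
    """
    x = _as_matrix(dosage)
    labels = np.asarray(labels)
    uniq = _check_groups(labels)
    max_pcs = min(x.shape[0] - 1, x.shape[1])
    if candidates is None:
        candidates = list(range(1, min(max_pcs, 30) + 1))
    candidates = list(candidates)
    if max(candidates) > max_pcs:
        raise ValueError("candidate PC count exceeds valid bound")
    rng = np.random.default_rng(seed)
    table = {}
    for n_pcs in candidates:
        model = dapc_fit(x, labels, n_pcs)
        obs = _mean_group_reassignment(model.predicted, labels, uniq)
        reps = np.empty(n_replicates)
        for r in range(n_replicates):
            rand_labels = rng.permutation(labels)
            try:
                rmodel = dapc_fit(x, rand_labels, n_pcs)
                rand = _mean_group_reassignment(
                    rmodel.predicted, rand_labels, np.unique(rand_labels)
                )
            except ValueError:  # a randomized group ended up with one member
                rand = 1.0 / len(uniq)
            reps[r] = obs - rand
        table[n_pcs] = (float(reps.mean()), float(reps.std(ddof=1)))
    best = max(table, key=lambda c: table[c][0])
    return {
        "best_n_pcs": best,
        "alpha_mean": table[best][0],
        "alpha_sd": table[best][1],
        "n_replicates": n_replicates,
        "table": table,
    }


def find_clusters(
    dosage, k_max: int, n_pcs_for_kmeans: int = 20, seed: int = 0, n_restarts: int = 10
) -> dict:
    """K-means cluster search on retained PC scores scored by BIC.

    BIC(K) = n·ln(WSS_K/n) + K·ln(n), where WSS is the within-cluster sum of
    squares; the best K minimizes BIC. K runs from 1 to ``k_max``.
    """
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    x = _as_matrix(dosage)
    n = x.shape[0]
    n_pcs = min(n_pcs_for_kmeans, n - 1, x.shape[1])
    scores = run_pca(x, n_axes=n_pcs).scores
    bic = {}
    assignments = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(np.sum((scores - scores.mean(axis=0)) ** 2))
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(scores)
            wss = float(km.inertia_)
            labels = km.labels_
        bic[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        assignments[k] = labels
    best_k = min(bic, key=bic.get)
    return {"bic": bic, "best_k": best_k, "assignments": assignments[best_k]}


def rda_fit(dosage, predictors) -> OrdinationResult:
    """Redundancy analysis: PCA of the response fitted onto the predictors.

    The response columns are centered; fitted values from the least-squares
    projection onto the predictors (with intercept) are decomposed by SVD.
    Axis variance fractions are relative to the *total* response variance,
    so constrained axes report the share of genotypic variance explained.
    """
    y = _as_matrix(dosage)
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if np.any(np.std(x, axis=0) == 0):
        raise ValueError("constant predictor")
    if x.shape[1] > 1:
        r = np.corrcoef(x, rowvar=False)
        mx = np.max(np.abs(r[np.triu_indices_from(r, k=1)]))
        if mx > 0.7:
            warnings.warn(
                f"predictor |correlation| = {mx:.2f} exceeds the 0.7 advisory",
                stacklevel=2,
            )
    yc = y - y.mean(axis=0)
    design = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(design, yc, rcond=None)
    fitted = design @ beta
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = min(x.shape[1], len(s))
    total = float(np.sum(yc**2))
    frac = s[:n_axes] ** 2 / total if total > 0 else np.zeros(n_axes)
    return OrdinationResult(
        u[:, :n_axes] * s[:n_axes], frac, loadings=vt[:n_axes].T, method="RDA"
    )


def _permanova_ss(d2: np.ndarray, onehot: np.ndarray, counts: np.ndarray):
    """SS_within for stacked one-hot label matrices (P, n, k)."""
    # sum_{i<j in g} d2 = z' D2 z / 2 per group
    zd = np.einsum("pnk,nm->pmk", onehot, d2)
    per_group = np.einsum("pmk,pmk->pk", zd, onehot) / 2.0
    return (per_group / counts).sum(axis=1)


def permanova(scores, labels, n_perm: int = 999, seed: int = 0):
    """PERMANOVA on Euclidean distances of (typically two) ordination axes.

    SS_total = (1/n)Σ_{i<j} d²; SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²;
    pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k)); R² = SS_between/SS_total.
    Significance by permuting individual labels. Returns
    (R², pseudo-F, PermutationTestResult on pseudo-F).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts == 0):
        raise ValueError("empty group")
    n, k = len(labels), len(uniq)
    diff = scores[:, None, :] - scores[None, :, :]
    d2 = np.sum(diff**2, axis=2)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    eye = np.eye(k)
    onehot_obs = eye[inv][None]
    ss_within = float(_permanova_ss(d2, onehot_obs, counts)[0])
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    f_obs = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(inv) for _ in range(n_perm)])
    onehot = eye[perms]  # (P, n, k)
    ssw = _permanova_ss(d2, onehot, counts)
    ssb = ss_total - ssw
    with np.errstate(divide="ignore"):
        f_null = (ssb / (k - 1)) / (ssw / (n - k))
    result = PermutationTestResult.from_null(f_obs, f_null, tail="upper")
    return float(r2), float(f_obs), result
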