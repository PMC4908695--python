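"""Landscape resistance, least-cost distances, and distance-matrix models.

A habitat-suitability raster is inverted into a resistance surface, linear
barriers (roads, power lines) are buffered onto it at one of two
permeability tiers, and pairwise least-cost distances among leks are
computed on an 8-connected grid graph (edge cost = mean of the two cell
resistances × cell size, × sqrt(2) for diagonal moves). Associations between
genetic distance and geographic / cost distances are tested with Mantel
tests and multi-predictor regression on distance matrices (MRM).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from ._utils import haversine_km
from .containers import BarrierSet, PairwiseLekMatrix, PermutationTestResult, ResistanceRaster

__all__ = [
    "invert_suitability",
    "apply_barriers",
    "least_cost_distances",
    "geographic_distances",
    "mantel_test",
    "mrm",
]

LOW_PERMEABILITY_FACTOR = 1e4  # barrier four orders of magnitude above max resistance


def invert_suitability(
    suitability: ResistanceRaster, r_max: float = 100.0, mode: str = "reciprocal"
) -> ResistanceRaster:
    """Turn a habitat-suitability raster in (0, 1] into a resistance surface.

    ``reciprocal`` (default) takes 1/suitability; ``complement`` takes
    1 − suitability. Either way the result is rescaled linearly onto
    [1, r_max], so resistance decreases monotonically with suitability and a
    constant input becomes the constant surface 1.
    """
    vals = suitability.values
    valid = suitability.valid_mask()
    if np.any(vals[valid] <= 0) or np.any(vals[valid] > 1):
        raise ValueError("suitability values must lie in (0, 1]")
    if mode == "reciprocal":
        raw = 1.0 / vals[valid]
    elif mode == "complement":
        raw = 1.0 - vals[valid]
    else:
        raise ValueError("mode must be 'reciprocal' or 'complement'")
    lo, hi = raw.min(), raw.max()
    out = np.full_like(vals, suitability.nodata)
    if hi > lo:
        out[valid] = 1.0 + (r_max - 1.0) * (raw - lo) / (hi - lo)
    else:
        out[valid] = 1.0
    return ResistanceRaster(
        out, suitability.origin, suitability.cell_size, suitability.nodata
    )


def _segment_distance(px, py, seg) -> np.ndarray:
    """Distance from points to a segment (x1, y1, x2, y2)."""
    x1, y1, x2, y2 = seg
    dx, dy = x2 - x1, y2 - y1
    len2 = dx * dx + dy * dy
    if len2 == 0:
        return np.hypot(px - x1, py - y1)
    t = np.clip(((px - x1) * dx + (py - y1) * dy) / len2, 0.0, 1.0)
    return np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def apply_barriers(resistance: ResistanceRaster, barriers: BarrierSet) -> ResistanceRaster:
    """Overwrite cells within the buffer of any barrier segment.

    Buffered cells get the maximum resistance of the surface (permeable
    mode) or that maximum × 10⁴ (low-permeable mode); all other cells are
    unchanged. An empty barrier set is the identity.
    """
    vals = resistance.values.copy()
    if barriers.n_segments == 0:
        return ResistanceRaster(vals, resistance.origin, resistance.cell_size, resistance.nodata)
    valid = resistance.valid_mask()
    rmax = vals[valid].max()
    fill = rmax if barriers.permeability == "permeable" else rmax * LOW_PERMEABILITY_FACTOR
    cx, cy = resistance.cell_centers()
    hit = np.zeros(vals.shape, dtype=bool)
    for seg in barriers.segments:
        hit |= _segment_distance(cx, cy, seg) <= barriers.buffer_radius
    vals[hit & valid] = fill
    return ResistanceRaster(vals, resistance.origin, resistance.cell_size, resistance.nodata)


def _grid_graph(raster: ResistanceRaster):
    """Sparse 8-connected cost graph over valid cells."""
    vals = raster.values
    nrows, ncols = vals.shape
    valid = raster.valid_mask()
    node = -np.ones(vals.shape, dtype=np.int64)
    node[valid] = np.arange(valid.sum())
    rows_i, cols_i, weights = [], [], []
    offsets = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    for dr, dc, mult in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        a, b = node[r0, c0], node[r1, c1]
        va, vb = vals[r0, c0], vals[r1, c1]
        ok = (a >= 0) & (b >= 0)
        rows_i.append(a[ok])
        cols_i.append(b[ok])
        weights.append((va[ok] + vb[ok]) / 2.0 * raster.cell_size * mult)
    i = np.concatenate(rows_i)
    j = np.concatenate(cols_i)
    w = np.concatenate(weights)
    n = int(valid.sum())
    graph = coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n))
    return graph.tocsr(), node


def least_cost_distances(
    resistance: ResistanceRaster, points: np.ndarray, labels
) -> PairwiseLekMatrix:
    """Pairwise least-cost distances among lek points on the resistance grid.

    Points are snapped to their containing cell centers; paths run on the
    8-connected grid graph. Points outside the raster or on nodata cells
    raise an error naming the lek.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = list(labels)
    nrows, ncols = resistance.shape
    cells = []
    for lbl, (x, y) in zip(labels, points):
        r, c = resistance.cell_of(x, y)
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise ValueError(f"lek {lbl!r} falls outside the raster extent")
        if resistance.values[r, c] == resistance.nodata:
            raise ValueError(f"lek {lbl!r} falls on a nodata cell")
        cells.append((r, c))
    graph, node = _grid_graph(resistance)
    sources = np.array([node[r, c] for r, c in cells])
    dist = dijkstra(graph, directed=False, indices=sources)
    vals = dist[:, sources]
    vals = (vals + vals.T) / 2.0  # symmetric up to float noise
    return PairwiseLekMatrix(labels, vals, kind="least_cost")


def geographic_distances(points: np.ndarray, labels, mode: str = "planar") -> PairwiseLekMatrix:
    """Pairwise geographic distances among leks.

    ``planar``: Euclidean distance of projected (x, y) map coordinates.
    ``latlon``: great-circle (haversine) distance in km of (lat, lon) pairs.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if np.any(~np.isfinite(points)):
        raise ValueError("missing or non-finite coordinates")
    labels = list(labels)
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "planar":
                d = float(np.hypot(*(points[i] - points[j])))
            elif mode == "latlon":
                d = float(haversine_km(points[i][0], points[i][1], points[j][0], points[j][1]))
            else:
                raise ValueError("mode must be 'planar' or 'latlon'")
            vals[i, j] = vals[j, i] = d
    return PairwiseLekMatrix(labels, vals, kind="geographic")


def _aligned_condensed(matrices: list[PairwiseLekMatrix]) -> list[np.ndarray]:
    labels = matrices[0].labels
    out = []
    for m in matrices:
        if list(m.labels) != list(labels):
            if set(m.labels) != set(labels):
                raise ValueError("distance matrices have mismatched labels")
            m = m.reordered(labels)
        out.append(m.condensed())
    return out


def mantel_test(
    d1: PairwiseLekMatrix, d2: PairwiseLekMatrix, n_perm: int = 999, seed: int = 0
):
    """Mantel correlation of two distance matrices with permutation p-value.

    r is the Pearson correlation over lower-triangle entries; the null
    permutes rows and columns of the second matrix simultaneously; the test
    is upper-tailed. Returns (r, r², PermutationTestResult).
    """
    v1, v2 = _aligned_condensed([d1, d2])
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero-variance distance matrix")
    obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = d1.n
    i, j = np.tril_indices(n, k=-1)
    m2 = d2.values if list(d2.labels) == list(d1.labels) else d2.reordered(d1.labels).values
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n)
        null[p] = np.corrcoef(v1, m2[perm[i], perm[j]])[0, 1]
    result = PermutationTestResult.from_null(obs, null, tail="upper")
    return obs, obs**2, result


def _ols_r2_coefs(y: np.ndarray, x: np.ndarray):
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
    return r2, beta


def mrm(
    response: PairwiseLekMatrix,
    predictors: list[PairwiseLekMatrix],
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Multiple regression on distance matrices.

    OLS of the unfolded response triangle on the unfolded predictor
    triangles (with intercept). Significance comes from simultaneous
    row/column permutation of the response matrix, re-fitting each
    replicate: the model p-value is upper-tailed on R², and each
    coefficient's p-value is two-sided on its magnitude. With a single
    predictor the model R² equals the Mantel r².
    """
    vecs = _aligned_condensed([response] + list(predictors))
    y, xs = vecs[0], np.column_stack(vecs[1:])
    if xs.shape[1] > 1:
        cond = np.linalg.cond(np.column_stack([np.ones(len(y)), xs]))
        if cond > 1e8:
            warnings.warn(f"predictors nearly collinear (condition number {cond:.2g})", stacklevel=2)
    r2_obs, beta_obs = _ols_r2_coefs(y, xs)
    rng = np.random.default_rng(seed)
    n = response.n
    i, j = np.tril_indices(n, k=-1)
    rv = response.values
    null_r2 = np.empty(n_perm)
    null_beta = np.empty((n_perm, len(beta_obs)))
    for p in range(n_perm):
        perm = rng.permutation(n)
        yp = rv[perm[i], perm[j]]
        null_r2[p], null_beta[p] = _ols_r2_coefs(yp, xs)
    model_test = PermutationTestResult.from_null(r2_obs, null_r2, tail="upper")
    coef_p = (
        (np.abs(null_beta) >= np.abs(beta_obs)).sum(axis=0) + 1
    ) / (n_perm + 1)
    return {
        "r2": float(r2_obs),
        "coefficients": beta_obs,  # intercept first
        "coefficient_p": coef_p,
        "model_test": model_test,
        "p_value": model_test.p_value,
    }
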