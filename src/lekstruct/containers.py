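"""Shared data containers used across the analysis stages.

The pipeline passes a small set of typed containers between stages:
sample metadata (:class:`SampleFrame`), symmetric lek-by-lek matrices
(:class:`PairwiseLekMatrix`), resistance rasters (:class:`ResistanceRaster`)
and linear barrier features (:class:`BarrierSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleFrame",
    "PairwiseLekMatrix",
    "ResistanceRaster",
    "BarrierSet",
    "PermutationTestResult",
]


@dataclass
class SampleFrame:
    """Individual-level metadata: lek and lek-complex membership plus lek coordinates.

    Wraps a DataFrame with columns ``individual``, ``lek``, ``complex``,
    ``lek_lat``, ``lek_lon``. Row order defines the canonical individual
    order used by genotype matrices.
    """

    table: pd.DataFrame

    REQUIRED = ("individual", "lek", "complex", "lek_lat", "lek_lon")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if self.table["individual"].duplicated().any():
            dups = self.table.loc[self.table["individual"].duplicated(), "individual"]
            raise ValueError(f"duplicate individual ids: {sorted(set(dups))}")
        self.table = self.table.reset_index(drop=True)

    @property
    def individuals(self) -> np.ndarray:
        return self.table["individual"].to_numpy()

    @property
    def leks(self) -> np.ndarray:
        return self.table["lek"].to_numpy()

    @property
    def complexes(self) -> np.ndarray:
        return self.table["complex"].to_numpy()

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    def lek_coordinates(self) -> pd.DataFrame:
        """One row per lek: lek, complex, lek_lat, lek_lon (first-occurrence order)."""
        return (
            self.table.drop_duplicates("lek")[["lek", "complex", "lek_lat", "lek_lon"]]
            .reset_index(drop=True)
        )

    def individual_coordinates(self) -> np.ndarray:
        """(n, 2) array of each individual's lek (lat, lon)."""
        return self.table[["lek_lat", "lek_lon"]].to_numpy(float)


@dataclass
class PairwiseLekMatrix:
    """Symmetric matrix over leks (or lek complexes) with a kind tag.

    ``kind`` is one of ``fst``, ``nei_d``, ``geographic``, ``least_cost``.
    F_ST values may be slightly negative (an estimator property); the other
    kinds are nonnegative. The diagonal is zero.
    """

    labels: list
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major, i > j) as a 1-D vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reordered(self, labels: list) -> "PairwiseLekMatrix":
        idx = [list(self.labels).index(l) for l in labels]
        return PairwiseLekMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


@dataclass
class ResistanceRaster:
    """Rectangular grid of positive movement-resistance values.

    ``origin`` is the map coordinate (x, y) of the *lower-left corner* of the
    grid; ``cell_size`` the square cell edge in map units. Cells equal to
    ``nodata`` are impassable. Rows are stored north-up: row 0 is the top
    (highest y) of the grid, matching the ESRI ASCII convention.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.values != self.nodata
        if np.any(self.values[valid] <= 0):
            raise ValueError("resistance values must be positive (cost weights)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map point (x, y); row 0 is north."""
        nrows = self.values.shape[0]
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.origin[1]) / self.cell_size))
        return nrows - 1 - row_from_bottom, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each shaped like ``values``."""
        nrows, ncols = self.values.shape
        xs = self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size
        ys_bottom_up = self.origin[1] + (np.arange(nrows) + 0.5) * self.cell_size
        ys = ys_bottom_up[::-1]  # row 0 = north
        return np.broadcast_to(xs, (nrows, ncols)).copy(), np.broadcast_to(
            ys[:, None], (nrows, ncols)
        ).copy()


@dataclass
class BarrierSet:
    """Linear barrier features (roads, power lines) as map-unit segments.

    ``segments`` is an (m, 4) array of (x1, y1, x2, y2). Cells within
    ``buffer_radius`` of any segment are treated as barrier cells; the
    ``permeability`` mode controls the resistance assigned to them.
    """

    segments: np.ndarray
    buffer_radius: float = 100.0
    permeability: str = "permeable"

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float).reshape(-1, 4)
        if self.buffer_radius < 0:
            raise ValueError("buffer_radius must be nonnegative")
        if self.permeability not in ("permeable", "low_permeable"):
            raise ValueError("permeability must be 'permeable' or 'low_permeable'")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass
class PermutationTestResult:
    """Observed statistic plus its permutation null.

    The p-value uses the add-one convention
    ``p = (count at least as extreme + 1) / (n_permutations + 1)`` so it is
    never exactly zero. ``tail`` records the direction of extremeness.
    """

    observed: float
    null: np.ndarray = field(repr=False)
    p_value: float = 0.0
    n_permutations: int = 0
    tail: str = "upper"

    @classmethod
    def from_null(
        cls, observed: float, null: np.ndarray, tail: str = "upper"
    ) -> "PermutationTestResult":
        null = np.asarray(null, dtype=float)
        if tail == "upper":
            extreme = np.sum(null >= observed)
        elif tail == "lower":
            extreme = np.sum(null <= observed)
        elif tail == "two-sided":
            extreme = np.sum(np.abs(null) >= abs(observed))
        else:
            raise ValueError(f"unknown tail: {tail}")
        p = (extreme + 1) / (len(null) + 1)
        return cls(float(observed), null, float(p), len(null), tail)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "tail": self.tail,
        }
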