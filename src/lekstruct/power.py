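"""Locus-subsampling precision analysis.

How many SNPs are needed to capture the geographic genetic structure?
Random locus subsets of increasing size are drawn, and for each subset the
Procrustes correlation of the first two PCs against lek geography and the
DAPC correct-assignment proportions (lek and lek-complex level) are
recorded. Means and standard deviations per size trace a precision curve
whose plateau marks the point where more loci stop adding information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import project_equirectangular
from .containers import SampleFrame
from .genotypes import DosageMatrix
from .ordination import dapc_fit, procrustes_correlation, run_pca

__all__ = ["SubsampleDesign", "PowerCurve", "run_subsampling", "plateau_size"]

# Subset sizes of the reference design (cap at the available locus count).
DEFAULT_SIZES = (
    50, 150, 250, 500, 1000, 2000, 3000, 4000, 5000, 6000, 8000, 10000,
    12000, 14000, 16000, 18000, 20000, 22000, 24000, 26000, 27000,
)


@dataclass
class SubsampleDesign:
    """Subset sizes, replicates per size, and the master seed."""

    sizes: tuple = DEFAULT_SIZES
    replicates_per_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if len(sizes) == 0 or any(s <= 0 for s in sizes):
            raise ValueError("sizes must be positive")
        if any(b < a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("sizes must be non-decreasing")
        self.sizes = sizes
        if self.replicates_per_size < 1:
            raise ValueError("replicates_per_size must be positive")

    def capped(self, n_loci: int) -> "SubsampleDesign":
        """Drop sizes above the available locus count (keeping the full set)."""
        sizes = tuple(s for s in self.sizes if s <= n_loci)
        if not sizes:
            raise ValueError("no subset size fits the available loci")
        return SubsampleDesign(sizes, self.replicates_per_size, self.seed)


@dataclass
class PowerCurve:
    """Per-size mean and sd of each precision metric."""

    table: pd.DataFrame = field(repr=False)

    METRICS = ("procrustes_t", "assign_lek", "assign_complex")

    def mean(self, metric: str) -> pd.Series:
        return self.table.set_index("size")[f"{metric}_mean"]

    def sd(self, metric: str) -> pd.Series:
        return self.table.set_index("size")[f"{metric}_sd"]


def _dapc_n_pcs(n_loci: int, n_ind: int, k: int, cap: int) -> int:
    return max(1, min(cap, n_loci, n_ind - k - 1))


def run_subsampling(
    dosage: DosageMatrix,
    samples: SampleFrame,
    design: SubsampleDesign,
    dapc_pc_cap: int = 20,
) -> PowerCurve:
    """Evaluate Procrustes and DAPC metrics on random locus subsets.

    For each size × replicate, loci are drawn uniformly without replacement
    (seeded from the design's master seed), the first two PCs are rotated
    onto the individuals' lek coordinates (projected to planar km), and DAPC
    with a-priori lek and complex labels records the correct-assignment
    proportions. The retained-PC count is min(``dapc_pc_cap``, subset size,
    n − k − 1); re-optimizing the alpha-score per subset is possible through
    :func:`lekstruct.ordination.optimize_a_score` but not done by default.
    Fully deterministic given the design seed.
    """
    x = dosage.dosage
    nl = x.shape[1]
    design = design.capped(nl)
    if design.sizes[-1] > nl:
        raise ValueError("subset size exceeds available loci")
    coords = samples.individual_coordinates()  # (lat, lon) per individual
    geo = project_equirectangular(coords[:, 0], coords[:, 1])
    leks = samples.leks
    complexes = samples.complexes
    k_lek, k_cx = len(set(leks)), len(set(complexes))
    n = x.shape[0]

    ss = np.random.SeedSequence(design.seed)
    seeds = ss.generate_state(len(design.sizes) * design.replicates_per_size)
    rows = []
    si = 0
    for size in design.sizes:
        recs = []
        for _ in range(design.replicates_per_size):
            rng = np.random.default_rng(int(seeds[si]))
            si += 1
            idx = rng.choice(nl, size=size, replace=False) if size < nl else np.arange(nl)
            sub = x[:, idx]
            pcs = run_pca(sub, n_axes=2).scores
            t = procrustes_correlation(pcs, geo)
            lek_model = dapc_fit(sub, leks, _dapc_n_pcs(size, n, k_lek, dapc_pc_cap))
            cx_model = dapc_fit(sub, complexes, _dapc_n_pcs(size, n, k_cx, dapc_pc_cap))
            recs.append((t, lek_model.reassignment_overall, cx_model.reassignment_overall))
        arr = np.array(recs)
        rows.append(
            {
                "size": size,
                "procrustes_t_mean": arr[:, 0].mean(),
                "procrustes_t_sd": arr[:, 0].std(ddof=1) if len(arr) > 1 else 0.0,
                "assign_lek_mean": arr[:, 1].mean(),
                "assign_lek_sd": arr[:, 1].std(ddof=1) if len(arr) > 1 else 0.0,
                "assign_complex_mean": arr[:, 2].mean(),
                "assign_complex_sd": arr[:, 2].std(ddof=1) if len(arr) > 1 else 0.0,
            }
        )
    return PowerCurve(pd.DataFrame(rows))


def plateau_size(curve: PowerCurve, tolerance: float, metric: str = "procrustes_t") -> int:
    """Smallest size whose mean is within ``tolerance`` (relative) of the
    largest-size mean."""
    means = curve.mean(metric)
    target = means.iloc[-1]
    for size, m in means.items():
        if abs(m - target) <= tolerance * abs(target):
            return int(size)
    return int(means.index[-1])


def plot_power_curve(curve: PowerCurve, path=None):
    """Size vs mean ± sd for each metric (one panel per metric)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(PowerCurve.METRICS), figsize=(12, 3.5))
    for ax, metric in zip(axes, PowerCurve.METRICS):
        m, s = curve.mean(metric), curve.sd(metric)
        ax.errorbar(m.index, m.values, yerr=s.values, fmt="o-", capsize=2)
        ax.set_xscale("log")
        ax.set_xlabel("SNPs")
        ax.set_title(metric)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
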