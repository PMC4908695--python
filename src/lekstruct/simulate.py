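"""Synthetic lek-structured populations with genotype-likelihood read data.

Generates the statistical structure the downstream analyses assume: a
two-level hierarchy of lek complexes and leks (differentiation stronger
among complexes than among leks within them), a latitudinal allele-frequency
gradient producing isolation by distance, and shallow-coverage read data
from which genotype likelihoods are computed.

Allele frequencies follow the Balding–Nichols F-model at each level of the
hierarchy: a population at differentiation F around mean frequency p draws
its frequency from Beta with mean p and variance F·p·(1−p), which gives the
F parameter a direct F_ST interpretation for parameter-recovery tests.
Genotypes are drawn in Hardy–Weinberg proportions at the lek frequency.

Read coverage uses a locus-level Normal rate (truncated at zero) with
individual depths Poisson at that rate, reproducing a per-locus mean/sd
coverage summary rather than a single global Poisson. Missing data arise
mechanistically from zero depth, never imposed independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import BarrierSet, ResistanceRaster, SampleFrame
from .genotypes import GenotypeLikelihoodTable, genotype_likelihoods_from_counts

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_hierarchical_frequencies",
    "simulate_reads",
    "simulate_dataset",
    "simulate_resistance_raster",
    "simulate_barriers",
]

# Study-area extent used for lek placement (central Nevada-like box, degrees).
_LAT_RANGE = (39.55, 40.15)
_LON_RANGE = (-116.55, -116.05)


@dataclass
class SimulationConfig:
    """Parameters of the hierarchical lek/lek-complex simulation.

    Defaults emulate the study system: 140 males in 10 leks grouped into 5
    lek complexes, ~27,866 biallelic SNPs at mean coverage 5.7X (sd 1.7),
    with complex-level differentiation exceeding lek-level differentiation
    and a latitudinal frequency gradient.
    """

    n_complexes: int = 5
    leks_per_complex: int = 2
    individuals_per_lek: int = 14
    n_loci: int = 27866
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    f_complex: float = 0.02
    f_lek: float = 0.005
    ibd_strength: float = 0.02
    mean_coverage: float = 5.7
    coverage_sd: float = 1.7
    error_rate: float = 0.01
    missing_locus_fraction_target: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_complex < 1 and 0 <= self.f_lek < 1):
            raise ValueError("f_complex and f_lek must be in [0, 1)")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.coverage_sd < 0:
            raise ValueError("coverage_sd must be nonnegative")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not (0 <= self.missing_locus_fraction_target < 1):
            raise ValueError("missing_locus_fraction_target must be in [0, 1)")
        if self.ibd_strength < 0:
            raise ValueError("ibd_strength must be nonnegative")

    @property
    def n_leks(self) -> int:
        return self.n_complexes * self.leks_per_complex

    @property
    def n_individuals(self) -> int:
        return self.n_leks * self.individuals_per_lek


@dataclass
class TruthRecord:
    """Ground truth of a simulation: frequencies, genotypes, geography."""

    ancestral_freq: np.ndarray  # (loci,)
    complex_freq: np.ndarray  # (n_complexes, loci)
    lek_freq: np.ndarray  # (n_leks, loci)
    genotypes: np.ndarray  # (n_individuals, loci) in {0, 1, 2}
    samples: SampleFrame
    lek_complex: np.ndarray = field(default=None)  # complex index per lek

    @property
    def n_loci(self) -> int:
        return self.ancestral_freq.shape[0]

    @property
    def lek_allele_freq_empirical(self) -> np.ndarray:
        """Realized alternate-allele frequency per lek from true genotypes."""
        leks = self.samples.leks
        uniq = list(dict.fromkeys(leks))
        out = np.empty((len(uniq), self.n_loci))
        for k, lek in enumerate(uniq):
            g = self.genotypes[leks == lek]
            out[k] = g.mean(axis=0) / 2.0
        return out


def _balding_nichols(rng: np.random.Generator, mean: np.ndarray, f: float) -> np.ndarray:
    """Beta draw with the given mean and variance f·p·(1−p); f=0 returns the mean.

    Means are clamped to [0.001, 0.999] first so the Beta parameterization is
    never degenerate.
    """
    p = np.clip(mean, 0.001, 0.999)
    if f == 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)


def _lek_geography(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place complex centers along a latitudinal gradient, leks near their center."""
    nc, lpc = config.n_complexes, config.leks_per_complex
    lat_centers = np.linspace(_LAT_RANGE[0] + 0.03, _LAT_RANGE[1] - 0.03, nc)
    lon_centers = np.mean(_LON_RANGE) + 0.12 * np.cos(
        np.linspace(0, 2.2 * np.pi, nc, endpoint=False)
    )
    rows = []
    for c in range(nc):
        for l in range(lpc):
            rows.append(
                {
                    "lek": f"lek_{c}{chr(ord('a') + l)}",
                    "complex": f"complex_{c}",
                    # leks sit within a few km of the complex center
                    "lek_lat": lat_centers[c] + rng.uniform(-0.02, 0.02),
                    "lek_lon": lon_centers[c] + rng.uniform(-0.03, 0.03),
                }
            )
    return pd.DataFrame(rows)


def simulate_hierarchical_frequencies(config: SimulationConfig) -> TruthRecord:
    """Draw the two-level allele-frequency hierarchy and true genotypes.

    Per locus: an ancestral frequency is drawn uniformly on
    ``ancestral_maf_range`` with random allele orientation; each complex
    frequency is a Balding–Nichols draw at ``f_complex`` around the ancestral
    value (shifted along standardized latitude by ``ibd_strength`` when
    positive); each lek frequency is a Balding–Nichols draw at ``f_lek``
    around its complex frequency. Genotypes are Binomial(2, lek frequency).
    """
    rng = np.random.default_rng(config.seed)
    nl = config.n_loci

    maf = rng.uniform(*config.ancestral_maf_range, size=nl)
    flip = rng.random(nl) < 0.5
    ancestral = np.where(flip, 1.0 - maf, maf)

    geo = _lek_geography(config, rng)
    complex_lat = geo.groupby("complex", sort=False)["lek_lat"].mean().to_numpy()
    z_lat = complex_lat - complex_lat.mean()
    sd = z_lat.std()
    z_lat = z_lat / sd if sd > 0 else z_lat

    complex_freq = np.empty((config.n_complexes, nl))
    for c in range(config.n_complexes):
        mean_c = ancestral + config.ibd_strength * z_lat[c]
        complex_freq[c] = _balding_nichols(rng, mean_c, config.f_complex)

    lek_complex = np.repeat(np.arange(config.n_complexes), config.leks_per_complex)
    lek_freq = np.empty((config.n_leks, nl))
    for k in range(config.n_leks):
        lek_freq[k] = _balding_nichols(rng, complex_freq[lek_complex[k]], config.f_lek)

    ipl = config.individuals_per_lek
    genotypes = np.empty((config.n_individuals, nl), dtype=np.int8)
    rows = []
    for k in range(config.n_leks):
        genotypes[k * ipl : (k + 1) * ipl] = rng.binomial(
            2, lek_freq[k], size=(ipl, nl)
        )
        lek_row = geo.iloc[k]
        for i in range(ipl):
            rows.append(
                {
                    "individual": f"{lek_row['lek']}_ind{i:02d}",
                    "lek": lek_row["lek"],
                    "complex": lek_row["complex"],
                    "lek_lat": lek_row["lek_lat"],
                    "lek_lon": lek_row["lek_lon"],
                }
            )
    samples = SampleFrame(pd.DataFrame(rows))
    return TruthRecord(ancestral, complex_freq, lek_freq, genotypes, samples, lek_complex)


def simulate_reads(truth: TruthRecord, config: SimulationConfig) -> GenotypeLikelihoodTable:
    """Generate read counts and genotype likelihoods from true genotypes.

    A per-locus coverage rate is drawn Normal(mean_coverage, coverage_sd)
    truncated at zero; each individual's depth at the locus is Poisson at
    that rate. Alternate-read counts are Binomial(depth, π_g) with
    π_g = (g/2)(1−ε) + (1−g/2)ε. Zero depth yields a flat likelihood triple.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x5EAD]).generate_state(1)[0]
    )
    n, nl = truth.genotypes.shape
    rate = np.clip(rng.normal(config.mean_coverage, config.coverage_sd, size=nl), 0, None)
    depth = rng.poisson(np.broadcast_to(rate, (n, nl)))
    g = truth.genotypes.astype(float)
    pi = (g / 2.0) * (1 - config.error_rate) + (1 - g / 2.0) * config.error_rate
    alt = rng.binomial(depth, pi)
    ref = depth - alt
    lik = genotype_likelihoods_from_counts(ref, alt, config.error_rate)

    table = GenotypeLikelihoodTable(
        likelihoods=lik,
        has_read=depth > 0,
        contig_id=np.array([f"contig_{j:06d}" for j in range(nl)]),
        locus_id=np.array([f"snp_{j:06d}" for j in range(nl)]),
        alleles=np.array([("A", "G")] * nl, dtype=object),
        n_alt_alleles=np.ones(nl, dtype=int),
        individual_id=truth.samples.individuals.copy(),
        read_depth=depth,
    )
    presence = table.has_read.mean(axis=0)
    frac_low = float(np.mean(presence < 0.9))
    if frac_low > config.missing_locus_fraction_target:
        warnings.warn(
            f"{frac_low:.1%} of loci fall below 90% read presence "
            f"(target {config.missing_locus_fraction_target:.0%})",
            stacklevel=2,
        )
    return table


def simulate_dataset(config: SimulationConfig) -> tuple[TruthRecord, GenotypeLikelihoodTable]:
    """Convenience: truth plus read-based likelihood table in one call."""
    truth = simulate_hierarchical_frequencies(config)
    return truth, simulate_reads(truth, config)


def simulate_resistance_raster(
    n_rows: int,
    n_cols: int,
    cell_size: float = 1.0,
    roughness: float = 1.0,
    seed: int = 0,
    r_max: float = 100.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> ResistanceRaster:
    """Smooth positive random resistance field rescaled to [1, r_max].

    Gaussian-filtered white noise; ``roughness`` controls spatial frequency
    (higher = shorter correlation length). ``roughness`` 0 gives the constant
    raster 1 — the degenerate flat landscape.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("raster must be at least 2x2")
    if roughness == 0:
        values = np.ones((n_rows, n_cols))
    else:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n_rows, n_cols))
        sigma = max(1.0, max(n_rows, n_cols) / (2.0 * (1.0 + roughness)))
        fld = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        lo, hi = fld.min(), fld.max()
        u = (fld - lo) / (hi - lo) if hi > lo else np.zeros_like(fld)
        values = 1.0 + (r_max - 1.0) * u
    return ResistanceRaster(values, origin=origin, cell_size=cell_size)


def simulate_barriers(
    raster: ResistanceRaster,
    n_barriers: int = 2,
    seed: int = 0,
    buffer_radius: float = 100.0,
    permeability: str = "permeable",
) -> BarrierSet:
    """Random straight line barriers spanning the raster extent."""
    rng = np.random.default_rng(seed)
    nrows, ncols = raster.shape
    x0, y0 = raster.origin
    w, h = ncols * raster.cell_size, nrows * raster.cell_size
    segs = []
    for _ in range(n_barriers):
        if rng.random() < 0.5:  # roughly vertical
            xa, xb = rng.uniform(x0, x0 + w, size=2)
            segs.append((xa, y0, xb, y0 + h))
        else:
            ya, yb = rng.uniform(y0, y0 + h, size=2)
            segs.append((x0, ya, x0 + w, yb))
    return BarrierSet(np.array(segs), buffer_radius=buffer_radius, permeability=permeability)
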