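"""Configuration-driven orchestration of the full analysis.

A :class:`RunConfig` names either input files (VCF or likelihood table plus
metadata, optionally a raster and barriers) or a simulation configuration —
exactly one of the two. ``run_pipeline`` executes the stages in dependency
order (data → filters → dosage → ordination / differentiation / landscape /
power), writes each stage's artifacts under the output directory, and
returns a manifest. Every stochastic stage receives a seed derived
deterministically from the master seed by hashing the stage name, so adding
a stage never perturbs the others and a rerun with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import io as lio
from ._utils import project_equirectangular, stage_seed
from .containers import BarrierSet, PairwiseLekMatrix, ResistanceRaster, SampleFrame
from .differentiation import (
    fst_permutation_test,
    nei_distance_matrix,
    neighbor_joining,
    pairwise_fst_matrix,
)
from .genotypes import (
    DosageMatrix,
    GenotypeLikelihoodTable,
    McmcSettings,
    estimate_dosages,
    filter_biallelic,
    filter_maf,
    filter_presence,
    thin_one_snp_per_contig,
)
from .landscape import (
    apply_barriers,
    geographic_distances,
    invert_suitability,
    least_cost_distances,
    mantel_test,
    mrm,
)
from .ordination import (
    dapc_fit,
    find_clusters,
    optimize_a_score,
    pair_sharing_distance_test,
    permanova,
    procrustes_permutation_test,
    rda_fit,
    run_pca,
)
from .power import PowerCurve, SubsampleDesign, run_subsampling
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("lekstruct")

STAGES = ("data", "filters", "dosage", "ordinate", "differentiate", "landscape", "power")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``input_paths`` (keys: genotypes, metadata, and optional
    raster, barriers) or ``simulation`` may be set. Filter, MCMC, and
    permutation defaults follow the analysis conventions of the package
    (presence 0.9, MAF 0.05; 999 permutations for ordination and Mantel
    tests, 1000 for the pair-sharing test).
    """

    output_dir: str = "lekstruct_out"
    master_seed: int = 0
    input_paths: dict | None = None
    simulation: SimulationConfig | None = None
    presence_min_fraction: float = 0.9
    maf_min: float = 0.05
    thin_per_contig: bool = True
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    n_perm_ordination: int = 999
    n_perm_pair_sharing: int = 1000
    n_perm_mantel: int = 999
    n_perm_fst: int = 99
    dapc_n_pcs: int | None = None  # None: choose by alpha-score
    find_clusters_k_max: int = 10
    find_clusters_n_pcs: int = 20
    raster_is_suitability: bool = True
    resistance_r_max: float = 100.0
    subsample: SubsampleDesign | None = None
    write_vcf: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise ValueError("exactly one of input_paths or simulation must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = McmcSettings(**d["mcmc"])
        if "subsample" in d and isinstance(d["subsample"], dict):
            d["subsample"] = SubsampleDesign(**d["subsample"])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def read_inputs(paths: dict):
    """Load genotype likelihoods, metadata, and optional landscape inputs.

    ``genotypes`` may be a VCF (PL or GL) or a plain likelihood TSV; every
    genotyped individual must appear in the metadata (missing ids raise an
    error naming them). Returns (table, samples, raster | None, barriers | None).
    """
    gpath = paths["genotypes"]
    if gpath.endswith((".vcf", ".vcf.gz")):
        table = lio.read_vcf(gpath)
    else:
        table = lio.read_likelihood_table(gpath)
    samples = lio.read_metadata(paths["metadata"], individuals=table.individual_id)
    raster = lio.read_esri_ascii(paths["raster"]) if paths.get("raster") else None
    barriers = (
        lio.read_barriers(
            paths["barriers"],
            buffer_radius=paths.get("barrier_buffer", 100.0),
            permeability=paths.get("barrier_permeability", "permeable"),
        )
        if paths.get("barriers")
        else None
    )
    return table, samples, raster, barriers


class PipelineState:
    """In-memory artifacts shared between stages."""

    def __init__(self) -> None:
        self.table: GenotypeLikelihoodTable | None = None
        self.samples: SampleFrame | None = None
        self.raster: ResistanceRaster | None = None
        self.barriers: BarrierSet | None = None
        self.dosage: DosageMatrix | None = None
        self.pca = None
        self.nei: PairwiseLekMatrix | None = None


def _write_json(obj, path: str) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)


def _lek_frequencies(dosage: DosageMatrix, samples: SampleFrame):
    leks = samples.leks
    uniq = list(dict.fromkeys(leks))
    freqs = np.stack([dosage.dosage[leks == l].mean(axis=0) / 2.0 for l in uniq])
    return uniq, freqs


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    stages = set(stages)
    # pull in dependencies
    if stages & {"ordinate", "differentiate", "landscape", "power"}:
        stages |= {"dosage"}
    if "dosage" in stages:
        stages |= {"filters"}
    if "filters" in stages:
        stages |= {"data"}
    manifest = {"config": _config_dict(config), "stages": {}}
    state = PipelineState()

    for stage in STAGES:
        if stage not in stages:
            continue
        if stage == "power" and config.subsample is None:
            continue
        seed = stage_seed(config.master_seed, stage)
        logger.info("stage %s (seed %d)", stage, seed)
        try:
            outputs = _STAGE_FUNCS[stage](config, state, seed, out)
        except Exception:
            manifest["stages"][stage] = {"status": "failed"}
            _write_json(manifest, os.path.join(out, "manifest.json"))
            raise
        manifest["stages"][stage] = {"status": "ok", "seed": seed, "outputs": outputs}
    _write_json(manifest, os.path.join(out, "manifest.json"))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _stage_data(config, state: PipelineState, seed, out):
    outputs = []
    if config.simulation is not None:
        truth, table = simulate_dataset(config.simulation)
        state.table, state.samples = table, truth.samples
        meta_path = os.path.join(out, "metadata.csv")
        lio.write_metadata(state.samples, meta_path)
        outputs.append(meta_path)
        truth_path = os.path.join(out, "truth_lek_freq.csv")
        import pandas as pd

        pd.DataFrame(
            truth.lek_freq.T, columns=list(dict.fromkeys(state.samples.leks))
        ).to_csv(truth_path, index=False, float_format="%.5f")
        outputs.append(truth_path)
        if config.write_vcf:
            vcf_path = os.path.join(out, "genotypes.vcf")
            lio.write_vcf(table, vcf_path)
            outputs.append(vcf_path)
    else:
        state.table, state.samples, state.raster, state.barriers = read_inputs(
            config.input_paths
        )
    return outputs


def _stage_filters(config, state: PipelineState, seed, out):
    t = state.table
    n0 = t.n_loci
    t = filter_presence(t, config.presence_min_fraction)
    t = filter_biallelic(t)
    t = filter_maf(t, config.maf_min)
    if config.thin_per_contig:
        t = thin_one_snp_per_contig(t, seed=seed)
    state.table = t
    logger.info("filters: %d -> %d loci", n0, t.n_loci)
    return {"n_loci_in": n0, "n_loci_out": t.n_loci}


def _stage_dosage(config, state: PipelineState, seed, out):
    settings = McmcSettings(
        n_steps=config.mcmc.n_steps,
        burn_in=config.mcmc.burn_in,
        thin=config.mcmc.thin,
        seed=seed,
    )
    state.dosage = estimate_dosages(state.table, settings)
    dpath = os.path.join(out, "dosage.tsv")
    lio.write_dosage_matrix(state.dosage, dpath)
    spath = os.path.join(out, "locus_summary.csv")
    lio.write_locus_summary(state.dosage, state.table, spath)
    return [dpath, spath]


def _stage_ordinate(config, state: PipelineState, seed, out):
    import pandas as pd

    dosage, samples = state.dosage, state.samples
    results = {}
    pca = run_pca(dosage, n_axes=2)
    state.pca = pca
    pd.DataFrame(
        pca.scores, index=samples.individuals, columns=["PC1", "PC2"]
    ).to_csv(os.path.join(out, "pca_scores.csv"))
    results["pca_variance_fraction"] = pca.axis_variance_fraction.tolist()

    coords = samples.individual_coordinates()
    geo = project_equirectangular(coords[:, 0], coords[:, 1])
    proc = procrustes_permutation_test(
        pca.scores, geo, n_perm=config.n_perm_ordination, seed=seed
    )
    results["procrustes"] = proc.to_dict()

    for level, labels in (("lek", samples.leks), ("complex", samples.complexes)):
        ps = pair_sharing_distance_test(
            pca.scores, labels, n_perm=config.n_perm_pair_sharing, seed=seed + 1
        )
        results[f"pair_sharing_{level}"] = ps.to_dict()
        r2, f, perm = permanova(
            pca.scores, labels, n_perm=config.n_perm_ordination, seed=seed + 2
        )
        results[f"permanova_{level}"] = {"r2": r2, "pseudo_f": f, **perm.to_dict()}
        if config.dapc_n_pcs is not None:
            n_pcs = config.dapc_n_pcs
        else:
            opt = optimize_a_score(
                dosage, labels, n_replicates=20, seed=seed + 3,
                candidates=range(1, min(31, samples.n_individuals - 1)),
            )
            results[f"dapc_{level}_alpha"] = {
                "best_n_pcs": opt["best_n_pcs"],
                "alpha_mean": opt["alpha_mean"],
                "alpha_sd": opt["alpha_sd"],
            }
            n_pcs = opt["best_n_pcs"]
        model = dapc_fit(dosage, labels, n_pcs)
        results[f"dapc_{level}"] = {
            "n_pcs": n_pcs,
            "reassignment_overall": model.reassignment_overall,
            "reassignment_per_group": model.reassignment_per_group(),
        }
        pd.DataFrame(
            model.assignment_probs, index=samples.individuals, columns=model.group_labels
        ).to_csv(os.path.join(out, f"dapc_{level}_assignments.csv"))

    fc = find_clusters(
        dosage,
        k_max=min(config.find_clusters_k_max, samples.n_individuals - 1),
        n_pcs_for_kmeans=config.find_clusters_n_pcs,
        seed=seed + 4,
    )
    results["find_clusters"] = {"best_k": fc["best_k"], "bic": fc["bic"]}

    rda = rda_fit(dosage, geo)
    results["rda_variance_fraction"] = rda.axis_variance_fraction.tolist()
    path = os.path.join(out, "ordination_results.json")
    _write_json(results, path)
    return results


def _stage_differentiate(config, state: PipelineState, seed, out):
    dosage, samples = state.dosage, state.samples
    results = {}
    fst = pairwise_fst_matrix(dosage, samples.leks)
    lio.write_pairwise_matrix(fst, os.path.join(out, "fst_leks.csv"))
    uniq, freqs = _lek_frequencies(dosage, samples)
    nei = nei_distance_matrix(freqs, uniq)
    state.nei = nei
    lio.write_pairwise_matrix(nei, os.path.join(out, "nei_d_leks.csv"))
    with open(os.path.join(out, "nj_nei_d.nwk"), "w") as fh:
        fh.write(neighbor_joining(nei) + "\n")
    results["fst_mean"] = float(np.mean(fst.condensed()))
    results["nei_d_mean"] = float(np.mean(nei.condensed()))
    if config.n_perm_fst > 0:
        sig = {}
        for a, b in zip(*np.triu_indices(fst.n, k=1)):
            pair = (fst.labels[a], fst.labels[b])
            res = fst_permutation_test(
                dosage, samples.leks, pair, n_perm=config.n_perm_fst, seed=seed
            )
            sig[f"{pair[0]}|{pair[1]}"] = res.to_dict()
        results["fst_tests"] = sig
    _write_json(results, os.path.join(out, "differentiation_results.json"))
    return {"fst_mean": results["fst_mean"], "nei_d_mean": results["nei_d_mean"]}


def _stage_landscape(config, state: PipelineState, seed, out):
    samples = state.samples
    if state.nei is None:
        uniq, freqs = _lek_frequencies(state.dosage, samples)
        state.nei = nei_distance_matrix(freqs, uniq)
    nei = state.nei
    lekframe = samples.lek_coordinates()
    order = [list(lekframe["lek"]).index(l) for l in nei.labels]
    lek_xy = project_equirectangular(
        lekframe["lek_lat"].to_numpy(), lekframe["lek_lon"].to_numpy()
    )[order]
    geo = geographic_distances(lek_xy, nei.labels, mode="planar")
    lio.write_pairwise_matrix(geo, os.path.join(out, "geographic_km.csv"))
    results = {}
    r, r2, test = mantel_test(nei, geo, n_perm=config.n_perm_mantel, seed=seed)
    results["mantel_distance"] = {"r": r, "r2": r2, **test.to_dict()}
    results["mrm_distance"] = _mrm_summary(
        mrm(nei, [geo], n_perm=config.n_perm_mantel, seed=seed + 1)
    )
    if state.raster is not None:
        resistance = (
            invert_suitability(state.raster, r_max=config.resistance_r_max)
            if config.raster_is_suitability
            else state.raster
        )
        lcp = least_cost_distances(resistance, lek_xy, nei.labels)
        lio.write_pairwise_matrix(lcp, os.path.join(out, "least_cost_habitat.csv"))
        results["mrm_distance_habitat"] = _mrm_summary(
            mrm(nei, [geo, lcp], n_perm=config.n_perm_mantel, seed=seed + 2)
        )
        if state.barriers is not None:
            for modename in ("permeable", "low_permeable"):
                b = BarrierSet(
                    state.barriers.segments, state.barriers.buffer_radius, modename
                )
                lcp_b = least_cost_distances(apply_barriers(resistance, b), lek_xy, nei.labels)
                results[f"mrm_distance_{modename}_barriers"] = _mrm_summary(
                    mrm(nei, [geo, lcp_b], n_perm=config.n_perm_mantel, seed=seed + 3)
                )
    _write_json(results, os.path.join(out, "landscape_results.json"))
    return {k: v.get("r2") for k, v in results.items() if isinstance(v, dict)}


def _mrm_summary(res: dict) -> dict:
    return {
        "r2": res["r2"],
        "p_value": res["p_value"],
        "coefficients": res["coefficients"].tolist(),
        "coefficient_p": res["coefficient_p"].tolist(),
    }


def _stage_power(config, state: PipelineState, seed, out):
    design = SubsampleDesign(
        sizes=config.subsample.sizes,
        replicates_per_size=config.subsample.replicates_per_size,
        seed=seed,
    )
    curve = run_subsampling(state.dosage, state.samples, design)
    path = os.path.join(out, "power_curve.csv")
    curve.table.to_csv(path, index=False, float_format="%.5f")
    return [path]


_STAGE_FUNCS = {
    "data": _stage_data,
    "filters": _stage_filters,
    "dosage": _stage_dosage,
    "ordinate": _stage_ordinate,
    "differentiate": _stage_differentiate,
    "landscape": _stage_landscape,
    "power": _stage_power,
}
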