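"""Readers and writers for the standard interchange formats.

Genotype likelihoods travel as VCF (PL phred-scaled or GL log10, both
normalized to linear-scale triples on read) or as a plain wide TSV with
three columns per individual. Metadata is CSV, rasters are ESRI ASCII
grids, distance matrices labeled CSV, and barriers a simple segment CSV
(x1,y1,x2,y2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import BarrierSet, PairwiseLekMatrix, ResistanceRaster, SampleFrame
from .genotypes import DosageMatrix, GenotypeLikelihoodTable

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_likelihood_table",
    "read_likelihood_table",
    "write_metadata",
    "read_metadata",
    "write_esri_ascii",
    "read_esri_ascii",
    "write_barriers",
    "read_barriers",
    "write_dosage_matrix",
    "write_locus_summary",
    "write_pairwise_matrix",
    "read_pairwise_matrix",
]

_PL_CAP = 255  # phred cap applied on write


def write_vcf(table: GenotypeLikelihoodTable, path: str) -> None:
    """Write the likelihood table as a minimal VCF with GT and PL fields.

    PL is the phred-scaled likelihood relative to the most likely genotype,
    capped at 255; GT is the maximum-likelihood genotype (``./.`` for
    individuals with no reads).
    """
    lik = table.likelihoods
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
            '"Phred-scaled genotype likelihoods">\n'
        )
        for contig in dict.fromkeys(table.contig_id):
            fh.write(f"##contig=<ID={contig}>\n")
        cols = "\t".join(str(s) for s in table.individual_id)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(table.n_loci):
            ref, alt = table.alleles[j]
            trip = lik[:, j, :]
            with np.errstate(divide="ignore"):
                pl = -10.0 * np.log10(trip / trip.max(axis=1, keepdims=True))
            pl = np.minimum(np.rint(pl), _PL_CAP).astype(int)
            fields = []
            for i in range(table.n_individuals):
                if table.has_read[i, j]:
                    gt = gt_strings[int(np.argmax(trip[i]))]
                    fields.append(f"{gt}:{pl[i,0]},{pl[i,1]},{pl[i,2]}")
                else:
                    fields.append("./.:0,0,0")
            fh.write(
                f"{table.contig_id[j]}\t1\t{table.locus_id[j]}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT:PL\t" + "\t".join(fields) + "\n"
            )


def read_vcf(path: str) -> GenotypeLikelihoodTable:
    """Read a VCF into a likelihood table, accepting PL (phred) or GL (log10).

    Triples are normalized to linear scale with maximum 1. Sites where an
    individual's genotype is missing and the triple is flat are flagged as
    read-absent. Multi-allelic sites are kept (with their alternate-allele
    count) so the biallelic filter can drop them explicitly.
    """
    vcf = VCF(path)
    individuals = np.array(vcf.samples)
    liks, has_read, contigs, loci, alleles, n_alt = [], [], [], [], [], []
    for var in vcf:
        n_alt_here = len(var.ALT)
        pl = var.format("PL")
        gl = var.format("GL") if pl is None else None
        if pl is not None:
            trip = np.power(10.0, -np.asarray(pl[:, :3], dtype=float) / 10.0)
        elif gl is not None:
            trip = np.power(10.0, np.asarray(gl[:, :3], dtype=float))
        else:
            raise ValueError(f"variant {var.ID or var.POS} has neither PL nor GL")
        trip = trip / trip.max(axis=1, keepdims=True)
        flat = np.all(np.abs(trip - trip[:, [0]]) < 1e-12, axis=1)
        gts = np.asarray(var.gt_types)
        missing = gts == 2  # cyvcf2 UNKNOWN
        liks.append(trip)
        has_read.append(~(flat & missing))
        contigs.append(var.CHROM)
        loci.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        alleles.append((var.REF, var.ALT[0] if var.ALT else "."))
        n_alt.append(n_alt_here)
    return GenotypeLikelihoodTable(
        likelihoods=np.stack(liks, axis=1),
        has_read=np.stack(has_read, axis=1),
        contig_id=np.array(contigs),
        locus_id=np.array(loci),
        alleles=np.array(alleles, dtype=object),
        n_alt_alleles=np.array(n_alt),
        individual_id=individuals,
    )


def write_likelihood_table(table: GenotypeLikelihoodTable, path: str) -> None:
    """Plain wide TSV: one row per locus, three likelihood columns per individual."""
    cols = {"locus": table.locus_id, "contig": table.contig_id}
    for i, ind in enumerate(table.individual_id):
        for g, tag in enumerate(("L0", "L1", "L2")):
            cols[f"{ind}:{tag}"] = table.likelihoods[i, :, g]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_likelihood_table(path: str) -> GenotypeLikelihoodTable:
    df = pd.read_csv(path, sep="\t")
    inds = list(dict.fromkeys(c.rsplit(":", 1)[0] for c in df.columns if ":" in c))
    nl = len(df)
    lik = np.empty((len(inds), nl, 3))
    for i, ind in enumerate(inds):
        for g, tag in enumerate(("L0", "L1", "L2")):
            lik[i, :, g] = df[f"{ind}:{tag}"].to_numpy()
    lik = lik / lik.max(axis=2, keepdims=True)
    flat = np.all(np.abs(lik - lik[:, :, [0]]) < 1e-9, axis=2)
    return GenotypeLikelihoodTable(
        likelihoods=lik,
        has_read=~flat,
        contig_id=df["contig"].to_numpy(str),
        locus_id=df["locus"].to_numpy(str),
        alleles=np.array([("A", "G")] * nl, dtype=object),
        n_alt_alleles=np.ones(nl, dtype=int),
        individual_id=np.array(inds),
    )


def write_metadata(samples: SampleFrame, path: str) -> None:
    samples.table.to_csv(path, index=False)


def read_metadata(path: str, individuals: np.ndarray | None = None) -> SampleFrame:
    """Read the individual → lek → complex table; optionally check coverage
    of a genotyped individual list and raise naming any absentees."""
    frame = SampleFrame(pd.read_csv(path))
    if individuals is not None:
        missing = sorted(set(map(str, individuals)) - set(map(str, frame.individuals)))
        if missing:
            raise ValueError(f"individuals absent from metadata: {missing}")
        order = {str(ind): i for i, ind in enumerate(frame.individuals)}
        idx = [order[str(ind)] for ind in individuals]
        frame = SampleFrame(frame.table.iloc[idx].reset_index(drop=True))
    return frame


def write_esri_ascii(raster: ResistanceRaster, path: str) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:.6f}\n")
        fh.write(f"yllcorner {raster.origin[1]:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_esri_ascii(path: str) -> ResistanceRaster:
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {values.shape} does not match header")
    return ResistanceRaster(
        values,
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        cell_size=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_barriers(barriers: BarrierSet, path: str) -> None:
    pd.DataFrame(barriers.segments, columns=["x1", "y1", "x2", "y2"]).to_csv(path, index=False)


def read_barriers(path: str, buffer_radius: float = 100.0, permeability: str = "permeable") -> BarrierSet:
    df = pd.read_csv(path)
    return BarrierSet(df[["x1", "y1", "x2", "y2"]].to_numpy(), buffer_radius, permeability)


def write_dosage_matrix(dosage: DosageMatrix, path: str) -> None:
    """Individuals × loci TSV of composite genotypes."""
    idx = dosage.individual_id if dosage.individual_id is not None else range(dosage.n_individuals)
    cols = dosage.locus_id if dosage.locus_id is not None else range(dosage.n_loci)
    pd.DataFrame(dosage.dosage, index=list(idx), columns=list(cols)).to_csv(
        path, sep="\t", float_format="%.5f"
    )


def write_locus_summary(dosage: DosageMatrix, table: GenotypeLikelihoodTable, path: str) -> None:
    """Per-locus q̄, MAF, and call rate CSV."""
    q = dosage.allele_freq_posterior_mean
    pd.DataFrame(
        {
            "locus": table.locus_id,
            "q_posterior_mean": q,
            "maf": np.minimum(q, 1 - q),
            "call_rate": table.has_read.mean(axis=0),
        }
    ).to_csv(path, index=False, float_format="%.5f")


def write_pairwise_matrix(matrix: PairwiseLekMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path)


def read_pairwise_matrix(path: str, kind: str) -> PairwiseLekMatrix:
    df = pd.read_csv(path, index_col=0)
    return PairwiseLekMatrix(list(df.index), df.to_numpy(), kind)
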