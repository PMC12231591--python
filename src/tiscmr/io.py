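"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as a dosage TSV (individuals x SNPs, header of SNP ids,
first column of individual ids) or are derived from VCF GT fields;
expression as MatrixMarket counts plus ``genes.tsv`` and ``cells.tsv``
(cell_id, individual_id, pseudotime, depth); phenotypes as a two-column TSV;
simulation ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .simulate import CellExpressionDataset, GenotypeMatrix, SimTruth

__all__ = [
    "write_genotypes_tsv", "read_genotypes_tsv", "read_vcf_dosages",
    "write_minimal_vcf", "write_expression_mtx", "read_expression_mtx",
    "write_phenotypes_tsv", "read_phenotypes_tsv", "write_truth_json",
]


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, index=genotypes.individual_ids,
                      columns=genotypes.snp_ids)
    df.to_csv(path, sep="\t", index_label="individual_id")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy(dtype=np.int8)
    freqs = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages, snp_ids=list(df.columns), allele_freqs=freqs,
        individual_ids=[str(i) for i in df.index],
    )


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Alt-allele dosages from VCF GT fields (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, rows = [], []
    for var in vcf:
        gts = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=hom alt, 3=unknown
        dos = np.where(gts == 3, 0, gts)
        rows.append(dos)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    dosages = np.array(rows, dtype=np.int8).T
    freqs = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(dosages=dosages, snp_ids=snp_ids,
                          allele_freqs=freqs, individual_ids=samples)


def write_minimal_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal single-chromosome VCF with GT fields matching the dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.individual_ids) + "\n")
        for j, snp in enumerate(genotypes.snp_ids):
            gts = "\t".join(gt_map[int(d)] for d in genotypes.dosages[:, j])
            fh.write(f"1\t{j + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_expression_mtx(cells: CellExpressionDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(cells.counts))
    pd.Series(cells.gene_ids, name="gene_id").to_csv(
        outdir / "genes.tsv", sep="\t", index=False)
    cols = ["cell_id", "individual_id", "pseudotime", "depth"]
    cells.cell_meta[cols].to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_expression_mtx(outdir: str | Path) -> CellExpressionDataset:
    outdir = Path(outdir)
    counts = np.asarray(spio.mmread(outdir / "matrix.mtx").todense())
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")["gene_id"].tolist()
    meta = pd.read_csv(outdir / "cells.tsv", sep="\t")
    ind_ids = sorted(meta["individual_id"].unique())
    lookup = {iid: i for i, iid in enumerate(ind_ids)}
    meta["individual_index"] = meta["individual_id"].map(lookup)
    return CellExpressionDataset(counts=counts.astype(np.int64),
                                 cell_meta=meta, gene_ids=genes)


def write_phenotypes_tsv(phenotypes: np.ndarray, individual_ids: list[str],
                         path: str | Path) -> None:
    pd.DataFrame({"individual_id": individual_ids, "Y": phenotypes}).to_csv(
        path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["Y"].to_numpy(), index=df["individual_id"])


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    """Persist the simulation ground truth needed for scoring."""
    payload = {
        "causal_genes": np.atleast_1d(truth.causal_genes).tolist(),
        "gamma": np.atleast_1d(truth.gamma).tolist(),
        "pleiotropic_snps": np.atleast_1d(truth.pleiotropic_snps).tolist(),
        "theta": np.atleast_1d(truth.theta).tolist(),
        "true_snp_gene_pairs": sorted(truth.true_snp_gene_pairs),
        "effect_mode": truth.effects.mode,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
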