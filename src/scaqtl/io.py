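"""Readers and writers for the pipeline's on-disk formats.

Counts travel as MatrixMarket (cells x peaks) with a BED peak file
(0-based, half-open) and a TSV cell-metadata table; genotypes as a dosage
TSV (rows = SNPs) or a minimal VCF; summary statistics, QTL records and
topic matrices as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_dosages_tsv",
    "read_dosages_tsv",
    "write_vcf",
    "read_summary_stats",
    "write_summary_stats",
]

CELL_COLUMNS = [
    "cell_id",
    "donor",
    "library",
    "study",
    "visit",
    "TSSEnrichment",
    "MTratio",
    "log10nFrags",
]


def write_dataset(ds, outdir: str | Path, write_vcf_file: bool = False) -> None:
    """Write a :class:`~scaqtl.synthdata.SimulatedDataset` bundle to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "counts.mtx", sparse.coo_matrix(ds.adata.X))
    ds.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        out / "peaks.bed", sep="\t", header=False, index=False
    )
    cells = ds.adata.obs.reset_index()[CELL_COLUMNS + ["depth"]]
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    write_dosages_tsv(ds.dosages, ds.snps, out / "dosages.tsv")
    truth = pd.DataFrame(
        {
            "peak_id": ds.peaks["peak_id"],
            "causal_snp": ds.truth.causal_snp_per_peak,
            "beta_true": ds.truth.beta_true,
            "delta_true": ds.truth.delta_true,
        }
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if write_vcf_file:
        write_vcf(ds.dosages, ds.snps, out / "genotypes.vcf")


def read_dataset(indir: str | Path):
    """Read back a dataset bundle -> (AnnData, peaks, snps, dosages)."""
    d = Path(indir)
    X = sparse.csr_matrix(spio.mmread(d / "counts.mtx"))
    peaks = pd.read_csv(
        d / "peaks.bed", sep="\t", names=["chrom", "start", "end", "peak_id"]
    )
    cells = pd.read_csv(d / "cells.tsv", sep="\t")
    obs = cells.set_index("cell_id")
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=peaks["peak_id"]))
    dosages, snps = read_dosages_tsv(d / "dosages.tsv")
    return adata, peaks, snps, dosages


def write_dosages_tsv(dosages: np.ndarray, snps: pd.DataFrame, path) -> None:
    """Dosage table: one row per SNP, donor columns after the annotation."""
    t = snps[["snp", "chrom", "pos", "ea", "oa"]].copy()
    for d in range(dosages.shape[0]):
        t[f"donor{d}"] = dosages[d]
    t.to_csv(path, sep="\t", index=False)


def read_dosages_tsv(path) -> tuple[np.ndarray, pd.DataFrame]:
    t = pd.read_csv(path, sep="\t")
    donor_cols = [c for c in t.columns if c.startswith("donor")]
    dosages = t[donor_cols].to_numpy().T
    return dosages, t[["snp", "chrom", "pos", "ea", "oa"]]


def write_vcf(dosages: np.ndarray, snps: pd.DataFrame, path) -> None:
    """Minimal unphased-GT VCF for the donor panel."""
    n_donors = dosages.shape[0]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"donor{d}" for d in range(n_donors))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, row in snps.reset_index(drop=True).iterrows():
            gts = "\t".join(gt_map[int(dosages[d, j])] for d in range(n_donors))
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t{row['oa']}\t"
                f"{row['ea']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


SUMMARY_COLUMNS = ["snp", "chrom", "pos", "ea", "oa", "beta", "se", "p", "maf", "n"]


def write_summary_stats(table: pd.DataFrame, path) -> None:
    table[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
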