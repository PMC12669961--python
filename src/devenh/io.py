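"""Plain-text readers and writers for the pipeline's file formats.

Fragments are 5-column headerless TSV (chrom, start, end, barcode, count;
0-based half-open), TSS annotation is BED6, RNA counts are MTX with row and
column name files, SNP tables are VCF-like TSV with 1-based positions, the
liftover chain is a simplified block-offset table, and planted truth is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .synthetic import PlantedTruth, SyntheticStudy

__all__ = [
    "write_fragments", "read_fragments", "write_tss_bed", "read_tss_bed",
    "write_rna_mtx", "read_rna_mtx", "write_snp_table", "read_snp_table",
    "write_chain", "read_chain", "write_peaks_bed", "write_truth_json",
    "read_truth_json", "write_study",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def write_fragments(fragments: pd.DataFrame, path) -> None:
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS)


def write_tss_bed(tss: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": tss["chrom"], "start": tss["tss"], "end": tss["tss"] + 1,
        "name": tss["gene"], "score": 0, "strand": tss.get("strand", "+"),
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame({"chrom": bed["chrom"], "tss": bed["start"],
                         "gene": bed["name"], "strand": bed["strand"]})


def write_rna_mtx(counts: pd.DataFrame, prefix) -> None:
    prefix = Path(prefix)
    scipy_io.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".barcodes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_rna_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = scipy_io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    barcodes = prefix.with_suffix(".barcodes.txt").read_text().splitlines()
    genes = prefix.with_suffix(".genes.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=barcodes, columns=genes)


def write_snp_table(gwas: pd.DataFrame, path) -> None:
    gwas.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_chain(chain: pd.DataFrame, path) -> None:
    chain.to_csv(path, sep="\t", index=False)


def read_chain(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6+ with name, score x 10 (rounded), strand '.', summit and cluster."""
    bed = pd.DataFrame({
        "chrom": peaks["chrom"], "start": peaks["start"], "end": peaks["end"],
        "name": peaks.index, "score": (peaks["score"] * 10).round().astype(int),
        "strand": ".",
        "summit": peaks["summit"] if "summit" in peaks else -1,
        "cluster": peaks["cluster"] if "cluster" in peaks else ".",
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def _df_to_records(df: pd.DataFrame) -> list[dict]:
    out = []
    for _, row in df.iterrows():
        rec = {}
        for k, v in row.items():
            if isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif isinstance(v, np.bool_):
                v = bool(v)
            elif v is not None and not isinstance(v, (str, int, float, bool, list)):
                v = None if pd.isna(v) else v
            rec[k] = v
        out.append(rec)
    return out


def write_truth_json(truth: PlantedTruth, path) -> None:
    payload = {
        "peaks": _df_to_records(truth.peaks),
        "snps": _df_to_records(truth.snps),
        "doublet_barcodes": list(truth.doublet_barcodes),
        "hvg_genes": list(truth.hvg_genes),
        "low_quality_barcodes": list(truth.low_quality_barcodes),
        "rna_outlier_barcodes": list(truth.rna_outlier_barcodes),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    peaks = pd.DataFrame(payload["peaks"])
    if "clusters" in peaks:
        peaks["clusters"] = peaks["clusters"].map(tuple)
    return PlantedTruth(
        peaks=peaks,
        snps=pd.DataFrame(payload["snps"]),
        doublet_barcodes=payload["doublet_barcodes"],
        hvg_genes=payload["hvg_genes"],
        low_quality_barcodes=payload["low_quality_barcodes"],
        rna_outlier_barcodes=payload["rna_outlier_barcodes"],
    )


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write every table of a synthetic study; returns the path map."""
    from .motifs import write_pwms

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fragments": outdir / "fragments.tsv",
        "cells": outdir / "cells.csv",
        "rna": outdir / "rna",
        "tss": outdir / "tss.bed",
        "snps": outdir / "snps.tsv",
        "chain": outdir / "chain.tsv",
        "genotypes": outdir / "genotypes.csv",
        "pwms": outdir / "pwms.jaspar",
        "roles": outdir / "tf_roles.csv",
        "truth": outdir / "truth.json",
        "genome": outdir / "genome.fa",
    }
    write_fragments(study.fragments, paths["fragments"])
    study.cells.to_csv(paths["cells"], index=False)
    write_rna_mtx(study.rna, paths["rna"])
    write_tss_bed(study.reference.tss, paths["tss"])
    write_snp_table(study.gwas, paths["snps"])
    write_chain(study.chain, paths["chain"])
    study.genotypes.to_csv(paths["genotypes"])
    write_pwms(study.reference.pwms, paths["pwms"])
    study.reference.roles.to_csv(paths["roles"], index=False)
    write_truth_json(study.truth, paths["truth"])
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(study.reference.genome):
            fh.write(f">{chrom}\n")
            seq = study.reference.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    return {k: str(v) for k, v in paths.items()}
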