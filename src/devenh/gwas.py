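"""The GWAS variant-prioritization cascade.

Stages: suggestive-significance filter (P < 1e-5), build liftover
(GRCh37 -> GRCh38 via a block-offset chain), selection of group-differential
peaks (mean difference or FDR, then log2 fold change, then peak-score
filters), SNP/peak overlap, and collapse of SNPs in strong LD (r2 > 0.9)
into loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CascadeParams", "liftover", "cascade_select_peaks",
           "overlap_snps_peaks", "compute_r2", "ld_collapse", "prioritize",
           "PrioritizedLocus"]


@dataclass
class CascadeParams:
    """Printed thresholds of the cascade; comparisons are strict exactly
    where the wording is strict ("more than" / "less than")."""

    p_max: float = 1e-5
    mean_diff_min: float = 0.03
    fdr_max: float = 0.01
    log2fc_min: float = 2.75
    score_min_combined: float = 25.0
    score_min_dev: float = 10.0
    r2_collapse: float = 0.9
    genomewide_p: float = 5e-8

    def __post_init__(self) -> None:
        for name in ("p_max", "mean_diff_min", "fdr_max", "log2fc_min",
                     "score_min_combined", "score_min_dev", "r2_collapse",
                     "genomewide_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p_max <= self.genomewide_p:
            raise ValueError("p_max must exceed the genome-wide threshold")


def liftover(snps: pd.DataFrame, chain: pd.DataFrame
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map SNP positions between builds via a block-offset chain table.

    ``chain`` columns: src_chrom, src_start, src_end (1-based inclusive),
    dst_chrom, offset.  SNPs falling in no block are returned separately.
    SNPs already in the target build pass through with a warning.
    """
    if "build" in snps.columns and (snps["build"] == "GRCh38").any():
        warnings.warn("some SNPs already in GRCh38; passing them through")
    lifted_rows, unmapped_rows = [], []
    blocks = {c: g.sort_values("src_start") for c, g in chain.groupby("src_chrom")}
    for _, s in snps.iterrows():
        if s.get("build") == "GRCh38":
            lifted_rows.append(s)
            continue
        g = blocks.get(s["chrom"])
        hit = None
        if g is not None:
            m = g[(g["src_start"] <= s["pos"]) & (s["pos"] <= g["src_end"])]
            if len(m):
                hit = m.iloc[0]
        if hit is None:
            unmapped_rows.append(s)
        else:
            s = s.copy()
            s["chrom"] = hit["dst_chrom"]
            s["pos"] = int(s["pos"]) + int(hit["offset"])
            s["build"] = "GRCh38"
            lifted_rows.append(s)
    lifted = pd.DataFrame(lifted_rows, columns=snps.columns).reset_index(drop=True)
    unmapped = pd.DataFrame(unmapped_rows, columns=snps.columns).reset_index(drop=True)
    return lifted, unmapped


def cascade_select_peaks(
    da: pd.DataFrame,
    cluster_scores: pd.DataFrame,
    params: CascadeParams | None = None,
) -> tuple[list, pd.DataFrame]:
    """Select group-differential peaks through the threshold cascade.

    A peak is selected iff (mean_diff > mean_diff_min OR fdr < fdr_max)
    AND log2fc > log2fc_min AND combined score >= score_min_combined AND
    developmental-only score >= score_min_dev.  ``cluster_scores`` needs
    columns ``combined_score`` and ``dev_score`` (NaN when the peak was not
    called on developmental cells — such peaks are rejected with a reason).
    """
    params = params or CascadeParams()
    table = da.join(cluster_scores, how="left")
    reasons = []
    for pid, row in table.iterrows():
        why = []
        if not (row["mean_diff"] > params.mean_diff_min or row["fdr"] < params.fdr_max):
            why.append("stage1_mean_diff_fdr")
        if not row["log2fc"] > params.log2fc_min:
            why.append("log2fc")
        if not (pd.notna(row.get("combined_score")) and row["combined_score"] >= params.score_min_combined):
            why.append("combined_score")
        if pd.isna(row.get("dev_score")):
            why.append("missing_dev_score")
        elif not row["dev_score"] >= params.score_min_dev:
            why.append("dev_score")
        reasons.append(";".join(why))
    table = table.copy()
    table["reject_reason"] = reasons
    table["selected"] = table["reject_reason"] == ""
    return list(table.index[table["selected"]]), table


def overlap_snps_peaks(
    snps: pd.DataFrame,
    peaks: pd.DataFrame,
    p_max: float = 1e-5,
) -> pd.DataFrame:
    """(snp, peak) pairs for significant SNPs inside selected peaks.

    SNP positions are 1-based, peaks 0-based half-open: a SNP overlaps iff
    start < pos <= end in 1-based terms (equivalently start <= pos-1 < end
    0-based).  The P filter is strict (p_gwas < p_max).
    """
    if "build" in snps.columns:
        builds = set(snps["build"].unique())
        if builds - {"GRCh38"}:
            raise ValueError(f"SNPs must be lifted to GRCh38 first (got {builds})")
    sig = snps[snps["P"] < p_max]
    rows = []
    by_chrom = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")}
    for _, s in sig.iterrows():
        g = by_chrom.get(s["chrom"])
        if g is None:
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        pos0 = int(s["pos"]) - 1
        i = np.searchsorted(starts, pos0, side="right") - 1
        if i >= 0 and pos0 < ends[i]:
            rows.append({"rsid": s["rsid"], "chrom": s["chrom"], "pos": int(s["pos"]),
                         "P": s["P"], "peak_id": g.index[i]})
    return pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "P", "peak_id"])


def compute_r2(genotypes: pd.DataFrame, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two allele-dosage columns."""
    a = genotypes[snp_a].to_numpy(dtype=float)
    b = genotypes[snp_b].to_numpy(dtype=float)
    if len(a) < 2:
        raise ValueError("need at least two individuals")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic genotype column; r2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_collapse(
    overlaps: pd.DataFrame,
    genotypes: pd.DataFrame | None,
    r2_collapse: float = 0.9,
    r2_table: pd.DataFrame | None = None,
) -> list[dict]:
    """Collapse overlapping SNPs into loci: connected components of the
    graph with an edge wherever r2 strictly exceeds ``r2_collapse``.

    The representative of a locus is its lowest-P member.  Pairs with no
    genotype/r2 information are treated as r2 = 0.
    """
    rsids = list(overlaps["rsid"])
    parent = {r: r for r in rsids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i, a in enumerate(rsids):
        for b in rsids[i + 1:]:
            r2 = 0.0
            if r2_table is not None and a in r2_table.index and b in r2_table.columns:
                r2 = float(r2_table.loc[a, b])
            elif genotypes is not None and a in genotypes.columns and b in genotypes.columns:
                try:
                    r2 = compute_r2(genotypes, a, b)
                except ValueError:
                    r2 = 0.0
            if r2 > r2_collapse:
                union(a, b)
    comps: dict[str, set] = {}
    for r in rsids:
        comps.setdefault(find(r), set()).add(r)
    p_of = dict(zip(overlaps["rsid"], overlaps["P"]))
    loci = []
    for members in comps.values():
        rep = min(members, key=lambda r: (p_of[r], r))
        loci.append({"members": frozenset(members), "representative": rep})
    loci.sort(key=lambda d: d["representative"])
    return loci


@dataclass
class PrioritizedLocus:
    locus_id: str
    members: frozenset
    representative: str
    peak_id: str
    peak_clusters: tuple
    genomewide_significant: bool
    shared_with_bo: bool
    allele_effects: list = field(default_factory=list)


def prioritize(
    snps: pd.DataFrame,
    chain: pd.DataFrame,
    da: pd.DataFrame,
    cluster_scores: pd.DataFrame,
    peaks: pd.DataFrame,
    genotypes: pd.DataFrame | None,
    params: CascadeParams | None = None,
    *,
    peak_cluster_membership: dict | None = None,
    bo_peaks: set | None = None,
    allele_effects: dict | None = None,
) -> tuple[list[PrioritizedLocus], dict]:
    """End-to-end cascade composition; returns loci and a stage waterfall.

    ``peak_cluster_membership`` maps peak_id -> tuple of clusters the peak
    was called in; ``bo_peaks`` is the set of peaks also called in Barrett's
    columnar clusters; ``allele_effects`` maps rsid -> list of
    :class:`~devenh.motifs.AlleleEffect`.
    """
    params = params or CascadeParams()
    waterfall = {"snps_input": len(snps)}
    lifted, unmapped = liftover(snps, chain)
    waterfall["snps_lifted"] = len(lifted)
    waterfall["snps_unmapped"] = len(unmapped)
    sig = lifted[lifted["P"] < params.p_max]
    waterfall["snps_significant"] = len(sig)
    selected, _ = cascade_select_peaks(da, cluster_scores, params)
    waterfall["peaks_selected"] = len(selected)
    overlaps = overlap_snps_peaks(sig, peaks.loc[selected], params.p_max)
    waterfall["snps_in_selected_peaks"] = len(overlaps)
    loci_raw = ld_collapse(overlaps, genotypes, params.r2_collapse)
    waterfall["loci"] = len(loci_raw)
    peak_of = dict(zip(overlaps["rsid"], overlaps["peak_id"]))
    p_of = dict(zip(overlaps["rsid"], overlaps["P"]))
    loci = []
    for i, locus in enumerate(loci_raw):
        rep = locus["representative"]
        pid = peak_of[rep]
        loci.append(PrioritizedLocus(
            locus_id=f"locus_{i:03d}",
            members=locus["members"],
            representative=rep,
            peak_id=pid,
            peak_clusters=tuple(peak_cluster_membership.get(pid, ())) if peak_cluster_membership else (),
            genomewide_significant=bool(p_of[rep] < params.genomewide_p),
            shared_with_bo=bool(pid in bo_peaks) if bo_peaks is not None else False,
            allele_effects=sum((allele_effects.get(r, []) for r in sorted(locus["members"])), [])
            if allele_effects else [],
        ))
    return loci, waterfall
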