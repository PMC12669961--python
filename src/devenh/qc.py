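"""Per-cell and per-gene quality control, normalization and metacells.

Implements the RNA-side QC (MAD outlier filters, doublet ceilings), the
ATAC-side QC (TSS enrichment and fragment-count thresholds), gene filtering,
pooled-deconvolution size factors, log normalization, highly-variable-gene
selection by mean-variance decomposition, in-silico doublet flagging, and
pseudo-multiome metacell construction.

Insertion-site convention: a fragment contributes two Tn5 insertion sites,
its ``start`` and ``end - 1`` (0-based); all window counting in this package
uses those two coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.linalg import lsqr
from scipy import sparse, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QcPolicy", "compute_qc_metrics", "compute_tss_enrichment", "filter_cells",
    "filter_genes", "deconvolution_size_factors", "normalize_log", "hvg_select",
    "in_silico_doublet_flags", "build_metacells", "MetacellResult",
    "insertion_sites",
]


@dataclass
class QcPolicy:
    """Thresholds for every QC mode; defaults follow the study design."""

    mad_k_library: float = 1.0
    mad_k_genes: float = 1.0
    mad_k_mito: float = 2.0
    aggregated_mad_k: tuple[float, float, float] = (2.5, 3.0, 3.0)
    doublet_ceiling: float = 50_000.0
    doublet_ceiling_quantile: float = 0.995
    min_tss: float = 4.0
    min_fragments: int = 1000
    min_gene_mean: float = 0.01
    multiome_min_gex: int = 500
    multiome_max_mito: float = 0.05
    mad_scaled: bool = False  # if True, scale MAD by 1.4826

    def __post_init__(self) -> None:
        for name in ("mad_k_library", "mad_k_genes", "mad_k_mito", "doublet_ceiling",
                     "min_tss", "min_fragments", "min_gene_mean", "multiome_min_gex",
                     "multiome_max_mito"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def insertion_sites(fragments: pd.DataFrame) -> pd.DataFrame:
    """Expand fragments into per-insertion records (chrom, pos, barcode)."""
    starts = fragments[["chrom", "start", "barcode"]].rename(columns={"start": "pos"})
    ends = fragments[["chrom", "end", "barcode"]].copy()
    ends["pos"] = ends.pop("end") - 1
    return pd.concat([starts, ends[["chrom", "pos", "barcode"]]], ignore_index=True)


def compute_tss_enrichment(
    fragments: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    *,
    signal_halfwidth: int = 50,
    flank_inner: int = 1900,
    flank_outer: int = 2000,
) -> pd.Series:
    """Per-cell TSS enrichment score.

    Insertions are counted in the signal windows (TSS +/- ``signal_halfwidth``)
    and in the distal flank windows ([-outer, -inner] and [+inner, +outer])
    aggregated over all TSSs.  The score is the signal insertion count over
    the flank count rescaled to the signal width, with a pseudocount of one
    insertion on each:

        score = (n_signal + 1) / (n_flank * signal_bp / flank_bp + 1)

    A cell with no promoter-proximal insertions therefore scores <= 1, and a
    flat genome-wide insertion rate gives a score near 1.
    """
    if len(tss_annotation) == 0:
        raise ValueError("need at least one TSS")
    ins = insertion_sites(fragments)
    barcodes = pd.Index(fragments["barcode"].unique())
    codes = pd.Categorical(ins["barcode"], categories=barcodes).codes
    n_signal = np.zeros(len(barcodes))
    n_flank = np.zeros(len(barcodes))
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in tss_annotation.groupby("chrom")}
    shared_chroms = set(ins["chrom"]).intersection(tss_by_chrom)
    if not shared_chroms:
        import warnings

        warnings.warn("no TSS on any fragment chromosome; scores set to 0")
        return pd.Series(0.0, index=barcodes)
    for chrom, grp in ins.groupby("chrom"):
        t = tss_by_chrom.get(chrom)
        if t is None:
            continue
        pos = grp["pos"].to_numpy()
        c = codes[grp.index.to_numpy()]
        idx = np.clip(np.searchsorted(t, pos), 0, len(t) - 1)
        # distance to nearest TSS (windows never overlap between TSSs here if
        # spacing exceeds 2 * flank_outer; nearest-TSS assignment is exact for
        # non-overlapping windows and a good approximation otherwise)
        d_right = np.abs(t[idx] - pos)
        d_left = np.abs(t[np.maximum(idx - 1, 0)] - pos)
        d = np.minimum(d_right, d_left)
        sig = d <= signal_halfwidth
        fl = (d >= flank_inner) & (d <= flank_outer)
        np.add.at(n_signal, c[sig], 1)
        np.add.at(n_flank, c[fl], 1)
    n_tss = len(tss_annotation)
    signal_bp = (2 * signal_halfwidth + 1) * n_tss
    flank_bp = 2 * (flank_outer - flank_inner + 1) * n_tss
    score = (n_signal + 1.0) / (n_flank * (signal_bp / flank_bp) + 1.0)
    return pd.Series(score, index=barcodes, name="tss_enrichment")


def compute_qc_metrics(
    counts: pd.DataFrame | None = None,
    fragments: pd.DataFrame | None = None,
    tss_annotation: pd.DataFrame | None = None,
    *,
    mito_prefix: str = "MT-",
) -> pd.DataFrame:
    """One metrics row per barcode seen in any modality.

    Missing-modality fields are NaN; a barcode present in the fragment file
    with zero records would simply be absent, but a barcode present in the
    RNA matrix with no fragments gets n_fragments 0 and tss_enrichment 0.
    """
    if counts is None and fragments is None:
        raise ValueError("need at least one modality")
    pieces: list[pd.DataFrame] = []
    if counts is not None:
        lib = counts.sum(axis=1)
        genes = (counts > 0).sum(axis=1)
        mito_cols = [c for c in counts.columns if str(c).startswith(mito_prefix)]
        mito = counts[mito_cols].sum(axis=1) if mito_cols else pd.Series(0, index=counts.index)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(lib > 0, mito / lib.replace(0, np.nan), 0.0)
        pieces.append(pd.DataFrame({
            "library_size": lib, "genes_detected": genes,
            "mito_fraction": mito_frac, "gex_reads": lib,
        }))
    if fragments is not None:
        n_frag = fragments.groupby("barcode").size()
        frag_df = pd.DataFrame({"n_fragments": n_frag})
        if tss_annotation is not None:
            frag_df["tss_enrichment"] = compute_tss_enrichment(fragments, tss_annotation)
        pieces.append(frag_df)
    metrics = pd.concat(pieces, axis=1)
    if fragments is not None:
        metrics["n_fragments"] = metrics["n_fragments"].fillna(0).astype(int)
        if "tss_enrichment" in metrics:
            metrics["tss_enrichment"] = metrics["tss_enrichment"].fillna(0.0)
    metrics.index.name = "barcode"
    return metrics


def _mad(values: np.ndarray, scaled: bool) -> float:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    return float(mad * (1.4826 if scaled else 1.0))


def filter_cells(
    metrics: pd.DataFrame,
    policy: QcPolicy,
    mode: str,
) -> tuple[list, pd.DataFrame]:
    """Apply per-cell QC; returns (retained barcodes, per-cell decision table).

    Modes: ``rna`` (one-sided MAD filters + fixed doublet ceiling), ``atac``
    (TSS enrichment >= min_tss and fragments >= min_fragments), ``multiome``
    (ATAC rules plus GEX reads and mitochondrial fraction), ``aggregated``
    (relaxed MADs and a quantile doublet ceiling).
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    if mode not in ("rna", "atac", "multiome", "aggregated"):
        raise ValueError(f"unknown mode {mode!r}")
    reasons = pd.DataFrame(index=metrics.index)
    reasons["reason"] = ""

    def _flag(mask: pd.Series, label: str) -> None:
        sel = mask.fillna(False).astype(bool)
        reasons.loc[sel, "reason"] = reasons.loc[sel, "reason"].where(
            reasons.loc[sel, "reason"] == "", reasons.loc[sel, "reason"] + ";"
        ) + label

    if mode in ("rna", "aggregated"):
        ks = ((policy.mad_k_library, policy.mad_k_genes, policy.mad_k_mito)
              if mode == "rna" else policy.aggregated_mad_k)
        lib = metrics["library_size"].to_numpy(float)
        genes = metrics["genes_detected"].to_numpy(float)
        mito = metrics["mito_fraction"].to_numpy(float)
        lib_thr = np.median(lib) - ks[0] * _mad(lib, policy.mad_scaled)
        gene_thr = np.median(genes) - ks[1] * _mad(genes, policy.mad_scaled)
        mito_thr = np.median(mito) + ks[2] * _mad(mito, policy.mad_scaled)
        ceiling = (policy.doublet_ceiling if mode == "rna"
                   else float(np.quantile(lib, policy.doublet_ceiling_quantile)))
        _flag(metrics["library_size"] < lib_thr, "low_library")
        _flag(metrics["genes_detected"] < gene_thr, "low_genes")
        _flag(metrics["mito_fraction"] > mito_thr, "high_mito")
        _flag(metrics["library_size"] > ceiling, "doublet_ceiling")
    if mode in ("atac", "multiome"):
        _flag(metrics["tss_enrichment"] < policy.min_tss, "low_tss")
        _flag(metrics["n_fragments"] < policy.min_fragments, "low_fragments")
    if mode == "multiome":
        _flag(metrics["gex_reads"] < policy.multiome_min_gex, "low_gex")
        _flag(metrics["mito_fraction"] > policy.multiome_max_mito, "high_mito")
    reasons["retained"] = reasons["reason"] == ""
    retained = list(metrics.index[reasons["retained"]])
    return retained, reasons


def filter_genes(counts: pd.DataFrame, policy: QcPolicy) -> list:
    """Genes with mean count per cell >= the policy minimum (default 0.01)."""
    if counts.shape[1] == 0:
        raise ValueError("no genes")
    means = counts.mean(axis=0)
    return list(counts.columns[means >= policy.min_gene_mean])


def deconvolution_size_factors(
    counts: pd.DataFrame,
    pool_sizes: tuple[int, ...] = (21, 41, 61),
) -> pd.Series:
    """Pooled-deconvolution size factors (geometric mean scaled to 1).

    Cells are placed on a ring ordered by library size; for every pool of
    each size, the median across genes of (pool sum / reference pseudo-cell)
    provides one linear equation in the per-cell factors, solved by least
    squares.
    """
    X = counts.to_numpy(dtype=float)
    n, _ = X.shape
    if n < max(pool_sizes):
        raise ValueError(f"need at least {max(pool_sizes)} cells for these pool sizes")
    lib = X.sum(axis=1)
    if (lib == 0).any():
        raise ValueError("all-zero cell in counts")
    order = np.argsort(lib, kind="stable")
    ref = X.mean(axis=0)
    keep = ref > 0
    rows, cols, vals, b = [], [], [], []
    eq = 0
    for s in pool_sizes:
        for i in range(n):
            members = order[(np.arange(i, i + s)) % n]
            pool_sum = X[members].sum(axis=0)
            r = np.median(pool_sum[keep] / ref[keep])
            for m in members:
                rows.append(eq)
                cols.append(m)
                vals.append(1.0)
            b.append(r)
            eq += 1
    # low-weight library-size anchor rows keep the system well conditioned
    w = 0.01
    for j in range(n):
        rows.append(eq)
        cols.append(j)
        vals.append(w)
        b.append(w * lib[j] / lib.mean())
        eq += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    theta = lsqr(A, np.array(b), atol=1e-12, btol=1e-12, iter_lim=20_000)[0]
    if (theta <= 0).any():
        raise ValueError("non-positive deconvolved size factor; use larger pools")
    theta = theta / np.exp(np.mean(np.log(theta)))
    return pd.Series(theta, index=counts.index, name="size_factor")


def normalize_log(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log(1 + 1e6 * count / (factor * mean library size)); natural log.

    Counts are divided by the cell's size factor, scaled so that cell totals
    average one million, then log-transformed with a pseudo-count of 1.
    """
    f = factors.reindex(counts.index).to_numpy(float)
    if (f <= 0).any():
        raise ValueError("size factors must be positive")
    ref = counts.to_numpy(float).sum(axis=1).mean()
    scaled = counts.to_numpy(float) / f[:, None] * (1e6 / ref)
    return pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)


def hvg_select(normalized: pd.DataFrame, *, lowess_frac: float = 0.3,
               bio_min: float = 0.5, fdr_max: float = 0.05) -> pd.DataFrame:
    """Highly variable genes by technical/biological variance decomposition.

    The technical component is a lowess trend of per-gene variance on mean;
    the biological component is the residual.  A normal tail test on the
    residual standardized by a robust (MAD-based) scale gives p-values,
    BH-adjusted; a gene is an HVG iff biological variance > ``bio_min`` and
    FDR < ``fdr_max``.
    """
    if normalized.shape[1] < 20:
        raise ValueError("need at least 20 genes to fit the variance trend")
    means = normalized.mean(axis=0).to_numpy()
    variances = normalized.var(axis=0, ddof=1).to_numpy()
    fitted = lowess(variances, means, frac=lowess_frac, return_sorted=False)
    tech = np.clip(fitted, 1e-12, None)
    bio = variances - tech
    med = np.median(bio)
    scale = 1.4826 * np.median(np.abs(bio - med))
    scale = max(scale, 1e-12)
    z = (bio - med) / scale
    p = stats.norm.sf(z)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": normalized.columns,
        "mean": means,
        "total_variance": variances,
        "technical_variance": tech,
        "biological_variance": bio,
        "p": p,
        "fdr": fdr,
    })
    out["is_hvg"] = (out["biological_variance"] > bio_min) & (out["fdr"] < fdr_max)
    return out


def in_silico_doublet_flags(
    peak_matrix: pd.DataFrame,
    *,
    embedding_dims: int = 15,
    n_synth: int | None = None,
    k: int = 25,
    enrichment: float = 2.0,
    seed: int = 0,
) -> list:
    """Flag putative doublets against synthesized cell-pair profiles.

    ``n_synth`` pseudo-cells are built as sums of random cell pairs and
    co-embedded with the real cells by depth-sensitive LSI (IDF-weighted raw
    counts), where a pair-sum separates from singlets by both composition and
    total signal; a real cell is flagged when the synthetic fraction among its
    k nearest neighbours exceeds ``enrichment`` times the global synthetic
    fraction n_synth / (n_synth + n_cells).
    """
    from sklearn.neighbors import NearestNeighbors

    from .peaks import lsi_embed

    X = peak_matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2 * k:
        raise ValueError("need at least 2k cells")
    # keep the synthetic fraction well below 1/enrichment so the flagging
    # threshold is attainable
    n_synth = max(k, n // 4) if n_synth is None else int(n_synth)
    if n_synth == 0:
        raise ValueError("n_synth must be positive")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=n_synth)
    b = rng.integers(0, n, size=n_synth)
    synth = X[a] + X[b]
    combined = np.vstack([X, synth])
    dims = min(embedding_dims, min(combined.shape) - 1)
    # depth-sensitive LSI: pair-sums separate by composition AND depth
    emb = lsi_embed(combined, d=dims, binarize=False, tf_normalize=False,
                    drop_depth_correlated=False).coords
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n])
    idx = idx[:, 1:]  # drop self
    synth_frac = (idx >= n).mean(axis=1)
    expected = n_synth / (n_synth + n)
    flagged_mask = synth_frac > enrichment * expected
    return list(pd.Index(peak_matrix.index)[flagged_mask])


@dataclass
class MetacellResult:
    rna: pd.DataFrame
    atac: pd.DataFrame
    labels: list
    rna_members: list[list]
    atac_members: list[list]


def build_metacells(
    rna_counts: pd.DataFrame,
    atac_peak_matrix: pd.DataFrame,
    cluster_labels: pd.Series,
    *,
    cells_per_metacell: int = 10,
    seed: int = 0,
) -> MetacellResult:
    """Pseudo-multiome metacells: per cluster, each metacell is the mean of
    ``cells_per_metacell`` cells sampled without replacement, independently
    in each modality."""
    rng = np.random.default_rng(seed)
    rna_rows, atac_rows, labels = [], [], []
    rna_members, atac_members = [], []
    for cluster in sorted(pd.unique(cluster_labels)):
        rna_cells = [c for c in rna_counts.index if cluster_labels.get(c) == cluster]
        atac_cells = [c for c in atac_peak_matrix.index if cluster_labels.get(c) == cluster]
        if min(len(rna_cells), len(atac_cells)) < cells_per_metacell:
            raise ValueError(f"cluster {cluster} smaller than cells_per_metacell")
        n_meta = min(len(rna_cells), len(atac_cells)) // cells_per_metacell
        for m in range(n_meta):
            rs = list(rng.choice(rna_cells, size=cells_per_metacell, replace=False))
            ats = list(rng.choice(atac_cells, size=cells_per_metacell, replace=False))
            rna_rows.append(rna_counts.loc[rs].mean(axis=0))
            atac_rows.append(atac_peak_matrix.loc[ats].mean(axis=0))
            labels.append(cluster)
            rna_members.append(rs)
            atac_members.append(ats)
    idx = [f"meta_{i:04d}" for i in range(len(labels))]
    return MetacellResult(
        rna=pd.DataFrame(rna_rows, index=idx),
        atac=pd.DataFrame(atac_rows, index=idx),
        labels=labels,
        rna_members=rna_members,
        atac_members=atac_members,
    )
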