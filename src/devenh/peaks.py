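"""Summit calling, fixed-width peak standardization, count matrices and LSI.

The summit caller is a deliberately minimal re-implementation of
fixed-window pileup peak calling: with model building and local background
estimation disabled, each Tn5 insertion is extended to a centred window
(shift -75 / extsize 150 gives +/-75 bp), per-bp pileup is compared with the
global mean rate under a Poisson null, and candidate summits are corrected
with Benjamini-Hochberg.  Summits are then standardized to 501 bp intervals
and merged by iteratively keeping the best-scoring candidate and discarding
everything that overlaps it.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import insertion_sites

PEAK_WIDTH = 501

__all__ = ["SummitParams", "LsiEmbedding", "call_summits", "standardize_and_merge",
           "build_peak_matrix", "gene_activity_scores", "lsi_embed"]


@dataclass
class SummitParams:
    """Fixed-window pileup parameters (defaults mirror
    ``--call-summits --keep-dup all --nomodel --nolambda --shift -75
    --extsize 150 -q 0.1``)."""

    shift: int = -75
    extsize: int = 150
    q_max: float = 0.1
    # candidate regions form where the per-bp Poisson p-value is below this
    # fixed threshold; only the final BH filter depends on q_max, so shrinking
    # q_max always returns a subset of summits
    candidate_p: float = 0.1

    def __post_init__(self) -> None:
        if self.extsize <= 0:
            raise ValueError("extsize must be positive")


def call_summits(
    fragments: pd.DataFrame,
    cell_subset=None,
    params: SummitParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Candidate summits with Poisson p, BH q and score = -log10(q).

    Every insertion (both fragment endpoints; duplicates kept) is extended to
    a window of ``extsize`` bp starting at ``pos + shift``; pileup maxima of
    contiguous candidate regions are tested against the global mean pileup.
    """
    params = params or SummitParams()
    frags = fragments if cell_subset is None else fragments[
        fragments["barcode"].isin(set(cell_subset))]
    if len(frags) == 0:
        raise ValueError("no insertions in the selected cells")
    ins = insertion_sites(frags)
    if chrom_lengths is None:
        chrom_lengths = {c: int(g["pos"].max()) + params.extsize + 1
                         for c, g in ins.groupby("chrom")}
    genome_len = sum(chrom_lengths.values())
    lam = len(ins) * params.extsize / genome_len

    rows = []
    for chrom, grp in ins.groupby("chrom"):
        L = chrom_lengths[chrom]
        raw = grp["pos"].to_numpy() + params.shift
        starts = np.clip(raw, 0, L)
        ends = np.clip(raw + params.extsize, 0, L)
        diff = np.zeros(L + 1, dtype=np.int32)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        pileup = np.cumsum(diff[:-1])
        # candidate regions: contiguous runs whose pileup beats the global
        # rate at the fixed candidate threshold
        min_pileup = int(stats.poisson.isf(params.candidate_p, lam)) + 1
        above = pileup >= min_pileup
        if not above.any():
            continue
        bounds = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8), 0]))
        for s, e in zip(bounds[::2], bounds[1::2]):
            seg = pileup[s:e]
            peak_val = int(seg.max())
            # flat-top robustness: bins within ~3 Poisson sd of the max are
            # statistical ties; the summit is the middle of that plateau
            near = np.flatnonzero(seg >= peak_val - 3.0 * np.sqrt(peak_val))
            summit = int(s + near[len(near) // 2])
            p = float(stats.poisson.sf(peak_val - 1, lam))
            rows.append({"chrom": chrom, "position": summit, "pileup": peak_val, "p": p})
    if not rows:
        return pd.DataFrame(columns=["chrom", "position", "pileup", "p", "q", "score"])
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out[out["q"] < params.q_max].reset_index(drop=True)
    out["score"] = -np.log10(np.clip(out["q"], 1e-300, None))
    return out.sort_values(["chrom", "position"], kind="stable").reset_index(drop=True)


def standardize_and_merge(
    summits: pd.DataFrame,
    width: int = PEAK_WIDTH,
    chrom_lengths: dict[str, int] | None = None,
    cluster: str | None = None,
) -> pd.DataFrame:
    """Fixed-width peaks by greedy score-ranked iterative merging.

    Each summit expands to [summit - (width-1)//2, summit + width//2 + 1);
    candidates are ranked by score (descending) and the best one retained
    while every overlapping candidate is discarded, until none remain.
    Summits too close to a chromosome edge are shifted inward and flagged.
    Output is coordinate-sorted and pairwise non-overlapping.
    """
    half = (width - 1) // 2
    cands = summits.copy()
    if len(cands) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "summit", "score",
                                     "cluster", "shifted"])
    cands["start"] = cands["position"] - half
    cands["end"] = cands["start"] + width
    cands["shifted"] = False
    if chrom_lengths is not None:
        for i in cands.index:
            L = chrom_lengths[cands.at[i, "chrom"]]
            s = cands.at[i, "start"]
            if s < 0:
                cands.at[i, "start"], cands.at[i, "end"] = 0, width
                cands.at[i, "shifted"] = True
            elif s + width > L:
                cands.at[i, "start"], cands.at[i, "end"] = L - width, L
                cands.at[i, "shifted"] = True
    else:
        neg = cands["start"] < 0
        cands.loc[neg, "start"], cands.loc[neg, "end"] = 0, width
        cands.loc[neg, "shifted"] = True
    order = cands.sort_values(["score", "chrom", "start"],
                              ascending=[False, True, True], kind="stable")
    kept_rows = []
    kept_by_chrom: dict[str, list[int]] = {}
    kept_ends: dict[str, list[int]] = {}
    for _, row in order.iterrows():
        starts = kept_by_chrom.setdefault(row["chrom"], [])
        ends = kept_ends.setdefault(row["chrom"], [])
        i = bisect.bisect_right(starts, row["start"])
        overlaps = (i > 0 and ends[i - 1] > row["start"]) or (
            i < len(starts) and starts[i] < row["end"])
        if overlaps:
            continue
        starts.insert(i, int(row["start"]))
        ends.insert(i, int(row["end"]))
        kept_rows.append(row)
    out = pd.DataFrame(kept_rows).sort_values(["chrom", "start"], kind="stable")
    out = out.rename(columns={"position": "summit"})
    out["cluster"] = cluster
    cols = ["chrom", "start", "end", "summit", "score", "cluster", "shifted"]
    out = out[[c for c in cols if c in out.columns]].reset_index(drop=True)
    out.index = [f"peak_{i:05d}" for i in range(len(out))]
    out.index.name = "peak_id"
    return out


def _assert_non_overlapping(peaks: pd.DataFrame) -> None:
    for chrom, grp in peaks.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping peaks on {chrom}")


def build_peak_matrix(
    fragments: pd.DataFrame,
    peaks: pd.DataFrame,
    cells=None,
) -> pd.DataFrame:
    """Cell x peak insertion-site count matrix ([start, end) half-open)."""
    _assert_non_overlapping(peaks)
    frags = fragments if cells is None else fragments[fragments["barcode"].isin(set(cells))]
    barcodes = pd.Index(cells) if cells is not None else pd.Index(frags["barcode"].unique())
    ins = insertion_sites(frags)
    codes = pd.Categorical(ins["barcode"], categories=barcodes).codes
    mat = np.zeros((len(barcodes), len(peaks)), dtype=np.int64)
    peak_pos = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")}
    col_of = {pid: j for j, pid in enumerate(peaks.index)}
    for chrom, grp in ins.groupby("chrom"):
        if chrom not in peak_pos:
            continue
        g = peak_pos[chrom]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g.index.to_numpy()
        pos = grp["pos"].to_numpy()
        c = codes[grp.index.to_numpy()]
        ok = c >= 0
        pos, c = pos[ok], c[ok]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        cols = np.array([col_of[i] for i in ids])[idx[inside]]
        np.add.at(mat, (c[inside], cols), 1)
    return pd.DataFrame(mat, index=barcodes, columns=peaks.index)


def gene_activity_scores(
    fragments: pd.DataFrame,
    tss_annotation: pd.DataFrame,
    cells=None,
    window: int = 100_000,
) -> pd.DataFrame:
    """Cell x gene insertion counts within TSS +/- ``window`` (inclusive)."""
    frags = fragments if cells is None else fragments[fragments["barcode"].isin(set(cells))]
    barcodes = pd.Index(cells) if cells is not None else pd.Index(frags["barcode"].unique())
    ins = insertion_sites(frags)
    codes = pd.Categorical(ins["barcode"], categories=barcodes).codes
    genes = tss_annotation["gene"].tolist()
    mat = np.zeros((len(barcodes), len(genes)), dtype=np.int64)
    for chrom, grp in ins.groupby("chrom"):
        sub = tss_annotation[tss_annotation["chrom"] == chrom]
        if len(sub) == 0:
            continue
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos = grp["pos"].to_numpy()[order]
        c = codes[grp.index.to_numpy()][order]
        ok = c >= 0
        pos, c = pos[ok], c[ok]
        for gi, tss in zip(sub.index, sub["tss"]):
            lo = np.searchsorted(pos, tss - window, side="left")
            hi = np.searchsorted(pos, tss + window, side="right")
            if hi > lo:
                col = genes.index(sub.at[gi, "gene"])
                np.add.at(mat[:, col], c[lo:hi], 1)
    return pd.DataFrame(mat, index=barcodes, columns=genes)


@dataclass
class LsiEmbedding:
    """TF-IDF + truncated-SVD embedding of a cell x peak matrix."""

    coords: np.ndarray
    d: int
    singular_values: np.ndarray
    dropped_first: bool = False
    index: pd.Index | None = None


def lsi_embed(
    peak_matrix,
    d: int,
    binarize: bool = True,
    drop_depth_correlated: bool = True,
    tf_normalize: bool = True,
) -> LsiEmbedding:
    """Latent semantic indexing: per-cell term frequency x log inverse
    document frequency, then truncated SVD.  The first component is dropped
    when it correlates (|r| > 0.9) with sequencing depth.

    With ``tf_normalize=False`` rows are left un-normalized (IDF-weighted raw
    counts), which keeps depth information in the embedding — useful when
    depth itself is a signal, as in doublet detection.
    """
    from sklearn.decomposition import TruncatedSVD

    index = peak_matrix.index if isinstance(peak_matrix, pd.DataFrame) else None
    X = np.asarray(peak_matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    if d >= min(X.shape):
        raise ValueError(f"d={d} must be < min(cells, peaks)={min(X.shape)}")
    depth = X.sum(axis=1)
    B = (X > 0).astype(float) if binarize else X
    if tf_normalize:
        row_sums = B.sum(axis=1)
        tf = B / np.where(row_sums > 0, row_sums, 1.0)[:, None]
    else:
        tf = B
    df = (B > 0).sum(axis=0)
    idf = np.log(1.0 + B.shape[0] / (1.0 + df))
    M = tf * idf[None, :]
    svd = TruncatedSVD(n_components=d, algorithm="arpack", random_state=0)
    coords = svd.fit_transform(M)
    sv = svd.singular_values_
    dropped = False
    if drop_depth_correlated and d >= 2 and np.std(coords[:, 0]) > 0 and np.std(depth) > 0:
        r = np.corrcoef(coords[:, 0], depth)[0, 1]
        if abs(r) > 0.9:
            coords = coords[:, 1:]
            dropped = True
    return LsiEmbedding(coords=coords, d=coords.shape[1], singular_values=sv,
                        dropped_first=dropped, index=index)
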