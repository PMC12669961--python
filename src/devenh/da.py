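"""Bias-matched background selection and per-peak Wilcoxon differential
accessibility with Benjamini-Hochberg correction; marker-peak calling.

Accessibility scales
--------------------
``mean_g1``/``mean_g2``/``mean_diff`` are computed on log1p counts
depth-normalized to the median cell depth — the scale on which a mean
difference of ~0.03 is meaningful for a moderately accessible peak.
``log2fc`` uses counts-per-million means with a pseudo-count (default 1), so
that the pseudo-count sits well below a genuinely accessible peak's mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["BackgroundMatch", "match_background", "wilcoxon_da", "marker_peaks",
           "cluster_markers"]


@dataclass
class BackgroundMatch:
    """Nearest-neighbour bias-matched background for a group of cells."""

    group: list
    background: list
    distances: pd.Series  # per group cell, distance to its selected match


def match_background(
    embedding,
    bias: pd.DataFrame,
    group: list,
) -> BackgroundMatch:
    """For each group cell, its nearest non-group neighbour in the
    (embedding (+) standardized bias) space; duplicates removed.

    ``bias`` columns are typically log10 fragment counts and TSS enrichment,
    indexed by barcode; ``embedding`` is an :class:`~devenh.peaks.LsiEmbedding`
    or a plain array aligned to ``bias``.
    """
    from sklearn.neighbors import NearestNeighbors

    coords = getattr(embedding, "coords", embedding)
    index = getattr(embedding, "index", None)
    if index is None:
        index = bias.index
    coords = np.asarray(coords, dtype=float)
    bias = bias.loc[index]
    b = bias.to_numpy(dtype=float)
    sd = b.std(axis=0)
    b = (b - b.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    space = np.hstack([coords, b])
    group_set = set(group)
    is_group = np.array([c in group_set for c in index])
    if (~is_group).sum() == 0:
        raise ValueError("no candidate cells outside the group")
    cand_idx = np.flatnonzero(~is_group)
    nn = NearestNeighbors(n_neighbors=1).fit(space[cand_idx])
    dist, pos = nn.kneighbors(space[is_group])
    matched = [index[cand_idx[p]] for p in pos[:, 0]]
    seen, background = set(), []
    for m in matched:
        if m not in seen:
            seen.add(m)
            background.append(m)
    distances = pd.Series(dist[:, 0], index=[c for c in index if c in group_set])
    return BackgroundMatch(group=list(group), background=background, distances=distances)


def _normalize_for_means(X: np.ndarray) -> np.ndarray:
    """log1p counts rescaled to the median cell depth."""
    depth = X.sum(axis=1)
    med = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    scale = np.where(depth > 0, med / np.where(depth > 0, depth, 1.0), 0.0)
    return np.log1p(X * scale[:, None])


def _cpm(X: np.ndarray) -> np.ndarray:
    depth = X.sum(axis=1)
    scale = np.where(depth > 0, 1e6 / np.where(depth > 0, depth, 1.0), 0.0)
    return X * scale[:, None]


def wilcoxon_da(
    peak_matrix: pd.DataFrame,
    group,
    background,
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Per-peak two-sided Wilcoxon rank-sum of group vs background.

    Uses exact enumeration when both sides have <= 8 cells, otherwise the
    tie-corrected normal approximation; BH correction across peaks.  A peak
    constant across all tested cells gets p = 1 by convention.
    """
    bg = background.background if isinstance(background, BackgroundMatch) else list(background)
    group = list(group)
    if len(group) == 0 or len(bg) == 0:
        raise ValueError("both cell groups must be non-empty")
    X = peak_matrix.to_numpy(dtype=float)
    idx = {c: i for i, c in enumerate(peak_matrix.index)}
    gi = np.array([idx[c] for c in group])
    bi = np.array([idx[c] for c in bg])
    norm = _normalize_for_means(X)
    cpm = _cpm(X)
    mean_g1 = norm[gi].mean(axis=0)
    mean_g2 = norm[bi].mean(axis=0)
    cpm_g1 = cpm[gi].mean(axis=0)
    cpm_g2 = cpm[bi].mean(axis=0)
    log2fc = np.log2((cpm_g1 + epsilon) / (cpm_g2 + epsilon))

    x, y = norm[gi], norm[bi]
    method = "exact" if (len(gi) <= 8 and len(bi) <= 8) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue, dtype=float)
    raw_both = X[np.concatenate([gi, bi])]
    constant = (raw_both == raw_both[0]).all(axis=0)
    p = np.where(constant | ~np.isfinite(p), 1.0, np.clip(p, 0.0, 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({
        "peak_id": peak_matrix.columns,
        "mean_g1": mean_g1, "mean_g2": mean_g2,
        "mean_diff": mean_g1 - mean_g2,
        "log2fc": log2fc,
        "p": p, "fdr": fdr,
    }).set_index("peak_id")


def marker_peaks(da: pd.DataFrame, log2fc_min: float = 1.0,
                 fdr_max: float = 0.01) -> pd.DataFrame:
    """Marker flag: log2 fold change strictly above ``log2fc_min`` and
    FDR at or below ``fdr_max``."""
    out = da.copy()
    out["is_marker"] = (out["log2fc"] > log2fc_min) & (out["fdr"] <= fdr_max)
    return out


def cluster_markers(
    peak_matrix: pd.DataFrame,
    clusters: pd.Series,
    embedding,
    bias: pd.DataFrame,
    log2fc_min: float = 1.0,
    fdr_max: float = 0.01,
) -> dict:
    """Marker peaks per cluster against a bias-matched background."""
    out = {}
    for cluster in sorted(pd.unique(clusters)):
        group = [c for c in peak_matrix.index if clusters.get(c) == cluster]
        match = match_background(embedding, bias, group)
        da = wilcoxon_da(peak_matrix, group, match)
        out[cluster] = marker_peaks(da, log2fc_min, fdr_max)
    return out
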