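"""Position-weight-matrix handling and allele-level motif analysis.

This module covers the motif side of the pipeline: parsing JASPAR-style PWM
libraries, calibrating per-motif log-odds thresholds on random background
k-mers, scanning sequences for best binding sites, classifying whether a risk
allele creates or disrupts a motif match, hypergeometric motif enrichment in
marker peaks, and chromVAR-style per-cell motif deviation scores.

Conventions
-----------
* Sequences are uppercase A/C/G/T strings; PWM columns are ordered A, C, G, T.
* Log-odds are base-2: ``sum_pos log2(p_pos(base) / bg(base))``.
* A "hit" means the best site score on either strand reaches the motif's
  calibrated threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.multitest import multipletests

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G in index space

__all__ = [
    "Pwm",
    "AlleleEffect",
    "load_pwms",
    "write_pwms",
    "calibrate_threshold",
    "best_site_score",
    "classify_allele_effect",
    "motif_hits",
    "motif_enrichment",
    "motif_deviation_scores",
]


def encode(sequence: str) -> np.ndarray:
    """Encode an A/C/G/T string as an int array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_IDX.items():
        out[arr == ord(base)] = idx
    if (out < 0).any():
        bad = sequence[int(np.argmax(out < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


@dataclass
class Pwm:
    """A probability PWM with background frequencies and a score threshold.

    ``matrix`` has shape (L, 4); each row is a probability vector over
    A, C, G, T.  ``threshold`` is the calibrated log-odds cutoff used to
    declare a binding site.
    """

    motif_id: str
    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PWM rows must sum to 1 (got {sums})")
        if (self.matrix <= 0).any():
            raise ValueError("PWM probabilities must be strictly positive")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) base-2 log-odds against the background."""
        return np.log2(self.matrix / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class AlleleEffect:
    """Creates/disrupts call for one (SNP, motif) pair.

    ``predicted_direction`` gives the expected change in enhancer activity:
    creating a repressor site or destroying an activator site both predict
    reduced activity.
    """

    rsid: str
    motif_id: str
    tf_name: str
    tf_role: str
    ref_best: float
    alt_best: float
    effect_class: str  # creates | disrupts | none
    predicted_direction: str  # reduced | increased | none


def _counts_to_probabilities(counts: np.ndarray, pseudocount: float = 0.8) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    col_sums = counts.sum(axis=1, keepdims=True)
    if np.allclose(col_sums, 1.0, atol=1e-4):
        # already a probability matrix; guard zeros with a tiny floor
        probs = np.clip(counts, 1e-9, None)
        return probs / probs.sum(axis=1, keepdims=True)
    if (col_sums <= 0).any():
        raise ValueError("PWM column with zero total count")
    probs = (counts + pseudocount) / (col_sums + 4 * pseudocount)
    return probs


def load_pwms(
    path,
    *,
    pseudocount: float = 0.8,
    background: np.ndarray | None = None,
    calibrate: bool = True,
    n_random: int = 100_000,
    tail: float = 0.001,
    seed: int = 0,
) -> list[Pwm]:
    """Read a JASPAR-format PWM library and calibrate score thresholds.

    Count matrices are converted to probabilities with a +``pseudocount``
    per cell.  The default threshold of each motif is the score of the top
    ``tail`` fraction (0.1%) of random k-mers drawn from the background,
    computed at load time.
    """
    background = np.full(4, 0.25) if background is None else np.asarray(background, float)
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
    rng = np.random.default_rng(seed)
    pwms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T  # (L, 4)
        probs = _counts_to_probabilities(counts, pseudocount)
        pwm = Pwm(
            motif_id=m.matrix_id or m.name,
            tf_name=m.name,
            matrix=probs,
            background=background,
        )
        if calibrate:
            pwm.threshold = calibrate_threshold(pwm, n_random=n_random, tail=tail, rng=rng)
        pwms.append(pwm)
    return pwms


def write_pwms(pwms: list[Pwm], path, scale: float = 1.0) -> None:
    """Write PWMs in JASPAR 2016 plain-text format.

    With the default scale the written matrices are probabilities, which
    :func:`load_pwms` detects (column sums of one) and re-normalizes without
    applying the count pseudocount, so write/read round-trips are faithful.
    """
    buf = io.StringIO()
    for pwm in pwms:
        buf.write(f">{pwm.motif_id}\t{pwm.tf_name}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v * scale:.12g}" for v in pwm.matrix[:, i])
            buf.write(f"{base}  [ {vals} ]\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def calibrate_all(
    pwms: list[Pwm],
    *,
    seed: int = 0,
    n_random: int = 100_000,
    tail: float = 0.001,
) -> list[Pwm]:
    """Copies of ``pwms`` with thresholds calibrated in listed order, exactly
    as :func:`load_pwms` would calibrate them at load time."""
    rng = np.random.default_rng(seed)
    return [
        replace(p, threshold=calibrate_threshold(p, n_random=n_random, tail=tail, rng=rng))
        for p in pwms
    ]


def calibrate_threshold(
    pwm: Pwm,
    *,
    n_random: int = 100_000,
    tail: float = 0.001,
    rng: np.random.Generator | None = None,
) -> float:
    """Score threshold at the top ``tail`` quantile of random background k-mers."""
    rng = np.random.default_rng(0) if rng is None else rng
    idx = rng.choice(4, size=(n_random, pwm.length), p=pwm.background / pwm.background.sum())
    scores = score_kmers(idx, pwm)
    return float(np.quantile(scores, 1.0 - tail))


def score_distribution(pwm: Pwm, step: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the log-odds score of a random background k-mer.

    Computed by convolving the per-position score distributions on a
    discretized grid of width ``step`` (scores are rounded down to the grid,
    so returned quantiles are conservative by at most ``L * step``).
    Returns (grid values, probabilities).
    """
    lo = pwm.log_odds
    bg = pwm.background / pwm.background.sum()
    offset = np.floor(lo.min(axis=1) / step).astype(int)
    width = int(np.ceil(lo.max() / step) - np.floor(lo.min() / step)) + 1
    total_lo = int(offset.sum())
    n_bins = width * pwm.length + 1
    probs = np.zeros(n_bins)
    probs[0] = 1.0
    pos_bins = np.floor(lo / step).astype(int) - offset[:, None]
    for i in range(pwm.length):
        nxt = np.zeros(n_bins)
        for b in range(4):
            k = pos_bins[i, b]
            nxt[k:] += bg[b] * probs[: n_bins - k] if k > 0 else bg[b] * probs
        probs = nxt
    grid = (np.arange(n_bins) + total_lo) * step
    keep = probs > 0
    return grid[keep], probs[keep]


def exact_score_quantile(pwm: Pwm, tail: float) -> float:
    """Smallest score s with P(random k-mer score >= s) <= tail, computed
    from the exact discretized score distribution."""
    grid, probs = score_distribution(pwm)
    upper = np.cumsum(probs[::-1])[::-1]
    idx = np.searchsorted(-upper, -tail, side="left")
    idx = min(idx, len(grid) - 1)
    return float(grid[idx])


def score_kmers(kmer_idx: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Log-odds scores of encoded k-mers of exactly the motif length."""
    lo = pwm.log_odds
    return lo[np.arange(pwm.length)[None, :], kmer_idx].sum(axis=1)


def _window_scores(seq_idx: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Forward-strand scores for every length-L window of an encoded sequence."""
    L = pwm.length
    n = seq_idx.size - L + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than motif length {L}")
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, L)
    return score_kmers(windows, pwm)


def best_site_score(sequence: str | np.ndarray, pwm: Pwm) -> float:
    """Best log-odds over all offsets on both strands."""
    seq_idx = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    fwd = _window_scores(seq_idx, pwm)
    rc = _COMPLEMENT_IDX[seq_idx[::-1]]
    rev = _window_scores(rc, pwm)
    return float(max(fwd.max(), rev.max()))


def classify_allele_effect(
    snp,
    genome: dict[str, str],
    pwms: list[Pwm],
    roles: dict[str, str] | pd.DataFrame,
    *,
    verbose: bool = False,
) -> list[AlleleEffect]:
    """Classify a risk allele's motif consequences (creates/disrupts).

    For each motif the window spans L-1 bp either side of the SNP; the best
    site score is computed with the reference and with the risk allele
    substituted.  ``creates``: risk site reaches the threshold while the
    reference does not; ``disrupts``: the reverse.  Matches with class
    ``none`` are suppressed unless ``verbose``.

    ``snp`` needs attributes/keys rsid, chrom, pos (1-based), ref, risk.
    """
    if isinstance(roles, pd.DataFrame):
        roles = dict(zip(roles["tf_name"], roles["role"]))
    get = (lambda k: getattr(snp, k)) if hasattr(snp, "rsid") else (lambda k: snp[k])
    chrom, pos = get("chrom"), int(get("pos"))
    ref, alt = get("ref").upper(), get("risk").upper()
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValueError(f"SNP position {pos} outside {chrom}")
    genome_base = seq[pos - 1].upper()
    if genome_base != ref:
        raise ValueError(
            f"reference allele {ref} does not match genome base {genome_base} "
            f"at {chrom}:{pos}"
        )
    effects = []
    for pwm in pwms:
        L = pwm.length
        lo = max(0, pos - 1 - (L - 1))
        hi = min(len(seq), pos + (L - 1))
        window = seq[lo:hi]
        snp_off = pos - 1 - lo
        alt_window = window[:snp_off] + alt + window[snp_off + 1 :]
        ref_best = best_site_score(window, pwm)
        alt_best = best_site_score(alt_window, pwm)
        if alt_best >= pwm.threshold > ref_best:
            effect_class = "creates"
        elif ref_best >= pwm.threshold > alt_best:
            effect_class = "disrupts"
        else:
            effect_class = "none"
        role = roles.get(pwm.tf_name, "unknown")
        if (effect_class == "creates" and role == "repressor") or (
            effect_class == "disrupts" and role == "activator"
        ):
            direction = "reduced"
        elif (effect_class == "creates" and role == "activator") or (
            effect_class == "disrupts" and role == "repressor"
        ):
            direction = "increased"
        else:
            direction = "none"
        if effect_class != "none" or verbose:
            effects.append(
                AlleleEffect(
                    rsid=get("rsid"),
                    motif_id=pwm.motif_id,
                    tf_name=pwm.tf_name,
                    tf_role=role,
                    ref_best=ref_best,
                    alt_best=alt_best,
                    effect_class=effect_class,
                    predicted_direction=direction,
                )
            )
    return effects


def motif_hits(
    peaks: pd.DataFrame,
    genome: dict[str, str],
    pwms: list[Pwm],
    *,
    per_peak_tail: float = 0.001,
) -> pd.DataFrame:
    """Boolean peak x motif hit matrix.

    A peak is a hit when its best site score reaches a per-peak-corrected
    threshold: the exact score quantile at ``per_peak_tail`` divided by the
    number of windows scanned (both strands), so the expected false-hit rate
    per peak stays near ``per_peak_tail`` regardless of peak width.  (The
    per-k-mer threshold stored on the PWM is appropriate for single-window
    decisions such as allele-effect calls, but saturates over the ~1000
    windows of a full peak.)

    ``peaks`` needs columns chrom/start/end (0-based half-open) and an index
    of peak ids.
    """
    encoded = {c: encode(s) for c, s in genome.items()}
    widths = (peaks["end"] - peaks["start"]).to_numpy()
    out = np.zeros((len(peaks), len(pwms)), dtype=bool)
    thr: dict[tuple[str, int], float] = {}
    for j, pwm in enumerate(pwms):
        for w in np.unique(widths):
            n_windows = max(1, 2 * (int(w) - pwm.length + 1))
            thr[(pwm.motif_id, int(w))] = exact_score_quantile(
                pwm, per_peak_tail / n_windows)
    for i, (_, row) in enumerate(peaks.iterrows()):
        chrom_idx = encoded[row["chrom"]]
        if row["start"] < 0 or row["end"] > chrom_idx.size:
            raise ValueError(f"peak outside genome bounds: {row['chrom']}:{row['start']}-{row['end']}")
        seq_idx = chrom_idx[int(row["start"]) : int(row["end"])]
        w = int(row["end"] - row["start"])
        for j, pwm in enumerate(pwms):
            out[i, j] = best_site_score(seq_idx, pwm) >= thr[(pwm.motif_id, w)]
    return pd.DataFrame(out, index=peaks.index, columns=[p.motif_id for p in pwms])


def motif_enrichment(marker_ids, all_ids, hits: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric motif enrichment of marker peaks within all peaks.

    For each motif: N = all peaks, m = peaks with the motif, K = marker
    peaks, k = marker peaks with the motif; p is the upper tail
    P(X >= k), BH-adjusted across motifs.
    """
    marker_ids = pd.Index(marker_ids)
    all_ids = pd.Index(all_ids)
    if len(marker_ids) == 0:
        raise ValueError("empty marker set")
    if not marker_ids.isin(all_ids).all():
        raise ValueError("marker peaks must be a subset of all peaks")
    sub = hits.loc[all_ids]
    N = len(all_ids)
    K = len(marker_ids)
    rows = []
    for motif in hits.columns:
        m = int(sub[motif].sum())
        k = int(hits.loc[marker_ids, motif].sum())
        p = float(stats.hypergeom.sf(k - 1, N, m, K))
        rows.append({"motif": motif, "k": k, "K": K, "m": m, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["neglog10_padj"] = -np.log10(np.clip(df["p_adj"], 1e-300, 1.0))
    return df.sort_values("p_adj", kind="stable").reset_index(drop=True)


def _gc_content(peaks: pd.DataFrame, genome: dict[str, str]) -> np.ndarray:
    gc = np.empty(len(peaks))
    for i, (_, row) in enumerate(peaks.iterrows()):
        seq = genome[row["chrom"]][int(row["start"]) : int(row["end"])]
        gc[i] = (seq.count("G") + seq.count("C")) / max(len(seq), 1)
    return gc


def motif_deviation_scores(
    peak_matrix: np.ndarray,
    hits: pd.DataFrame,
    gc: np.ndarray,
    *,
    n_background: int = 50,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """chromVAR-style per-cell motif deviations and background-normalized z.

    Raw deviation for motif m, cell c:
    (observed reads in m's peaks - expected) / expected, centred across
    cells, where expected = cell total x global fraction of reads in m's
    peaks.  The z score normalizes against ``n_background`` random peak sets
    matched to m's peaks within GC-content x mean-accessibility decile strata.

    Returns {"raw": DataFrame cells x motifs, "z": DataFrame}.
    Motifs with zero hit peaks are excluded.
    """
    X = np.asarray(peak_matrix, dtype=float)
    n_cells, n_peaks = X.shape
    if hits.shape[0] != n_peaks:
        raise ValueError("hits rows must match peak_matrix columns")
    gc = np.asarray(gc, float)
    totals = X.sum(axis=1)
    grand_total = totals.sum()
    mean_acc = X.mean(axis=0)

    # decile strata on GC and mean accessibility
    def _decile(v):
        ranks = stats.rankdata(v, method="average") / len(v)
        return np.minimum((ranks * 10).astype(int), 9)

    strata = _decile(gc) * 10 + _decile(mean_acc)
    strata_members = {s: np.flatnonzero(strata == s) for s in np.unique(strata)}
    rng = np.random.default_rng(seed)

    def _raw_dev(mask: np.ndarray) -> np.ndarray:
        frac = X[:, mask].sum(axis=None) / grand_total
        expected = totals * frac
        obs = X[:, mask].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.where(expected > 0, (obs - expected) / expected, 0.0)
        return dev - dev.mean()

    kept, raw_cols, z_cols = [], [], []
    for motif in hits.columns:
        mask = hits[motif].to_numpy()
        if mask.sum() == 0:
            continue
        raw = _raw_dev(mask)
        # matched background sets
        bg_devs = np.empty((n_background, n_cells))
        hit_idx = np.flatnonzero(mask)
        for b in range(n_background):
            sampled = []
            for s, count in zip(*np.unique(strata[hit_idx], return_counts=True)):
                pool = strata_members[s]
                take = min(count, pool.size)
                sampled.append(rng.choice(pool, size=take, replace=False))
            bg_mask = np.zeros(n_peaks, dtype=bool)
            bg_mask[np.concatenate(sampled)] = True
            bg_devs[b] = _raw_dev(bg_mask)
        mean_bg = bg_devs.mean(axis=0)
        sd_bg = bg_devs.std(axis=0, ddof=1)
        sd_bg = np.where(sd_bg > 0, sd_bg, 1.0)
        kept.append(motif)
        raw_cols.append(raw)
        z_cols.append((raw - mean_bg) / sd_bg)
    raw_df = pd.DataFrame(np.column_stack(raw_cols) if raw_cols else np.empty((n_cells, 0)), columns=kept)
    z_df = pd.DataFrame(np.column_stack(z_cols) if z_cols else np.empty((n_cells, 0)), columns=kept)
    return {"raw": raw_df, "z": z_df}
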