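"""Seeded synthetic study generator with recorded planted truth.

Generates a miniature multi-sample single-nucleus study that mirrors the data
shapes the pipeline consumes: a small multi-chromosome genome, a TSS
annotation, barcoded ATAC fragment records for several cell clusters grouped
into developmental / Barrett's / adult compartments, an RNA count matrix with
mitochondrial genes and planted highly variable genes, a GWAS summary table on
an earlier genome build with a block-offset liftover chain, a genotype matrix
for LD, and a JASPAR-style PWM library whose motifs are engineered so that
planted risk alleles create or destroy binding sites.

Everything recoverable downstream (differential peaks, in-peak SNPs,
engineered allele effects, doublets, HVGs, low-quality cells) is recorded in
:class:`PlantedTruth` so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import motifs as motmod
from .motifs import BASES, Pwm, best_site_score

GROUPS = ("developmental", "barretts", "adult")
PEAK_WIDTH = 501


def _chain_tail(chrom_length: int) -> int:
    """Length of the chromosome tail left uncovered by the liftover chain."""
    return min(100_000, chrom_length // 10)

__all__ = ["SynthConfig", "PlantedTruth", "Reference", "SyntheticStudy",
           "generate_reference", "plant_truth", "simulate_fragments",
           "simulate_rna_counts", "simulate_gwas_table", "generate_study"]


@dataclass
class SynthConfig:
    """All knobs of the synthetic study; identical config + seed gives
    byte-identical outputs."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_clusters: int = 6
    cells_per_cluster: int = 330
    group_of_cluster: dict[int, str] = field(default_factory=lambda: {
        0: "developmental", 1: "developmental",
        2: "barretts", 3: "barretts",
        4: "adult", 5: "adult",
    })
    peaks_per_cluster: int = 40
    shared_peak_fraction: float = 0.4
    differential_fraction: float = 0.25
    background_rate: float = 2.0e-4      # fragments / bp / cell
    peak_enrichment_fold: float = 25.0
    doublet_fraction: float = 0.04
    n_genes: int = 300
    mito_gene_fraction: float = 0.05
    hvg_fraction: float = 0.1
    hvg_bio_variance: float = 2.0
    n_snps: int = 40
    snps_in_selected_peak_fraction: float = 0.5
    ld_pair_fraction: float = 0.25
    motif_plant_fraction: float = 0.6
    # free parameters of the fragment / RNA models (no values are dictated by
    # the data the study emulates; see docs/methods.md for rationale)
    promoter_insertions_mean: float = 100.0
    fragment_len_range: tuple[int, int] = (80, 300)
    depth_sigma: float = 0.15
    low_quality_fraction: float = 0.05
    significant_fraction: float = 0.4
    rna_mean_depth: float = 3000.0
    rna_depth_sigma: float = 0.3
    rna_outlier_fraction: float = 0.02
    rna_outlier_mito: float = 0.4
    rare_gene_fraction: float = 0.1
    baseline_mito_fraction: float = 0.02
    n_individuals: int = 400

    def validate(self) -> None:
        fracs = dict(
            shared_peak_fraction=self.shared_peak_fraction,
            differential_fraction=self.differential_fraction,
            doublet_fraction=self.doublet_fraction,
            mito_gene_fraction=self.mito_gene_fraction,
            hvg_fraction=self.hvg_fraction,
            snps_in_selected_peak_fraction=self.snps_in_selected_peak_fraction,
            ld_pair_fraction=self.ld_pair_fraction,
            motif_plant_fraction=self.motif_plant_fraction,
            low_quality_fraction=self.low_quality_fraction,
            significant_fraction=self.significant_fraction,
        )
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        counts = dict(
            n_chromosomes=self.n_chromosomes, chrom_length=self.chrom_length,
            n_clusters=self.n_clusters, cells_per_cluster=self.cells_per_cluster,
            peaks_per_cluster=self.peaks_per_cluster, n_genes=self.n_genes,
            n_snps=self.n_snps, n_individuals=self.n_individuals,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.peak_enrichment_fold < 1:
            raise ValueError("peak_enrichment_fold must be >= 1")
        if set(self.group_of_cluster) != set(range(self.n_clusters)):
            raise ValueError("group_of_cluster must cover clusters 0..n_clusters-1")
        if not set(self.group_of_cluster.values()) <= set(GROUPS):
            raise ValueError(f"groups must be in {GROUPS}")


# default motif panel: six allele-effect TFs with literature roles plus one
# marker motif per cluster; the anchor position (index 4) carries nearly all
# of the information so a single-base change can cross the score threshold.
_ALLELE_TFS = [("YY1", "repressor"), ("ZNF18", "repressor"), ("ZNF708", "repressor"),
               ("KLF5", "activator"), ("NFIC", "activator"), ("TEAD", "activator")]
_CLUSTER_TFS = ["GATA6", "HNF4A", "TP63", "GRHL1", "FOXA3", "RFX"]
_ANCHOR = 4
_MOTIF_LEN = 10


def _make_pwm(motif_id: str, tf_name: str, consensus_idx: np.ndarray) -> Pwm:
    mat = np.full((_MOTIF_LEN, 4), 0.15)
    mat[np.arange(_MOTIF_LEN), consensus_idx] = 0.55
    mat[_ANCHOR] = 0.001
    mat[_ANCHOR, consensus_idx[_ANCHOR]] = 0.997
    return Pwm(motif_id=motif_id, tf_name=tf_name, matrix=mat / mat.sum(axis=1, keepdims=True))


@dataclass
class Reference:
    """Genome sequences, TSS annotation, PWM library and TF role table."""

    genome: dict[str, str]
    tss: pd.DataFrame              # chrom, tss (0-based), gene, strand
    pwms: list[Pwm]
    roles: pd.DataFrame            # tf_name, role


@dataclass
class PlantedTruth:
    peaks: pd.DataFrame            # peak_id, chrom, start, end, kind, clusters, fold, differential, planted_motif
    snps: pd.DataFrame             # rsid, chrom, pos (b38 1-based), pos_b37, ref, risk, p, significant,
                                   # in_peak, target_peak, engineered_class, engineered_motif, ld_partner_of
    doublet_barcodes: list[str]
    hvg_genes: list[str]
    low_quality_barcodes: list[str] = field(default_factory=list)
    rna_outlier_barcodes: list[str] = field(default_factory=list)

    def expected_loci(self) -> list[frozenset[str]]:
        """Loci the cascade should report: significant SNPs in differential
        peaks, LD partners collapsed onto their primary SNP."""
        snps = self.snps
        eligible = snps[snps["significant"] & snps["in_peak"]]
        loci: dict[str, set[str]] = {}
        for _, row in eligible.iterrows():
            primary = row["ld_partner_of"] or row["rsid"]
            loci.setdefault(primary, set()).add(row["rsid"])
        return [frozenset(v) for v in loci.values()]


@dataclass
class SyntheticStudy:
    config: SynthConfig
    reference: Reference
    truth: PlantedTruth
    fragments: pd.DataFrame        # chrom, start, end, barcode, count
    cells: pd.DataFrame            # barcode, cluster, group, is_doublet, is_low_quality
    rna: pd.DataFrame              # cells x genes count matrix
    gwas: pd.DataFrame             # rsid, chrom, pos (1-based b37), ref, risk_allele, P, build
    chain: pd.DataFrame            # src_chrom, src_start, src_end, dst_chrom, offset
    genotypes: pd.DataFrame        # individuals x rsid dosage matrix


def _rng(config: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def generate_reference(config: SynthConfig) -> Reference:
    """Random genome, evenly scattered TSSs, the default PWM panel and roles."""
    config.validate()
    rng = _rng(config, 0)
    genome = {}
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for c in range(config.n_chromosomes):
        idx = rng.integers(0, 4, size=config.chrom_length)
        genome[f"chr{c + 1}"] = base_bytes[idx].tobytes().decode("ascii")

    # TSSs: uniform positions with minimum spacing, away from chromosome ends
    chroms = sorted(genome)
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[: config.n_genes % len(chroms)] += 1
    rows = []
    gene_idx = 0
    L = config.chrom_length
    lo = min(5_000, L // 20)
    hi_margin = _chain_tail(L) + min(25_000, L // 10)
    for chrom, n in zip(chroms, per_chrom):
        hi = config.chrom_length - hi_margin
        if hi <= lo:
            raise ValueError("chromosome too short for TSS placement")
        pos = np.sort(rng.choice(np.arange(lo, hi, 6_000), size=min(int(n), (hi - lo) // 6_000), replace=False))
        for p in pos:
            rows.append({"chrom": chrom, "tss": int(p), "gene": f"GENE{gene_idx:04d}", "strand": "+"})
            gene_idx += 1
    tss = pd.DataFrame(rows)

    pwms = []
    for i, (tf, _) in enumerate(_ALLELE_TFS):
        cons = rng.integers(0, 4, size=_MOTIF_LEN)
        pwms.append(_make_pwm(f"M{i:03d}", tf, cons))
    for j, tf in enumerate(_CLUSTER_TFS[: config.n_clusters]):
        cons = rng.integers(0, 4, size=_MOTIF_LEN)
        pwms.append(_make_pwm(f"M{len(_ALLELE_TFS) + j:03d}", tf, cons))
    roles = pd.DataFrame(
        [{"tf_name": tf, "role": role} for tf, role in _ALLELE_TFS]
        + [{"tf_name": tf, "role": "activator"} for tf in _CLUSTER_TFS[: config.n_clusters]]
    )
    return Reference(genome=genome, tss=tss, pwms=pwms, roles=roles)


def _calibrated(reference: Reference) -> list[Pwm]:
    """PWMs with thresholds exactly as the pipeline will calibrate them."""
    return motmod.calibrate_all(reference.pwms)


def _splice(genome: dict[str, str], chrom: str, start: int, piece: str) -> None:
    s = genome[chrom]
    genome[chrom] = s[:start] + piece + s[start + len(piece):]


def plant_truth(config: SynthConfig, reference: Reference) -> PlantedTruth:
    """Place peaks, SNPs, engineered alleles, doublets and HVGs; edits the
    reference genome in place where motif sites are planted."""
    config.validate()
    rng = _rng(config, 1)
    chroms = sorted(reference.genome)
    L = config.chrom_length

    # candidate slots for peak placement: a coarse grid excluding TSS
    # neighbourhoods, guaranteeing pairwise non-overlap of 501 bp intervals
    slot_step = 4_000
    peak_lo = min(10_000, L // 20)
    peak_hi = L - _chain_tail(L) - min(30_000, L // 10)
    tss_by_chrom = {c: g["tss"].to_numpy() for c, g in reference.tss.groupby("chrom")}
    slots = []
    for chrom in chroms:
        grid = np.arange(peak_lo, peak_hi, slot_step)
        t = tss_by_chrom.get(chrom, np.array([]))
        if t.size:
            near_tss = np.min(np.abs(grid[:, None] - t[None, :]), axis=1) < 3_000
            grid = grid[~near_tss]
        slots.extend((chrom, int(p)) for p in grid)
    rng.shuffle(slots)

    n_shared = int(round(config.peaks_per_cluster * config.shared_peak_fraction))
    n_diff = int(round(config.peaks_per_cluster * config.differential_fraction))
    n_specific = config.peaks_per_cluster - n_shared - n_diff
    if n_specific < 0:
        raise ValueError("shared_peak_fraction + differential_fraction exceed 1")
    n_total = n_shared + n_diff + n_specific * config.n_clusters
    if n_total > len(slots):
        raise ValueError(f"cannot fit {n_total} non-overlapping peaks; enlarge the genome")

    dev_barr = [c for c in range(config.n_clusters)
                if config.group_of_cluster[c] in ("developmental", "barretts")]
    pwms_cal = _calibrated(reference)
    cluster_pwms = {j: pwms_cal[len(_ALLELE_TFS) + j]
                    for j in range(min(config.n_clusters, len(_CLUSTER_TFS)))}

    peak_rows = []
    slot_iter = iter(slots)

    def _add_peak(kind: str, clusters: list[int], planted_motif: str | None):
        chrom, start = next(slot_iter)
        pid = f"truth_{len(peak_rows):04d}"
        if planted_motif is not None:
            pwm = next(p for p in pwms_cal if p.motif_id == planted_motif)
            # plant the consensus off-centre so engineered SNP sites can sit
            # nearer the middle of the interval
            _splice(reference.genome, chrom, start + 60, pwm.consensus)
        peak_rows.append({
            "peak_id": pid, "chrom": chrom, "start": start, "end": start + PEAK_WIDTH,
            "kind": kind, "clusters": tuple(clusters),
            "fold": config.peak_enrichment_fold,
            "differential": kind == "differential",
            "planted_motif": planted_motif,
        })
        return peak_rows[-1]

    for _ in range(n_shared):
        _add_peak("shared", list(range(config.n_clusters)), None)
    diff_peaks = []
    for i in range(n_diff):
        motif = cluster_pwms[dev_barr[i % len(dev_barr)]].motif_id if dev_barr else None
        diff_peaks.append(_add_peak("differential", dev_barr, motif))
    for cl in range(config.n_clusters):
        for i in range(n_specific):
            motif = cluster_pwms[cl].motif_id if (cl in cluster_pwms and i < int(0.8 * n_specific)) else None
            _add_peak("cluster", [cl], motif)
    peaks = pd.DataFrame(peak_rows)

    # ---- SNPs -------------------------------------------------------------
    n_sig = int(round(config.n_snps * config.significant_fraction))
    n_in_peak = int(round(n_sig * config.snps_in_selected_peak_fraction))
    if n_in_peak > len(diff_peaks):
        raise ValueError("more in-peak SNPs requested than differential peaks available")
    repressors = [p for p in pwms_cal if dict(_ALLELE_TFS).get(p.tf_name) == "repressor"]
    activators = [p for p in pwms_cal if dict(_ALLELE_TFS).get(p.tf_name) == "activator"]
    roles = dict(zip(reference.roles["tf_name"], reference.roles["role"]))

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for pr in peak_rows:
        if pr["planted_motif"] is not None:
            occupied[pr["chrom"]].append((pr["start"] + 60, pr["start"] + 60 + _MOTIF_LEN))

    snp_rows: list[dict] = []
    n_engineered = int(round(n_in_peak * config.motif_plant_fraction))

    def _free_position(chrom: str, lo: int, hi: int, width: int) -> int:
        for _ in range(200):
            pos = int(rng.integers(lo, hi - width))
            if all(pos + width <= s or pos >= e for s, e in occupied[chrom]):
                return pos
        raise RuntimeError("could not find a free position for motif planting")

    def _engineer(peak: dict, effect: str, pwm: Pwm, rsid: str) -> dict:
        """Write a motif site into the genome so ref/alt cross the threshold."""
        chrom = peak["chrom"]
        cons_idx = np.array([BASES.index(b) for b in pwm.consensus])
        for _ in range(60):
            site_start = _free_position(chrom, peak["start"] + 120, peak["start"] + PEAK_WIDTH - 120, _MOTIF_LEN)
            anchor_pos = site_start + _ANCHOR          # 0-based genome position of SNP
            cons_base = pwm.consensus[_ANCHOR]
            worst = BASES[int(np.argmin(pwm.matrix[_ANCHOR]))]
            if worst == cons_base:
                worst = next(b for b in BASES if b != cons_base)
            if effect == "creates":
                site = pwm.consensus[:_ANCHOR] + worst + pwm.consensus[_ANCHOR + 1:]
                ref, alt = worst, cons_base
            else:
                site = pwm.consensus
                ref, alt = cons_base, worst
            _splice(reference.genome, chrom, site_start, site)
            # brute-force verification on the final genome
            wlo = anchor_pos - (_MOTIF_LEN - 1)
            whi = anchor_pos + _MOTIF_LEN
            window = reference.genome[chrom][wlo:whi]
            off = anchor_pos - wlo
            alt_window = window[:off] + alt + window[off + 1:]
            ref_best = best_site_score(window, pwm)
            alt_best = best_site_score(alt_window, pwm)
            ok = (alt_best >= pwm.threshold > ref_best) if effect == "creates" else (
                ref_best >= pwm.threshold > alt_best)
            if ok:
                occupied[chrom].append((site_start, site_start + _MOTIF_LEN))
                return {"rsid": rsid, "chrom": chrom, "pos": anchor_pos + 1,
                        "ref": ref, "risk": alt, "significant": True, "in_peak": True,
                        "target_peak": peak["peak_id"], "engineered_class": effect,
                        "engineered_motif": pwm.motif_id, "ld_partner_of": None}
            # scrub: re-randomise the site and retry elsewhere
            scrub = "".join(BASES[i] for i in rng.integers(0, 4, size=_MOTIF_LEN).tolist())
            _splice(reference.genome, chrom, site_start, scrub)
        raise RuntimeError(f"failed to engineer {effect} site for {pwm.tf_name}")

    def _plain_snp(rsid: str, chrom: str, pos0: int, significant: bool,
                   in_peak: bool, target: str | None) -> dict:
        ref = reference.genome[chrom][pos0]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        return {"rsid": rsid, "chrom": chrom, "pos": pos0 + 1, "ref": ref, "risk": alt,
                "significant": significant, "in_peak": in_peak, "target_peak": target,
                "engineered_class": None, "engineered_motif": None, "ld_partner_of": None}

    rsid_counter = iter(range(10_000, 99_999))
    chosen_diff = list(rng.choice(len(diff_peaks), size=n_in_peak, replace=False))
    for i, pk_i in enumerate(chosen_diff):
        peak = diff_peaks[int(pk_i)]
        rsid = f"rs{next(rsid_counter)}"
        if i < n_engineered:
            effect = "creates" if i % 2 == 0 else "disrupts"
            pool = repressors if effect == "creates" else activators
            pwm = pool[i % len(pool)]
            snp_rows.append(_engineer(peak, effect, pwm, rsid))
        else:
            pos0 = _free_position(peak["chrom"], peak["start"] + 120,
                                  peak["start"] + PEAK_WIDTH - 120, 1)
            snp_rows.append(_plain_snp(rsid, peak["chrom"], pos0, True, True, peak["peak_id"]))

    # LD partners: extra significant SNPs inside the same differential peak
    n_ld = int(round(len(chosen_diff) * config.ld_pair_fraction))
    for i in range(n_ld):
        primary = snp_rows[i]
        peak = next(p for p in diff_peaks if p["peak_id"] == primary["target_peak"])
        pos0 = _free_position(peak["chrom"], peak["start"] + 120,
                              peak["start"] + PEAK_WIDTH - 120, 1)
        row = _plain_snp(f"rs{next(rsid_counter)}", peak["chrom"], pos0, True, True, peak["peak_id"])
        row["ld_partner_of"] = primary["rsid"]
        snp_rows.append(row)

    # out-of-peak significant SNPs: half in shared peaks (rejected by DA),
    # half in open background
    shared_peaks = [p for p in peak_rows if p["kind"] == "shared"]
    n_out = n_sig - n_in_peak
    for i in range(n_out):
        rsid = f"rs{next(rsid_counter)}"
        if i % 2 == 0 and shared_peaks:
            pk = shared_peaks[i % len(shared_peaks)]
            pos0 = _free_position(pk["chrom"], pk["start"] + 120, pk["start"] + PEAK_WIDTH - 120, 1)
            snp_rows.append(_plain_snp(rsid, pk["chrom"], pos0, True, False, pk["peak_id"]))
        else:
            chrom = chroms[i % len(chroms)]
            pos0 = _free_position(chrom, peak_lo, peak_hi, 1)
            snp_rows.append(_plain_snp(rsid, chrom, pos0, True, False, None))

    # decoy SNPs above the P threshold; a third of them inside differential
    # peaks to exercise the significance filter
    n_decoy = config.n_snps - n_sig
    for i in range(n_decoy):
        rsid = f"rs{next(rsid_counter)}"
        if i % 3 == 0 and diff_peaks:
            pk = diff_peaks[i % len(diff_peaks)]
            pos0 = _free_position(pk["chrom"], pk["start"] + 120, pk["start"] + PEAK_WIDTH - 120, 1)
            snp_rows.append(_plain_snp(rsid, pk["chrom"], pos0, False, True, pk["peak_id"]))
        else:
            chrom = chroms[i % len(chroms)]
            pos0 = _free_position(chrom, peak_lo, peak_hi, 1)
            snp_rows.append(_plain_snp(rsid, chrom, pos0, False, False, None))

    snps = pd.DataFrame(snp_rows)

    # ---- cells: doublets, low quality, HVGs, RNA outliers -----------------
    barcodes = [f"C{cl}_{i:04d}" for cl in range(config.n_clusters)
                for i in range(config.cells_per_cluster)]
    n_cells = len(barcodes)
    n_doublets = int(round(n_cells * config.doublet_fraction))
    doublet_barcodes = [f"DBL_{i:04d}" for i in range(n_doublets)]
    n_lowq = int(round(n_cells * config.low_quality_fraction))
    lowq = list(rng.choice(barcodes, size=n_lowq, replace=False))
    n_out_rna = int(round(n_cells * config.rna_outlier_fraction))
    remaining = [b for b in barcodes if b not in set(lowq)]
    rna_outliers = list(rng.choice(remaining, size=n_out_rna, replace=False))
    n_hvg = int(round(config.n_genes * config.hvg_fraction))
    n_mito = int(round(config.n_genes * config.mito_gene_fraction))
    non_mito_genes = [f"GENE{i:04d}" for i in range(config.n_genes - n_mito)]
    hvg_genes = list(rng.choice(non_mito_genes, size=n_hvg, replace=False))

    truth = PlantedTruth(
        peaks=peaks, snps=snps, doublet_barcodes=doublet_barcodes,
        hvg_genes=sorted(hvg_genes), low_quality_barcodes=sorted(lowq),
        rna_outlier_barcodes=sorted(rna_outliers),
    )
    _check_truth(config, reference, truth)
    return truth


def _check_truth(config: SynthConfig, reference: Reference, truth: PlantedTruth) -> None:
    peaks = truth.peaks
    adult = {c for c, g in config.group_of_cluster.items() if g == "adult"}
    for _, p in peaks[peaks["differential"]].iterrows():
        if set(p["clusters"]) & adult:
            raise AssertionError("differential peak accessible in an adult cluster")
    by_id = peaks.set_index("peak_id")
    for _, s in truth.snps.iterrows():
        if s["in_peak"]:
            p = by_id.loc[s["target_peak"]]
            if not (p["start"] < s["pos"] - 1 < p["end"] - 1):
                raise AssertionError(f"SNP {s['rsid']} not strictly inside its target peak")
        base = reference.genome[s["chrom"]][s["pos"] - 1]
        if base != s["ref"]:
            raise AssertionError(f"SNP {s['rsid']} ref allele mismatch with genome")


def _cell_table(config: SynthConfig, truth: PlantedTruth,
                rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, tuple[str, str]]]:
    rows = []
    for cl in range(config.n_clusters):
        for i in range(config.cells_per_cluster):
            bc = f"C{cl}_{i:04d}"
            rows.append({"barcode": bc, "cluster": cl,
                         "group": config.group_of_cluster[cl],
                         "is_doublet": False,
                         "is_low_quality": bc in set(truth.low_quality_barcodes)})
    singlets = [r["barcode"] for r in rows]
    pair_of: dict[str, tuple[str, str]] = {}
    for bc in truth.doublet_barcodes:
        a, b = rng.choice(singlets, size=2, replace=False)
        pair_of[bc] = (str(a), str(b))
        cl = int(a.split("_")[0][1:])
        rows.append({"barcode": bc, "cluster": cl,
                     "group": config.group_of_cluster[cl],
                     "is_doublet": True, "is_low_quality": False})
    return pd.DataFrame(rows), pair_of


def simulate_fragments(truth: PlantedTruth, config: SynthConfig,
                       reference: Reference) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcoded fragment records (0-based half-open, coordinate-sorted).

    Per cell: uniform background at ``background_rate`` fragments/bp, promoter
    fragments concentrated at TSSs, and in accessible peaks an extra
    ``(fold - 1) x background_rate`` per bp.  Doublet barcodes receive the
    union of two freshly drawn cells.  Low-quality cells get reduced depth and
    almost no promoter signal.
    """
    config.validate()
    rng = _rng(config, 2)
    cells, pair_of = _cell_table(config, truth, rng)
    chroms = sorted(reference.genome)
    L = config.chrom_length
    genome_len = L * len(chroms)
    lmin, lmax = config.fragment_len_range
    tss_arr = reference.tss[["chrom", "tss"]].to_numpy()
    peaks = truth.peaks
    acc_by_cluster = {
        cl: peaks[[cl in cs for cs in peaks["clusters"]]][["chrom", "start"]].to_numpy()
        for cl in range(config.n_clusters)
    }

    def _draw_cell(cluster: int, depth: float, prom_factor: float):
        out_chrom, out_start = [], []
        # background
        n_bg = rng.poisson(config.background_rate * genome_len * depth)
        ci = rng.integers(0, len(chroms), size=n_bg)
        pos = rng.integers(0, L - lmax, size=n_bg)
        out_chrom.append(ci)
        out_start.append(pos)
        # promoter signal: insertion point ~ N(tss, 25)
        n_prom = rng.poisson(config.promoter_insertions_mean * depth * prom_factor)
        ti = rng.integers(0, len(tss_arr), size=n_prom)
        tpos = tss_arr[ti, 1].astype(int) + rng.normal(0, 25, size=n_prom).astype(int)
        tchrom = np.array([chroms.index(c) for c in tss_arr[ti, 0]], dtype=np.int64)
        out_chrom.append(tchrom)
        out_start.append(np.clip(tpos, 0, L - lmax))
        # in-peak enrichment
        acc = acc_by_cluster[cluster]
        if len(acc):
            lam = config.background_rate * (config.peak_enrichment_fold - 1) * PEAK_WIDTH * depth
            counts = rng.poisson(lam, size=len(acc))
            rep = np.repeat(np.arange(len(acc)), counts)
            if rep.size:
                # fragment CENTRES uniform in the peak keeps the insertion
                # cloud symmetric so called summits land near the interval
                # centre
                centres = acc[rep, 1].astype(int) + rng.integers(0, PEAK_WIDTH, size=rep.size)
                plens = rng.integers(lmin, lmax + 1, size=rep.size)
                starts = np.clip(centres - plens // 2, 0, L - lmax)
                pchrom = np.array([chroms.index(c) for c in acc[rep, 0]], dtype=np.int64)
                out_chrom.append(pchrom)
                out_start.append(starts)
        ci = np.concatenate(out_chrom).astype(np.int64)
        st = np.concatenate(out_start).astype(np.int64)
        lens = rng.integers(lmin, lmax + 1, size=st.size)
        return ci, st, st + lens

    frames = []
    lowq = set(truth.low_quality_barcodes)
    singlet_draws: dict[str, tuple] = {}
    for _, row in cells[~cells["is_doublet"]].iterrows():
        bc = row["barcode"]
        depth = float(np.exp(rng.normal(0, config.depth_sigma)))
        prom = 1.0
        if bc in lowq:
            depth *= 0.25
            prom = 0.1
        singlet_draws[bc] = _draw_cell(int(row["cluster"]), depth, prom)
    for bc, (a, b) in pair_of.items():
        ca, sa, ea = singlet_draws[a]
        cb, sb, eb = singlet_draws[b]
        singlet_draws[bc] = (np.concatenate([ca, cb]),
                             np.concatenate([sa, sb]), np.concatenate([ea, eb]))
    for bc, (ci, st, en) in singlet_draws.items():
        frames.append(pd.DataFrame({
            "chrom": np.array(chroms)[ci], "start": st, "end": en,
            "barcode": bc, "count": 1,
        }))
    fragments = pd.concat(frames, ignore_index=True)
    fragments = fragments.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    assert (fragments["start"] < fragments["end"]).all()
    assert (fragments["end"] <= L).all()
    return fragments, cells


def simulate_rna_counts(truth: PlantedTruth, config: SynthConfig,
                        cells: pd.DataFrame) -> pd.DataFrame:
    """Cells x genes negative-binomial count matrix.

    HVG genes carry extra log-normal rate variance (``hvg_bio_variance`` on
    the natural-log scale); mitochondrial genes make up a configured fraction
    of each cell's counts; planted outlier cells get a 0.4 mitochondrial
    fraction and inflated/deflated library sizes.
    """
    config.validate()
    rng = _rng(config, 3)
    n_mito = int(round(config.n_genes * config.mito_gene_fraction))
    n_reg = config.n_genes - n_mito
    genes = [f"GENE{i:04d}" for i in range(n_reg)] + [f"MT-G{i:02d}" for i in range(n_mito)]
    hvg_mask = np.array([g in set(truth.hvg_genes) for g in genes])
    n_rare = int(round(n_reg * config.rare_gene_fraction))
    # gene relative abundances; the last `n_rare` non-mito, non-HVG genes are
    # planted at means below the downstream 0.01-mean filter
    base = np.exp(rng.normal(0, 1, size=config.n_genes))
    rare_candidates = [i for i in range(n_reg) if not hvg_mask[i]][-n_rare:] if n_rare else []
    base /= base.sum()
    barcodes = cells["barcode"].tolist()
    doublet = cells["is_doublet"].to_numpy()
    outliers = set(truth.rna_outlier_barcodes)

    mat = np.zeros((len(barcodes), config.n_genes), dtype=np.int64)
    sigma2 = config.hvg_bio_variance
    for i, bc in enumerate(barcodes):
        depth = config.rna_mean_depth * np.exp(rng.normal(0, config.rna_depth_sigma))
        if doublet[i]:
            depth *= 2.0
        mito_f = config.baseline_mito_fraction
        if bc in outliers:
            mito_f = config.rna_outlier_mito
            depth *= 20.0 if i % 2 == 0 else 0.1
        rates = base.copy()
        if sigma2 > 0 and hvg_mask.any():
            noise = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=int(hvg_mask.sum())))
            rates[hvg_mask] *= noise
        rates /= rates.sum()
        # mild NB overdispersion for every gene
        rates = rates * rng.gamma(20.0, 1.0 / 20.0, size=config.n_genes)
        nonmito = rng.poisson(depth * (1 - mito_f) * rates / max(rates.sum(), 1e-12))
        mat[i] = nonmito
        if n_mito:
            mito_total = rng.poisson(depth * mito_f)
            mat[i, n_reg:] = rng.multinomial(mito_total, np.full(n_mito, 1.0 / n_mito))
    # force rare genes to near-zero means
    for gi in rare_candidates:
        mat[:, gi] = rng.binomial(1, 0.003, size=len(barcodes))
    return pd.DataFrame(mat, index=barcodes, columns=genes)


def simulate_gwas_table(truth: PlantedTruth, config: SynthConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """GWAS summary table on build GRCh37, the liftover chain, and genotypes.

    The chain covers all but the last 100 kb of each chromosome with one
    block and a per-chromosome offset; planted SNPs all fall inside blocks.
    LD-partner genotype columns are copies of their primary (sample r2 > 0.9
    by construction); all other columns are independent binomial dosages.
    """
    config.validate()
    rng = _rng(config, 4)
    chroms = sorted({c for c in truth.snps["chrom"]})
    tail = _chain_tail(config.chrom_length)
    offsets = {c: int(rng.integers(-5_000, 5_000)) for c in chroms}
    chain = pd.DataFrame([
        {"src_chrom": c, "src_start": 1, "src_end": config.chrom_length - tail,
         "dst_chrom": c, "offset": offsets[c]}
        for c in chroms
    ])
    rows = []
    for _, s in truth.snps.iterrows():
        if s["significant"]:
            p = 10.0 ** rng.uniform(-12, -5.3)
        else:
            p = 10.0 ** rng.uniform(-4.5, -0.05)
        pos_b37 = int(s["pos"]) - offsets[s["chrom"]]
        rows.append({"rsid": s["rsid"], "chrom": s["chrom"], "pos": pos_b37,
                     "ref": s["ref"], "risk_allele": s["risk"], "P": p,
                     "build": "GRCh37"})
    gwas = pd.DataFrame(rows)
    truth.snps = truth.snps.drop(columns=["P", "pos_b37"], errors="ignore")
    truth.snps = truth.snps.merge(gwas[["rsid", "P"]], on="rsid", how="left")
    truth.snps["pos_b37"] = truth.snps["pos"] - truth.snps["chrom"].map(offsets)

    # two decoys in the uncovered tail of chr1 exercise the unmapped path
    tail_lo = config.chrom_length - tail + 1
    for i in range(2):
        gwas.loc[len(gwas)] = {"rsid": f"rs_unmapped_{i}", "chrom": chroms[0],
                               "pos": tail_lo + 50 + i * 100, "ref": "A",
                               "risk_allele": "G", "P": 0.5, "build": "GRCh37"}

    n_ind = config.n_individuals
    geno = {}
    primaries = truth.snps.set_index("rsid")["ld_partner_of"]
    for rsid in gwas["rsid"]:
        partner = primaries.get(rsid)
        if isinstance(partner, str) and partner in geno:
            col = geno[partner].copy()
            j = int(rng.integers(0, n_ind))
            col[j] = min(2, col[j] + 1) if col[j] < 2 else col[j] - 1
            geno[rsid] = col
        else:
            maf = rng.uniform(0.1, 0.5)
            geno[rsid] = rng.binomial(2, maf, size=n_ind)
    genotypes = pd.DataFrame(geno, index=[f"ind{i:03d}" for i in range(n_ind)])
    return gwas, chain, genotypes


def generate_study(config: SynthConfig | None = None) -> SyntheticStudy:
    """Full seeded synthetic study: reference, truth and all data tables."""
    config = SynthConfig() if config is None else config
    reference = generate_reference(config)
    truth = plant_truth(config, reference)
    fragments, cells = simulate_fragments(truth, config, reference)
    rna = simulate_rna_counts(truth, config, cells)
    gwas, chain, genotypes = simulate_gwas_table(truth, config)
    return SyntheticStudy(config=config, reference=reference, truth=truth,
                          fragments=fragments, cells=cells, rna=rna,
                          gwas=gwas, chain=chain, genotypes=genotypes)
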