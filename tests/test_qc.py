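"""Unit and property tests for per-cell/per-gene QC and normalization."""

import numpy as np
import pandas as pd
import pytest

from devenh.qc import (QcPolicy, build_metacells,
                       compute_qc_metrics, compute_tss_enrichment,
                       deconvolution_size_factors, filter_cells, filter_genes,
                       hvg_select, in_silico_doublet_flags, normalize_log)


def _frag(chrom, start, end, barcode):
    return {"chrom": chrom, "start": start, "end": end, "barcode": barcode, "count": 1}


class TestQcMetrics:
    def test_mito_fraction_ratio(self):
        counts = pd.DataFrame({"GENE1": [90], "MT-G1": [10]}, index=["c1"])
        m = compute_qc_metrics(counts=counts)
        assert m.loc["c1", "mito_fraction"] == pytest.approx(0.1)
        assert m.loc["c1", "library_size"] == 100

    def test_zero_fragment_cell(self, toy_tss):
        counts = pd.DataFrame({"G": [5, 3]}, index=["c1", "c2"])
        frags = pd.DataFrame([_frag("chrA", 100, 300, "c1")])
        m = compute_qc_metrics(counts=counts, fragments=frags, tss_annotation=toy_tss)
        assert m.loc["c2", "n_fragments"] == 0
        assert m.loc["c2", "tss_enrichment"] == 0.0

    def test_genes_detected_matches_brute_force(self, rng):
        counts = pd.DataFrame(rng.poisson(0.5, size=(6, 9)),
                              index=[f"c{i}" for i in range(6)],
                              columns=[f"g{j}" for j in range(9)])
        m = compute_qc_metrics(counts=counts)
        for c in counts.index:
            assert m.loc[c, "genes_detected"] == sum(counts.loc[c, g] > 0 for g in counts.columns)

    def test_all_zero_cell_row_handled(self):
        counts = pd.DataFrame({"G1": [0, 4], "MT-G1": [0, 1]}, index=["z", "c"])
        m = compute_qc_metrics(counts=counts)
        assert m.loc["z", "library_size"] == 0
        assert m.loc["z", "mito_fraction"] == 0.0


class TestTssEnrichment:
    def test_no_promoter_signal_scores_at_most_one(self, toy_tss):
        rows = [_frag("chrA", 50_000 + 100 * i, 50_200 + 100 * i, "c1") for i in range(50)]
        score = compute_tss_enrichment(pd.DataFrame(rows), toy_tss)
        assert score["c1"] <= 1.0

    def test_flat_deep_coverage_scores_near_one(self, rng):
        tss = pd.DataFrame({"chrom": "chrA", "tss": [50_000], "gene": ["G"], "strand": "+"})
        starts = rng.integers(0, 100_000, size=50_000)
        frags = pd.DataFrame({"chrom": "chrA", "start": starts,
                              "end": starts + 1, "barcode": "c1", "count": 1})
        score = compute_tss_enrichment(frags, tss)
        assert score["c1"] == pytest.approx(1.0, abs=0.1)

    def test_matches_brute_force_window_counting(self, toy_tss, rng):
        starts = rng.integers(8_000, 32_000, size=400)
        frags = pd.DataFrame({"chrom": "chrA", "start": starts,
                              "end": starts + 150, "barcode": "c1", "count": 1})
        score = compute_tss_enrichment(frags, toy_tss)["c1"]
        # direct recount over every TSS window
        ins = np.concatenate([starts, starts + 149])
        n_sig = n_fl = 0
        for _, t in toy_tss.iterrows():
            if t["chrom"] != "chrA":
                continue
            d = np.abs(ins - t["tss"])
            n_sig += int((d <= 50).sum())
            n_fl += int(((d >= 1900) & (d <= 2000)).sum())
        n_tss = len(toy_tss)
        expect = (n_sig + 1) / (n_fl * (101 * n_tss) / (202 * n_tss) + 1)
        assert score == pytest.approx(expect)

    def test_no_tss_on_fragment_chromosomes_warns_and_zeroes(self, toy_tss):
        frags = pd.DataFrame([_frag("chrZ", 10, 200, "c1")])
        with pytest.warns(UserWarning):
            score = compute_tss_enrichment(frags, toy_tss)
        assert score["c1"] == 0.0


class TestFilterCells:
    def test_atac_boundaries(self):
        m = pd.DataFrame({
            "tss_enrichment": [4.0, 3.9, 4.0],
            "n_fragments": [1000, 1000, 999],
        }, index=["keep", "low_tss", "low_frag"])
        retained, reasons = filter_cells(m, QcPolicy(), "atac")
        assert retained == ["keep"]
        assert reasons.loc["low_tss", "reason"] == "low_tss"
        assert reasons.loc["low_frag", "reason"] == "low_fragments"

    def test_doublet_ceiling_boundary(self):
        m = pd.DataFrame({
            "library_size": [50_000, 50_001, 40_000],
            "genes_detected": [500, 500, 500],
            "mito_fraction": [0.01, 0.01, 0.01],
        }, index=["at", "above", "normal"])
        retained, reasons = filter_cells(m, QcPolicy(), "rna")
        assert "above" not in retained
        assert "doublet_ceiling" in reasons.loc["above", "reason"]
        assert "at" in retained

    def test_identical_metrics_mad_zero_no_rejection(self):
        m = pd.DataFrame({
            "library_size": [5000] * 8, "genes_detected": [900] * 8,
            "mito_fraction": [0.02] * 8,
        }, index=[f"c{i}" for i in range(8)])
        retained, _ = filter_cells(m, QcPolicy(), "rna")
        assert len(retained) == 8

    def test_multiome_additional_rules(self):
        m = pd.DataFrame({
            "tss_enrichment": [5.0, 5.0, 5.0],
            "n_fragments": [2000, 2000, 2000],
            "gex_reads": [500, 499, 600],
            "mito_fraction": [0.05, 0.01, 0.051],
        }, index=["ok", "low_gex", "high_mito"])
        retained, _ = filter_cells(m, QcPolicy(), "multiome")
        assert retained == ["ok"]

    def test_idempotent_on_fixed_threshold_modes(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame({
            "tss_enrichment": rng.uniform(0, 12, 200),
            "n_fragments": rng.integers(100, 5000, 200),
        }, index=[f"c{i}" for i in range(200)])
        retained, _ = filter_cells(m, QcPolicy(), "atac")
        retained2, _ = filter_cells(m.loc[retained], QcPolicy(), "atac")
        assert retained2 == retained

    def test_rna_idempotent_on_tight_core_with_outliers(self):
        # a tight core plus gross outliers: one pass removes the outliers and
        # a second pass changes nothing (MAD of the core is zero)
        m = pd.DataFrame({
            "library_size": [5000] * 20 + [100],
            "genes_detected": [900] * 20 + [50],
            "mito_fraction": [0.02] * 20 + [0.8],
        }, index=[f"c{i}" for i in range(21)])
        retained, _ = filter_cells(m, QcPolicy(), "rna")
        retained2, _ = filter_cells(m.loc[retained], QcPolicy(), "rna")
        assert retained2 == retained

    @pytest.mark.parametrize("loose,tight", [
        (QcPolicy(min_tss=4.0), QcPolicy(min_tss=6.0)),
        (QcPolicy(min_fragments=500), QcPolicy(min_fragments=2000)),
    ])
    def test_tightening_never_increases_retained(self, loose, tight):
        rng = np.random.default_rng(2)
        m = pd.DataFrame({
            "tss_enrichment": rng.uniform(0, 12, 300),
            "n_fragments": rng.integers(100, 5000, 300),
        }, index=[f"c{i}" for i in range(300)])
        kept_loose, _ = filter_cells(m, loose, "atac")
        kept_tight, _ = filter_cells(m, tight, "atac")
        assert set(kept_tight) <= set(kept_loose)

    def test_aggregated_mode_uses_quantile_ceiling(self):
        rng = np.random.default_rng(3)
        lib = rng.normal(5000, 100, 1000)
        lib[0] = 50_000
        m = pd.DataFrame({"library_size": lib,
                          "genes_detected": np.full(1000, 800.0),
                          "mito_fraction": np.full(1000, 0.02)},
                         index=[f"c{i}" for i in range(1000)])
        retained, reasons = filter_cells(m, QcPolicy(), "aggregated")
        assert "c0" not in retained
        assert "doublet_ceiling" in reasons.loc["c0", "reason"]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            filter_cells(pd.DataFrame(), QcPolicy(), "rna")


class TestFilterGenes:
    def test_mean_threshold_boundary(self):
        counts = pd.DataFrame({
            "keep": np.r_[np.ones(10), np.zeros(990)],      # mean 0.010
            "drop": np.r_[np.ones(9), np.zeros(991)],       # mean 0.009
            "zero": np.zeros(1000),
        })
        kept = filter_genes(counts, QcPolicy())
        assert kept == ["keep"]

    def test_matches_brute_force_on_toy(self, rng):
        counts = pd.DataFrame(rng.poisson(0.02, size=(5, 5)),
                              columns=[f"g{j}" for j in range(5)])
        kept = filter_genes(counts, QcPolicy())
        expect = [g for g in counts.columns if counts[g].mean() >= 0.01]
        assert kept == expect


class TestSizeFactors:
    def test_identical_cells_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([5, 3, 2, 8], (30, 1)))
        f = deconvolution_size_factors(counts, pool_sizes=(5, 11))
        np.testing.assert_allclose(f, 1.0, atol=1e-8)

    def test_double_depth_gives_double_factor(self):
        base = np.tile([5.0, 3.0, 2.0, 8.0, 1.0], (20, 1))
        counts = pd.DataFrame(np.vstack([base, 2 * base]))
        f = deconvolution_size_factors(counts, pool_sizes=(5, 11))
        ratio = f.iloc[20:].mean() / f.iloc[:20].mean()
        assert ratio == pytest.approx(2.0, abs=1e-6)

    def test_gene_permutation_invariance(self, rng):
        counts = pd.DataFrame(rng.poisson(5, size=(30, 12)) + 1)
        f1 = deconvolution_size_factors(counts, pool_sizes=(5, 11))
        perm = rng.permutation(12)
        f2 = deconvolution_size_factors(counts.iloc[:, perm], pool_sizes=(5, 11))
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_reduces_to_library_size_for_shared_composition(self, rng):
        profile = rng.dirichlet(np.ones(20) * 5)
        scale = rng.uniform(0.5, 2.0, size=40)
        counts = pd.DataFrame((2000 * scale[:, None] * profile[None, :]).round())
        f = deconvolution_size_factors(counts, pool_sizes=(5, 11, 21))
        lib = counts.sum(axis=1)
        lib_f = lib / np.exp(np.mean(np.log(lib)))
        np.testing.assert_allclose(f, lib_f, rtol=0.02)

    def test_all_zero_cell_rejected(self):
        counts = pd.DataFrame(np.vstack([np.ones((10, 3)), np.zeros((1, 3))]))
        with pytest.raises(ValueError):
            deconvolution_size_factors(counts, pool_sizes=(3,))


class TestNormalizeLog:
    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"g": [0, 4]})
        out = normalize_log(counts, pd.Series([1.0, 1.0]))
        assert out.iloc[0, 0] == 0.0

    def test_doubling_factor_halves_prelog(self):
        counts = pd.DataFrame({"g1": [4, 4], "g2": [2, 2]})
        a = normalize_log(counts, pd.Series([1.0, 1.0]))
        b = normalize_log(counts, pd.Series([1.0, 2.0]))
        np.testing.assert_allclose(np.expm1(b.iloc[1]), np.expm1(a.iloc[1]) / 2)

    def test_matches_hand_computed_two_by_two(self):
        counts = pd.DataFrame({"g1": [2, 0], "g2": [0, 6]})
        factors = pd.Series([1.0, 2.0])
        out = normalize_log(counts, factors)
        ref = counts.to_numpy().sum(axis=1).mean()  # = 4
        assert out.iloc[0, 0] == pytest.approx(np.log1p(1e6 * 2 / (1.0 * ref)))
        assert out.iloc[1, 1] == pytest.approx(np.log1p(1e6 * 6 / (2.0 * ref)))


class TestHvg:
    def test_null_controls_false_positive_rate(self, rng):
        n_cells, n_genes = 500, 500
        base = np.exp(rng.normal(0, 1.5, size=n_genes))
        base /= base.sum()
        depth = 3000 * np.exp(rng.normal(0, 0.3, size=n_cells))
        counts = pd.DataFrame(rng.poisson(depth[:, None] * base[None, :]))
        lib = counts.sum(axis=1)
        f = lib / np.exp(np.mean(np.log(lib)))
        res = hvg_select(normalize_log(counts, f))
        assert res["is_hvg"].mean() <= 0.05 + 0.03
        assert abs((res["p"] < 0.05).mean() - 0.05) <= 0.03

    def test_planted_hvgs_recovered(self, rng):
        n_cells, n_genes, n_bio = 500, 400, 40
        base = np.exp(rng.normal(0, 1.5, size=n_genes))
        base /= base.sum()
        depth = 3000 * np.exp(rng.normal(0, 0.3, size=n_cells))
        lam = depth[:, None] * base[None, :]
        bio_idx = rng.choice(n_genes, n_bio, replace=False)
        lam[:, bio_idx] *= np.exp(rng.normal(-1.0, np.sqrt(2.0), size=(n_cells, n_bio)))
        counts = pd.DataFrame(rng.poisson(lam))
        lib = counts.sum(axis=1)
        f = lib / np.exp(np.mean(np.log(lib)))
        res = hvg_select(normalize_log(counts, f))
        flagged = set(res.index[res["is_hvg"]])
        recall = len(flagged & set(bio_idx)) / n_bio
        assert recall >= 0.8

    def test_duplicated_gene_same_result(self, rng):
        counts = pd.DataFrame(rng.poisson(3, size=(100, 30)))
        counts[30] = counts[7]
        f = pd.Series(np.ones(100))
        res = hvg_select(normalize_log(counts, f))
        assert res.loc[7, "biological_variance"] == pytest.approx(
            res.loc[30, "biological_variance"])

    def test_too_few_genes_error(self):
        with pytest.raises(ValueError):
            hvg_select(pd.DataFrame(np.ones((10, 5))))


class TestDoublets:
    def test_null_flag_rate_low(self, rng):
        X = pd.DataFrame(rng.poisson(2.0, size=(1000, 60)))
        flagged = in_silico_doublet_flags(X, seed=0)
        assert len(flagged) / 1000 <= 0.02

    def test_planted_cross_cluster_doublets_recovered(self, rng):
        # two well-separated clusters with disjoint peak usage
        n_each, n_peaks = 200, 80
        a = np.hstack([rng.poisson(5.0, size=(n_each, n_peaks // 2)),
                       rng.poisson(0.05, size=(n_each, n_peaks // 2))])
        b = np.hstack([rng.poisson(0.05, size=(n_each, n_peaks // 2)),
                       rng.poisson(5.0, size=(n_each, n_peaks // 2))])
        doublets = a[:40] + b[:40]
        X = pd.DataFrame(np.vstack([a, b, doublets]),
                         index=[f"a{i}" for i in range(n_each)]
                         + [f"b{i}" for i in range(n_each)]
                         + [f"d{i}" for i in range(40)])
        flagged = set(in_silico_doublet_flags(X, seed=0))
        planted = {f"d{i}" for i in range(40)}
        assert len(flagged & planted) / 40 >= 0.8

    def test_zero_synth_rejected(self, rng):
        X = pd.DataFrame(rng.poisson(2.0, size=(100, 20)))
        with pytest.raises(ValueError):
            in_silico_doublet_flags(X, n_synth=0)


class TestMetacells:
    def _data(self, rng):
        rna = pd.DataFrame(rng.poisson(4, size=(60, 15)),
                           index=[f"c{i}" for i in range(60)])
        atac = pd.DataFrame(rng.poisson(1, size=(60, 25)),
                            index=[f"c{i}" for i in range(60)])
        labels = pd.Series(["x"] * 30 + ["y"] * 30, index=rna.index)
        return rna, atac, labels

    def test_identical_cells_give_identical_metacell(self):
        rna = pd.DataFrame(np.tile([3, 1, 4], (30, 1)), index=[f"c{i}" for i in range(30)])
        atac = pd.DataFrame(np.tile([2, 2], (30, 1)), index=rna.index)
        labels = pd.Series("k", index=rna.index)
        res = build_metacells(rna, atac, labels)
        np.testing.assert_allclose(res.rna.iloc[0], [3, 1, 4])

    def test_metacell_equals_mean_of_recorded_members(self, rng):
        rna, atac, labels = self._data(rng)
        res = build_metacells(rna, atac, labels, seed=3)
        for i in range(len(res.labels)):
            np.testing.assert_allclose(res.rna.iloc[i],
                                       rna.loc[res.rna_members[i]].mean(axis=0))
            np.testing.assert_allclose(res.atac.iloc[i],
                                       atac.loc[res.atac_members[i]].mean(axis=0))
            assert len(res.rna_members[i]) == 10  # default pool of ten cells

    def test_small_cluster_rejected(self, rng):
        rna, atac, labels = self._data(rng)
        with pytest.raises(ValueError):
            build_metacells(rna.iloc[:5], atac.iloc[:5], labels.iloc[:5])
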