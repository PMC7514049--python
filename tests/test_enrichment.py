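"""Matched resampling, signal counting and SNP-selection rules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from priortho.enrichment import (af_matched_control_snps,
                                 count_signals_near_genes, enrichment_test,
                                 sample_matched_controls, sample_snps_per_gene,
                                 select_top_snps, subset_comparison,
                                 SnpSelection)

from conftest import make_genotypes


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])


def _snps(positions, chrom="1"):
    return pd.DataFrame({"snp_id": [f"s{i}" for i in range(len(positions))],
                         "chrom": chrom, "pos_bp": positions})


class TestCounting:
    def test_empty_index_list(self):
        genes = _genes([("g1", "1", 100, 200)])
        assert count_signals_near_genes({"g1"}, genes, _snps([]), 50) == 0

    def test_snp_in_two_overlapping_genes_counts_once(self):
        genes = _genes([("g1", "1", 100, 300), ("g2", "1", 200, 400)])
        assert count_signals_near_genes({"g1", "g2"}, genes, _snps([250]), 10) == 1

    def test_matches_interval_oracle(self):
        rng = np.random.default_rng(5)
        genes = _genes([(f"g{i}", "1", s, s + rng.integers(500, 5_000))
                        for i, s in enumerate(rng.integers(0, 500_000, 20))])
        snps = _snps(sorted(rng.integers(0, 510_000, 60)))
        w = 1_000
        got = count_signals_near_genes(set(genes["gene_id"]), genes, snps, w)
        manual = sum(
            any(g.start_bp - w <= pos <= g.end_bp + w for _, g in genes.iterrows())
            for pos in snps["pos_bp"])
        assert got == manual

    def test_window_boundaries_inclusive(self):
        genes = _genes([("g1", "1", 1_000, 2_000)])
        assert count_signals_near_genes({"g1"}, genes, _snps([900]), 100) == 1
        assert count_signals_near_genes({"g1"}, genes, _snps([899]), 100) == 0


class TestMatchedControls:
    def test_single_stratum_candidates(self):
        rng = np.random.default_rng(0)
        uni = [f"g{i}" for i in range(120)]
        sizes = np.arange(120, dtype=float)
        # candidates all in stratum 3 (ranks 25..36)
        cand = set(uni[24:36])
        ctrl = sample_matched_controls(cand, uni, sizes, k=10, rng=rng)
        assert len(ctrl) == 12
        assert ctrl <= set(uni[24:36])

    def test_candidates_equal_universe(self):
        uni = [f"g{i}" for i in range(40)]
        ctrl = sample_matched_controls(set(uni), uni, np.arange(40.0), k=4,
                                       rng=1)
        assert ctrl == set(uni)

    def test_histogram_preserved_every_replicate(self):
        from priortho.overlap import stratify_by_quantile
        rng = np.random.default_rng(2)
        uni = [f"g{i}" for i in range(200)]
        sizes = rng.lognormal(3, 1, 200)
        labels = stratify_by_quantile(sizes, k=10)
        cand = set(rng.choice(uni, 35, replace=False))
        cand_hist = np.bincount([labels[uni.index(g)] for g in cand],
                                minlength=11)
        for _ in range(50):
            ctrl = sample_matched_controls(cand, uni, sizes, k=10, rng=rng)
            hist = np.bincount([labels[uni.index(g)] for g in ctrl],
                               minlength=11)
            assert np.array_equal(hist, cand_hist)

    def test_impossible_stratum_errors(self):
        uni = [f"g{i}" for i in range(20)]
        cand = set(uni[:2])  # both in lowest stratum
        with pytest.raises(ValueError, match="stratum"):
            sample_matched_controls(cand, uni, np.arange(20.0), k=10, rng=0,
                                    exclude_candidates=True)


class TestEnrichmentTest:
    GENES = _genes([(f"g{i}", "1", i * 10_000, i * 10_000 + 2_000)
                    for i in range(40)])

    def test_no_signals_anywhere_p_is_one(self):
        sizes = (self.GENES["end_bp"] - self.GENES["start_bp"]
                 + np.arange(40)).to_numpy(dtype=float)
        res = enrichment_test({"g1", "g2"}, self.GENES["gene_id"].tolist(),
                              sizes, self.GENES, _snps([]), 1_000,
                              n_reps=50, seed=0)
        assert res.observed_count == 0
        assert all(c == 0 for c in res.null_counts)
        assert res.empirical_p == 1.0

    def test_candidates_equal_universe_p_is_one(self):
        sizes = np.arange(40, dtype=float)
        res = enrichment_test(set(self.GENES["gene_id"]),
                              self.GENES["gene_id"].tolist(), sizes,
                              self.GENES, _snps([5_000, 15_000]), 1_000,
                              n_reps=20, seed=0)
        assert res.empirical_p == 1.0

    def test_plus_one_correction_flag(self):
        sizes = np.arange(40, dtype=float)
        res = enrichment_test({"g0"}, self.GENES["gene_id"].tolist(), sizes,
                              self.GENES, _snps([]), 1_000, n_reps=10,
                              seed=0, plus_one=True)
        assert res.empirical_p == pytest.approx(11 / 11)

    def test_seed_reproducible(self):
        sizes = np.arange(40, dtype=float)
        r1 = enrichment_test({"g0", "g5"}, self.GENES["gene_id"].tolist(),
                             sizes, self.GENES, _snps([5_000, 25_000]),
                             1_000, n_reps=30, seed=9)
        r2 = enrichment_test({"g0", "g5"}, self.GENES["gene_id"].tolist(),
                             sizes, self.GENES, _snps([5_000, 25_000]),
                             1_000, n_reps=30, seed=9)
        assert r1.null_counts == r2.null_counts


class TestSubsetComparison:
    GENES = _genes([(f"g{i}", "1", i * 10_000, i * 10_000 + 2_000)
                    for i in range(30)])

    def test_identical_sets_full_subsample_p_one(self):
        ids = set(self.GENES["gene_id"])
        res = subset_comparison(ids, len(ids), ids, self.GENES,
                                _snps([5_000, 15_000]), n_reps=20, seed=0)
        assert res.empirical_p == 1.0

    def test_reference_count_zero(self):
        ids = set(self.GENES["gene_id"])
        res = subset_comparison(ids, 5, {"g0"}, self.GENES,
                                _snps([155_000]), window_bp=1_000,
                                n_reps=100, seed=1)
        frac_zero = np.mean([c == 0 for c in res.null_counts])
        assert res.empirical_p == pytest.approx(frac_zero)


class TestSnpSelection:
    def _validation(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(100, 15)).astype(np.float32)
        return make_genotypes(d, positions=np.arange(15) * 2_000 + 1_000)

    def test_top_one_is_global_min_p(self):
        geno = self._validation()
        genes = _genes([("g1", "1", 0, 40_000)])
        summary = pd.DataFrame({
            "snp_id": geno.snp_meta["snp_id"], "chrom": "1",
            "pos_bp": geno.snp_meta["pos_bp"],
            "p": np.linspace(0.9, 0.01, 15)})
        sel = select_top_snps({"g1"}, genes, summary, geno, n_top=1, min_mac=1)
        assert sel.snp_ids == [geno.snp_meta["snp_id"].iloc[-1]]

    def test_all_fail_mac_warns_and_empty(self):
        geno = self._validation()
        genes = _genes([("g1", "1", 0, 40_000)])
        summary = pd.DataFrame({
            "snp_id": geno.snp_meta["snp_id"], "chrom": "1",
            "pos_bp": geno.snp_meta["pos_bp"], "p": 0.5})
        with pytest.warns(UserWarning, match="eligible"):
            sel = select_top_snps({"g1"}, genes, summary, geno, n_top=5,
                                  min_mac=10_000)
        assert sel.snp_ids == []

    def test_matches_manual_sort(self):
        geno = self._validation()
        genes = _genes([("g1", "1", 0, 40_000)])
        rng = np.random.default_rng(3)
        summary = pd.DataFrame({
            "snp_id": geno.snp_meta["snp_id"], "chrom": "1",
            "pos_bp": geno.snp_meta["pos_bp"], "p": rng.uniform(size=15)})
        sel = select_top_snps({"g1"}, genes, summary, geno, n_top=6, min_mac=1)
        manual = summary.sort_values(["p", "chrom", "pos_bp"])["snp_id"].head(6)
        assert sel.snp_ids == manual.tolist()

    def test_per_gene_sampling_takes_all_when_short(self):
        geno = self._validation()
        genes = _genes([("g1", "1", 1_000, 5_000)])
        sel = sample_snps_per_gene({"g1"}, genes, geno.snp_meta, k=5,
                                   window_bp=0, min_mac=1, rng=0)
        in_gene = geno.snp_meta[(geno.snp_meta["pos_bp"] >= 1_000)
                                & (geno.snp_meta["pos_bp"] <= 5_000)]
        assert sorted(sel.snp_ids) == sorted(in_gene["snp_id"])

    def test_shared_snps_deduplicated(self):
        geno = self._validation()
        genes = _genes([("g1", "1", 0, 30_000), ("g2", "1", 0, 30_000)])
        sel = sample_snps_per_gene({"g1", "g2"}, genes, geno.snp_meta, k=5,
                                   window_bp=0, min_mac=1, rng=1)
        assert len(sel.snp_ids) == len(set(sel.snp_ids))

    def test_per_gene_sampling_reproducible(self):
        geno = self._validation()
        genes = _genes([("g1", "1", 0, 30_000)])
        a = sample_snps_per_gene({"g1"}, genes, geno.snp_meta, k=3, rng=7)
        b = sample_snps_per_gene({"g1"}, genes, geno.snp_meta, k=3, rng=7)
        assert a.snp_ids == b.snp_ids


class TestAfMatching:
    def _meta(self, freqs, prefix="p"):
        return pd.DataFrame({
            "snp_id": [f"{prefix}{i}" for i in range(len(freqs))],
            "chrom": "1", "pos_bp": np.arange(len(freqs)) * 100 + 1,
            "allele_freq": freqs, "mac": 50, "monomorphic": False})

    def test_single_bin_candidates_draw_from_that_bin(self):
        cand = SnpSelection("c", [f"c{i}" for i in range(5)], "top_by_p",
                            {f"c{i}": 0.47 for i in range(5)})
        pool = self._meta(np.concatenate([np.full(20, 0.46),
                                          np.full(20, 0.12)]))
        sel = af_matched_control_snps(cand, pool, rng=0)
        assert len(sel.snp_ids) == 5
        assert all(0.45 <= sel.allele_freq[s] < 0.5 for s in sel.snp_ids)

    def test_bin_histograms_match(self):
        rng = np.random.default_rng(10)
        maf = rng.uniform(0.05, 0.5, 40)
        cand = SnpSelection("c", [f"c{i}" for i in range(40)], "top_by_p",
                            {f"c{i}": maf[i] for i in range(40)})
        pool = self._meta(rng.uniform(0.02, 0.5, 2_000))
        sel = af_matched_control_snps(cand, pool, bin_width=0.05, rng=1)
        def hist(freqs):
            m = np.minimum(np.asarray(freqs), 1 - np.asarray(freqs))
            return np.bincount((m / 0.05).astype(int), minlength=12)
        assert np.array_equal(hist(list(cand.allele_freq.values())),
                              hist(list(sel.allele_freq.values())))

    def test_mean_maf_gap_below_bin_width(self):
        rng = np.random.default_rng(11)
        maf = rng.uniform(0.05, 0.5, 30)
        cand = SnpSelection("c", [f"c{i}" for i in range(30)], "top_by_p",
                            {f"c{i}": maf[i] for i in range(30)})
        gaps = []
        for seed in range(20):
            pool = self._meta(np.random.default_rng(seed).uniform(0.02, 0.5, 1_000))
            sel = af_matched_control_snps(cand, pool, rng=seed)
            gaps.append(abs(np.mean(np.minimum(maf, 1 - maf))
                            - np.mean([min(f, 1 - f)
                                       for f in sel.allele_freq.values()])))
        assert np.mean(gaps) < 0.05
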