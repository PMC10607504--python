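"""Prefix-block enumeration, EM haplotype inference, and the omnibus test."""

import numpy as np
import pytest

from haploclust.datasets import CASE, CONTROL
from haploclust.haplotypes import (BlockResult, LDBlock, bonferroni_adjust,
                                   em_haplotype_frequencies,
                                   enumerate_prefix_blocks, omnibus_chi2,
                                   omnibus_test, run_cluster_gwas,
                                   select_best_block)

from conftest import make_dataset


def ht_freqs(table):
    """Haplotype-string -> frequency mapping for readable assertions."""
    return dict(zip(table.haplotype_strings(), table.freq_overall))


class TestPrefixBlocks:
    def test_five_variant_cluster_yields_four_blocks(self):
        pos = np.array([10, 20, 30, 40, 50])
        blocks = enumerate_prefix_blocks(0, np.arange(5), pos)
        assert [b.size for b in blocks] == [2, 3, 4, 5]
        for b in blocks:
            np.testing.assert_array_equal(b.variant_indices, np.arange(b.size))

    def test_pair_cluster_yields_one_block(self):
        blocks = enumerate_prefix_blocks(1, np.array([3, 7]), np.arange(100))
        assert len(blocks) == 1 and blocks[0].size == 2

    def test_blocks_respect_coordinate_order(self):
        pos = np.array([500, 100, 300])
        blocks = enumerate_prefix_blocks(0, np.array([0, 1, 2]), pos)
        np.testing.assert_array_equal(blocks[0].variant_indices, [1, 2])
        np.testing.assert_array_equal(blocks[1].variant_indices, [1, 2, 0])

    def test_singleton_cluster_untestable(self):
        assert enumerate_prefix_blocks(0, np.array([4]), np.arange(10)) == []


class TestEMFrequencies:
    def test_no_phase_ambiguity_exact_counts(self):
        d = np.array([[0, 0]] * 50 + [[2, 2]] * 50, dtype=np.int8)
        ds = make_dataset(d, phenotype=[CASE] * 50 + [CONTROL] * 50)
        ht = em_haplotype_frequencies(ds, np.array([0, 1]))
        freqs = ht_freqs(ht)
        assert freqs.get("00", 0) == pytest.approx(0.5, abs=1e-9)
        assert freqs.get("11", 0) == pytest.approx(0.5, abs=1e-9)
        assert ht.converged

    def test_double_heterozygotes_resolve_to_coupling(self):
        d = np.array([[0, 0]] * 40 + [[2, 2]] * 40 + [[1, 1]] * 20, dtype=np.int8)
        ds = make_dataset(d, phenotype=[CASE] * 50 + [CONTROL] * 50)
        ht = em_haplotype_frequencies(ds, np.array([0, 1]))
        freqs = ht_freqs(ht)
        assert freqs.get("00", 0) == pytest.approx(0.5, abs=1e-4)
        assert freqs.get("11", 0) == pytest.approx(0.5, abs=1e-4)
        assert freqs.get("01", 0) == pytest.approx(0.0, abs=1e-4)
        assert freqs.get("10", 0) == pytest.approx(0.0, abs=1e-4)

    def test_loglik_monotone_and_freqs_normalized(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        ds = make_dataset(d, phenotype=rng.integers(0, 2, 60).astype(np.int8))
        ht = em_haplotype_frequencies(ds, np.arange(4))
        assert ht.freq_overall.sum() == pytest.approx(1.0, abs=1e-6)
        diffs = np.diff(ht.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_counts_sum_to_chromosome_totals(self):
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, size=(80, 3)).astype(np.int8)
        pheno = np.array([CASE] * 30 + [CONTROL] * 50, dtype=np.int8)
        ds = make_dataset(d, phenotype=pheno)
        ht = em_haplotype_frequencies(ds, np.arange(3))
        assert ht.count_case.sum() == pytest.approx(60, abs=1e-6)
        assert ht.count_control.sum() == pytest.approx(100, abs=1e-6)

    def test_direct_counting_when_unambiguous(self):
        # at most one het site per individual: phase is determined
        rng = np.random.default_rng(12)
        hap = rng.integers(0, 2, size=(200, 3))
        d = (hap[0::2] + hap[1::2]).astype(np.int8)
        keep = (d == 1).sum(axis=1) <= 1
        d = d[keep]
        ds = make_dataset(d, phenotype=np.zeros(len(d), dtype=np.int8))
        ht = em_haplotype_frequencies(ds, np.arange(3))
        # oracle: count haplotypes directly from resolved phases
        from collections import Counter
        counts = Counter()
        for row in d:
            hets = np.flatnonzero(row == 1)
            h1 = (row == 2).astype(int)
            h2 = h1.copy()
            if len(hets) == 1:
                h1[hets[0]] = 1
            counts["".join(map(str, h1))] += 1
            counts["".join(map(str, h2))] += 1
        total = sum(counts.values())
        freqs = ht_freqs(ht)
        for hap_str, c in counts.items():
            assert freqs.get(hap_str, 0) == pytest.approx(c / total, abs=1e-6)

    def test_ligation_matches_exhaustive_enumeration(self, block_panel):
        # 16-variant block solved by ligation vs full enumeration as oracle
        from haploclust.simulate import mosaic_resample
        ds = mosaic_resample(block_panel, 250, seed=21)
        idx = np.arange(16)
        pheno = np.zeros(250, dtype=np.int8)
        ds = make_dataset(ds.dosages[:, :16], phenotype=pheno)
        lig = em_haplotype_frequencies(ds, idx, max_enum=12)
        full = em_haplotype_frequencies(ds, idx, max_enum=16)
        f_lig = ht_freqs(lig)
        f_full = ht_freqs(full)
        common = {h for h, f in f_full.items() if f > 0.01}
        for h in common:
            assert f_lig.get(h, 0) == pytest.approx(f_full[h], abs=0.02)

    def test_oversized_block_skipped(self):
        d = np.zeros((10, 70), dtype=np.int8)
        ds = make_dataset(d, phenotype=np.zeros(10, dtype=np.int8))
        with pytest.warns(UserWarning):
            out = em_haplotype_frequencies(ds, np.arange(70), max_block=64)
        assert out is None


class TestOmnibusTest:
    @staticmethod
    def _table(count_case, count_control):
        from haploclust.haplotypes import HaplotypeTable
        count_case = np.asarray(count_case, dtype=float)
        count_control = np.asarray(count_control, dtype=float)
        total = count_case + count_control
        return HaplotypeTable(
            haplotype_codes=np.arange(len(total)), n_sites=1,
            freq_overall=total / total.sum(),
            count_case=count_case, count_control=count_control,
            n_case=int(count_case.sum() // 2),
            n_control=int(count_control.sum() // 2),
            converged=True, log_likelihood=0.0)

    def test_identical_distributions_null(self):
        res = omnibus_test(self._table([50, 50], [50, 50]))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_unadjusted == pytest.approx(1.0)

    def test_known_2x2_statistic(self):
        # closed form N(ad-bc)^2 / (row x col products) = 12.5 on this table
        res = omnibus_test(self._table([90, 10], [70, 30]))
        assert res.chi2 == pytest.approx(12.5)
        assert res.df == 1
        assert res.p_unadjusted == pytest.approx(4.07e-4, rel=2e-3)

    def test_rare_haplotype_excluded(self):
        res = omnibus_test(self._table([90, 10, 0.5], [70, 30, 0.5]),
                           min_hap_freq=0.01)
        assert res.df == 1

    def test_untestable_when_one_haplotype_left(self):
        res = omnibus_test(self._table([99, 1], [99, 1]), min_hap_freq=0.05)
        assert not res.testable
        assert res.p_unadjusted == 1.0

    def test_matches_textbook_chi2_on_fractional_table(self):
        rng = np.random.default_rng(2)
        table = rng.random((4, 2)) * 50 + 1
        stat, df, p = omnibus_chi2(table)
        from scipy.stats import chi2_contingency
        ref = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestSelectionAndAdjustment:
    @staticmethod
    def _result(p, size, cid=0):
        return BlockResult(cid, size, np.arange(size), 1.0, 1, p, testable=True,
                           converged=True)

    def test_tie_on_p_takes_largest_block(self):
        results = [self._result(0.01, 2), self._result(0.001, 3),
                   self._result(0.001, 4)]
        assert select_best_block(results).size == 4

    def test_single_block_selected(self):
        r = [self._result(0.5, 2)]
        assert select_best_block(r) is r[0]
        assert r[0].selected

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ordering(self, seed):
        rng = np.random.default_rng(seed)
        ps = rng.choice([0.1, 0.01, 0.001], size=8)
        sizes = rng.integers(2, 10, size=8)
        results = [self._result(p, s) for p, s in zip(ps, sizes)]
        best = select_best_block(results)
        oracle = sorted(enumerate(results),
                        key=lambda ir: (ir[1].p_unadjusted, -ir[1].size, ir[0]))[0][1]
        assert best is oracle

    def test_bonferroni_scaling_and_cap(self):
        r1, r2 = self._result(0.001, 2), self._result(0.5, 2)
        bonferroni_adjust([r1, r2], m=50)
        assert r1.p_adjusted == pytest.approx(0.05)
        assert r2.p_adjusted == 1.0

    def test_m_smaller_than_results_raises(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([self._result(0.1, 2)] * 3, m=2)

    def test_m_is_cluster_count_not_block_count(self):
        # the adjustment is invariant to how many prefix blocks clusters had
        selected = [self._result(0.01, s, cid) for cid, s in enumerate([2, 9])]
        bonferroni_adjust(selected, m=2)
        assert all(r.p_adjusted == pytest.approx(0.02) for r in selected)


class TestClusterGWAS:
    def test_null_simulation_no_significant_clusters(self):
        from haploclust.simulate import generate_reference_panel, mosaic_resample
        rng = np.random.default_rng(31)
        n_sig = 0
        for seed in range(20):
            panel = generate_reference_panel(n_variants=60, seed=400 + seed)
            ds = mosaic_resample(panel, 300, seed=500 + seed)
            pheno = np.zeros(300, dtype=np.int8)
            pheno[rng.permutation(300)[:100]] = CASE
            ds = make_dataset(ds.dosages, phenotype=pheno,
                              positions=panel.variants["pos"].to_numpy())
            from haploclust.cluster import run_dbscan
            from haploclust.ld import distance_matrix, ld_matrix
            dist = distance_matrix(ld_matrix(ds, estimator="dosage_corr"))
            labels = run_dbscan(dist, eps=0.35, min_samples=2)
            _, summary = run_cluster_gwas(ds, labels, mode="fixed")
            n_sig += summary["n_significant"]
        assert n_sig == 0

    def test_summary_block_sizes_at_least_two(self, block_panel):
        from haploclust.cluster import run_dbscan
        from haploclust.ld import distance_matrix, ld_matrix
        from haploclust.simulate import mosaic_resample
        ds = mosaic_resample(block_panel, 200, seed=6)
        pheno = np.zeros(200, dtype=np.int8)
        pheno[:80] = CASE
        ds = make_dataset(ds.dosages, phenotype=pheno,
                          positions=block_panel.variants["pos"].to_numpy())
        dist = distance_matrix(ld_matrix(ds, estimator="dosage_corr"))
        labels = run_dbscan(dist, eps=0.35, min_samples=2)
        selected, summary = run_cluster_gwas(ds, labels, mode="fixed")
        assert summary["selected_block_size_median"] >= 2
        assert all(r.size >= 2 for r in selected)
        assert all(r.p_adjusted >= r.p_unadjusted - 1e-15 for r in selected)
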