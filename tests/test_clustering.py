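"""Density-based clustering, quality metrics, and parameter tuning."""

import numpy as np
import pytest

from haploclust.cluster import (EPS_GRID, MIN_SAMPLES_GRID, SNPClusterer,
                                consensus_params, evaluate_quality,
                                run_dbscan, run_hdbscan, summarize_partitions,
                                tune_parameters)


def dbscan_reachability_oracle(dist, eps, min_samples):
    """Brute-force Ester et al. DBSCAN: core points by neighborhood census,
    clusters as connected components of eps-reachable core points (expanded
    in index order), border points claimed by the first expanding cluster."""
    n = len(dist)
    neighbors = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        frontier = [i]
        labels[i] = cid
        while frontier:
            q = frontier.pop()
            if not core[q]:
                continue
            for nb in neighbors[q]:
                if labels[nb] == -1:
                    labels[nb] = cid
                    frontier.append(nb)
        cid += 1
    return labels


def random_distance_matrix(rng, n):
    d = rng.random((n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def relabelled(labels):
    """Canonical form: clusters renumbered by first appearance."""
    mapping, out = {}, []
    for lab in labels:
        if lab == -1:
            out.append(-1)
            continue
        mapping.setdefault(lab, len(mapping))
        out.append(mapping[lab])
    return out


class TestDBSCAN:
    def test_two_separated_groups(self):
        # within-group distance 0, between-group 1, eps=0.35, min_samples=2
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        labels = run_dbscan(d, eps=0.35, min_samples=2)
        assert len(set(labels)) == 2 and -1 not in labels

    def test_isolated_point_is_noise(self):
        d = np.zeros((4, 4))
        d[3, :] = d[:, 3] = 1.0
        d[3, 3] = 0.0
        labels = run_dbscan(d, eps=0.35, min_samples=2)
        assert labels[3] == -1
        assert len(set(labels[:3])) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        d = random_distance_matrix(rng, n)
        eps = float(rng.uniform(0.1, 0.9))
        ms = int(rng.integers(2, 6))
        got = run_dbscan(d, eps=eps, min_samples=ms)
        want = dbscan_reachability_oracle(d, eps, ms)
        assert relabelled(got) == relabelled(want)

    def test_eps_out_of_range_raises(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            run_dbscan(d, eps=1.5, min_samples=2)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(42)
        d = random_distance_matrix(rng, 20)
        labels = run_dbscan(d, eps=0.4, min_samples=3)
        perm = rng.permutation(20)
        labels_p = run_dbscan(d[np.ix_(perm, perm)], eps=0.4, min_samples=3)
        # cluster partitions agree up to relabeling
        from sklearn.metrics import adjusted_rand_score
        keep = (labels[perm] != -1) & (labels_p != -1)
        assert (labels[perm] == -1).sum() == (labels_p == -1).sum()
        if keep.sum() > 1:
            assert adjusted_rand_score(labels[perm][keep], labels_p[keep]) == 1.0

    def test_efficiency_non_increasing_in_min_samples(self):
        rng = np.random.default_rng(7)
        d = random_distance_matrix(rng, 40)
        effs = []
        for ms in range(2, 8):
            labels = run_dbscan(d, eps=0.3, min_samples=ms)
            effs.append((labels != -1).mean())
        assert all(a >= b - 1e-12 for a, b in zip(effs, effs[1:]))


class TestHDBSCAN:
    def test_two_tight_groups(self):
        d = np.ones((10, 10)) * 0.9
        d[:5, :5] = 0.05
        d[5:, 5:] = 0.05
        np.fill_diagonal(d, 0)
        labels = run_hdbscan(d, cluster_selection_epsilon=0.25, min_samples=2)
        assert len(set(labels) - {-1}) == 2

    def test_variable_density_recovery(self):
        # dense group (distances 0.05) + sparse but separated group (0.45);
        # dbscan at eps=0.25 loses the sparse group, hdbscan keeps both
        n1, n2 = 6, 6
        n = n1 + n2
        d = np.full((n, n), 0.95)
        d[:n1, :n1] = 0.05
        d[n1:, n1:] = 0.45
        np.fill_diagonal(d, 0)
        db = run_dbscan(d, eps=0.25, min_samples=3)
        assert set(db[n1:]) == {-1}
        hd = run_hdbscan(d, cluster_selection_epsilon=0.0, min_samples=3)
        assert len(set(hd[:n1])) == 1 and set(hd[:n1]) != {-1}
        assert len(set(hd[n1:])) == 1 and set(hd[n1:]) != {-1}

    def test_all_far_apart_is_all_noise(self):
        d = np.ones((12, 12))
        np.fill_diagonal(d, 0)
        labels = run_hdbscan(d, cluster_selection_epsilon=0.25,
                             min_samples=5, min_cluster_size=5)
        assert set(labels) == {-1}

    def test_min_cluster_size_below_two_raises(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            run_hdbscan(d, 0.25, min_samples=1, min_cluster_size=1)

    def test_hdbscan_not_noisier_than_dbscan_on_block_panels(self):
        # at the shared genome-scan settings (eps 0.41, min_samples 5), hdbscan
        # assigns at least as many variants as dbscan in expectation over seeds
        from haploclust.ld import distance_matrix, ld_matrix
        from haploclust.simulate import generate_reference_panel, mosaic_resample
        noise_db, noise_hd = 0, 0
        for seed in range(10):
            panel = generate_reference_panel(n_variants=150, seed=100 + seed)
            ds = mosaic_resample(panel, 300, seed=200 + seed)
            dist = distance_matrix(ld_matrix(ds, estimator="dosage_corr"))
            noise_db += (run_dbscan(dist, eps=0.41, min_samples=5) == -1).sum()
            noise_hd += (run_hdbscan(dist, 0.41, min_samples=5) == -1).sum()
        assert noise_hd <= noise_db


class TestQuality:
    def test_perfectly_separated_clusters_have_silhouette_one(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        q = evaluate_quality(d, labels)
        assert q.silhouette == pytest.approx(1.0)
        assert q.n_clusters == 2
        assert q.efficiency == 1.0

    def test_silhouette_matches_hand_formula(self):
        rng = np.random.default_rng(13)
        d = random_distance_matrix(rng, 12)
        labels = np.array([0] * 4 + [1] * 4 + [2] * 4)
        q = evaluate_quality(d, labels)
        svals = []
        for i in range(12):
            own = [d[i, j] for j in range(12) if labels[j] == labels[i] and j != i]
            a = np.mean(own)
            b = min(np.mean([d[i, j] for j in range(12) if labels[j] == other])
                    for other in set(labels) - {labels[i]})
            svals.append((b - a) / max(a, b))
        assert q.silhouette == pytest.approx(np.mean(svals), abs=1e-12)

    def test_efficiency_from_census(self):
        # clustered / (clustered + noise): the published genome-wide DBSCAN census
        labels = np.array([0, 0, -1, 1, 1])
        q = evaluate_quality(np.zeros((5, 5)), labels)
        assert q.efficiency == pytest.approx(4 / 5)
        assert round(475_445 / (475_445 + 396_180), 2) == 0.55

    def test_single_cluster_flagged_invalid(self):
        d = np.zeros((4, 4))
        q = evaluate_quality(d, np.zeros(4, dtype=int))
        assert not q.valid and np.isnan(q.silhouette)


class TestTuning:
    @staticmethod
    def _two_group_dist():
        d = np.full((12, 12), 0.9)
        d[:6, :6] = 0.1
        d[6:, 6:] = 0.1
        np.fill_diagonal(d, 0)
        return d

    def test_winner_separates_groups(self):
        params, traj = tune_parameters(self._two_group_dist(), "dbscan")
        assert 0.1 < params["eps"] < 0.9

    def test_grid_census(self):
        _, traj = tune_parameters(self._two_group_dist(), "dbscan")
        assert len(traj) == len(MIN_SAMPLES_GRID) + len(EPS_GRID)
        assert (traj["stage"] == 1).sum() == 9
        # eps grid: 0.01, 0.11, ..., 0.91 plus the appended 1.00 endpoint
        assert (traj["stage"] == 2).sum() == 11
        assert traj.loc[traj["stage"] == 2, "eps"].iloc[0] == 0.01
        assert traj.loc[traj["stage"] == 2, "eps"].iloc[-1] == 1.0

    def test_recovers_generating_blocks(self, block_panel):
        # clean block panel: tuned clustering reproduces the generator's blocks
        from sklearn.metrics import adjusted_rand_score

        from haploclust.ld import distance_matrix, ld_matrix
        from haploclust.simulate import mosaic_resample
        ds = mosaic_resample(block_panel, 300, recomb_scale=50.0,
                             error_rate=0.0, seed=5)
        dist = distance_matrix(ld_matrix(ds, estimator="dosage_corr"))
        params, _ = tune_parameters(dist, "dbscan")
        labels = SNPClusterer("dbscan", eps=params["eps"],
                              min_samples=params["min_samples"]).fit(dist).labels_
        truth = block_panel.block_id
        # clusters that survive tuning coincide with generating blocks; small
        # blocks below the tuned min_samples legitimately fall out as noise
        keep = labels != -1
        assert keep.mean() > 0.4
        assert adjusted_rand_score(truth[keep], labels[keep]) > 0.95

    def test_all_degenerate_raises(self):
        d = np.ones((8, 8))
        np.fill_diagonal(d, 0)
        # every point isolated at distance 1: stage 1 at eps=0.5 finds no clusters
        with pytest.raises(RuntimeError):
            tune_parameters(d, "dbscan")

    def test_consensus_mode_prefers_smaller_eps(self):
        params = [{"algorithm": "dbscan", "eps": 0.41, "min_samples": 5},
                  {"algorithm": "dbscan", "eps": 0.31, "min_samples": 5},
                  {"algorithm": "dbscan", "eps": 0.41, "min_samples": 5},
                  {"algorithm": "dbscan", "eps": 0.31, "min_samples": 5}]
        assert consensus_params(params)["eps"] == 0.31


class TestPartitionSummary:
    def test_z_scores_with_population_sd(self):
        from haploclust.cluster import ClusterQuality
        qs = [ClusterQuality(s, s, int(s), 10, 0) for s in (1.0, 2.0, 3.0)]
        df = summarize_partitions(qs, [1, 1, 1])
        np.testing.assert_allclose(df["z_silhouette"],
                                   [-1.22474487, 0.0, 1.22474487], atol=1e-6)

    def test_identical_partitions_give_zero(self):
        from haploclust.cluster import ClusterQuality
        qs = [ClusterQuality(0.5, 10.0, 3, 10, 2)] * 4
        df = summarize_partitions(qs, [10] * 4)
        assert (df.to_numpy() == 0).all()
        assert df.attrs["degenerate"]["silhouette"]

    def test_normalization_by_variant_count(self):
        from haploclust.cluster import ClusterQuality
        # same metric, different partition sizes: z reflects metric / n
        qs = [ClusterQuality(1.0, 1.0, 1, 10, 0), ClusterQuality(2.0, 2.0, 2, 20, 0)]
        df = summarize_partitions(qs, [10, 20])
        assert (df["z_silhouette"] == 0).all()
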