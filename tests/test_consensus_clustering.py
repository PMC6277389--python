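"""Consensus-clustering checks: matrix construction, AUC-CDF selection,
final cuts, coherence statistics, and planted-partition recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score

from bamscope import (
    ClusterAssignment,
    ScenarioConfig,
    auc_cdf,
    coherence_tests,
    compute_tscore_bam,
    consensus_cluster,
    cut_clusters,
    fit_pca,
    make_default_template,
    select_k,
    simulate_bam_library,
)
from bamscope.consensus_clustering import ConsensusResult
from bamscope.phenoprint import project_library


def _two_clouds(n_per=12, sep=100.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 5))
    b = rng.normal(0, 1, size=(n_per, 5)) + sep
    x = np.vstack([a, b])
    ids = [f"d{i}" for i in range(2 * n_per)]
    return x, ids


def _fake_result(aucs: dict[int, float]) -> ConsensusResult:
    ks = sorted(aucs)
    n = 4
    m = np.eye(n)
    return ConsensusResult(
        drug_ids=[f"d{i}" for i in range(n)],
        ks=ks,
        consensus={k: m for k in ks},
        cosample_counts=np.full((n, n), 10),
        aucs=aucs,
        n_iterations=10,
        subsample_frac=0.8,
        seed=0,
    )


class TestConsensusMatrix:
    def test_separated_clouds_give_block_consensus(self):
        x, ids = _two_clouds()
        res = consensus_cluster(x, ids, k_range=[2], n_iterations=100, seed=1)
        m = res.consensus[2]
        within = np.concatenate([m[:12, :12][np.triu_indices(12, 1)],
                                 m[12:, 12:][np.triu_indices(12, 1)]])
        between = m[:12, 12:].ravel()
        assert np.all(within == 1.0)
        assert np.all(between == 0.0)

    def test_full_subsample_gives_binary_entries(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(15, 4))
        ids = [f"d{i}" for i in range(15)]
        res = consensus_cluster(x, ids, k_range=[3], n_iterations=25,
                                subsample_frac=1.0, seed=3)
        vals = res.consensus[3][np.triu_indices(15, 1)]
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_matrix_invariants(self, small_run):
        res = small_run.consensus
        for k in res.ks:
            m = res.consensus[k]
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_allclose(np.diag(m), 1.0)
            assert m.min() >= 0.0 and m.max() <= 1.0
            assert 0.0 <= res.aucs[k] <= 1.0

    def test_permutation_equivariance(self):
        x, ids = _two_clouds(n_per=8, seed=4)
        res = consensus_cluster(x, ids, k_range=[2, 3], n_iterations=60, seed=5)
        perm = np.random.default_rng(0).permutation(len(ids))
        res_p = consensus_cluster(
            x[perm], [ids[i] for i in perm], k_range=[2, 3], n_iterations=60, seed=5
        )
        # same data relabelled: consensus is equivariant up to resampling noise,
        # and exactly equivariant in the separated-cloud geometry
        m = res.consensus[2][np.ix_(perm, perm)]
        np.testing.assert_allclose(m, res_p.consensus[2])

    def test_k_not_below_subsample_rejected(self):
        x, ids = _two_clouds(n_per=4)
        with pytest.raises(ValueError, match="subsample"):
            consensus_cluster(x, ids, k_range=[7], subsample_frac=0.8,
                              n_iterations=5, seed=0)


class TestAucCdf:
    def test_all_zero_entries_full_area(self):
        m = np.eye(6)
        assert auc_cdf(m) == pytest.approx(1.0)

    def test_all_one_entries_zero_area(self):
        m = np.ones((6, 6))
        assert auc_cdf(m) == pytest.approx(0.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (10,), elements=st.floats(0.0, 1.0)))
    def test_area_always_in_unit_interval(self, vals):
        n = 5
        m = np.eye(n)
        iu = np.triu_indices(n, 1)
        m[iu] = vals
        m.T[iu] = vals
        assert 0.0 <= auc_cdf(m) <= 1.0

    def test_uniform_entries_half_area(self):
        rng = np.random.default_rng(0)
        n = 80
        m = np.eye(n)
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0, 1, size=len(iu[0]))
        m[iu] = vals
        m.T[iu] = vals
        assert auc_cdf(m) == pytest.approx(0.5, abs=0.02)


class TestSelectK:
    def test_plateau_rule_example(self):
        res = _fake_result({2: 0.60, 3: 0.80, 4: 0.90, 5: 0.901, 6: 0.902})
        assert select_k(res) == 4

    def test_flat_aucs_select_smallest(self):
        res = _fake_result({2: 0.7, 3: 0.7, 4: 0.7})
        assert select_k(res) == 2

    def test_no_plateau_returns_max_with_warning(self, caplog):
        res = _fake_result({2: 0.1, 3: 0.2, 4: 0.4})
        with caplog.at_level("WARNING"):
            assert select_k(res) == 4
        assert "plateau" in caplog.text

    def test_single_k_rejected(self):
        res = _fake_result({2: 0.5})
        with pytest.raises(ValueError):
            select_k(res)


class TestCutClusters:
    def test_block_diagonal_matrix_cut_matches_blocks(self):
        n = 10
        m = np.zeros((n, n))
        m[:5, :5] = 1.0
        m[5:, 5:] = 1.0
        res = ConsensusResult(
            drug_ids=[f"d{i}" for i in range(n)], ks=[2], consensus={2: m},
            cosample_counts=np.full((n, n), 5), aucs={2: 0.5},
            n_iterations=5, subsample_frac=0.8, seed=0,
        )
        asg = cut_clusters(res, 2)
        labels = asg.labels.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_singleton_cluster_pattern_is_own_map(self):
        n = 5
        m = np.zeros((n, n))
        m[:4, :4] = 1.0
        np.fill_diagonal(m, 1.0)
        ids = [f"d{i}" for i in range(n)]
        maps = {d: np.full((3, 3), float(i)) for i, d in enumerate(ids)}
        res = ConsensusResult(
            drug_ids=ids, ks=[2], consensus={2: m},
            cosample_counts=np.full((n, n), 5), aucs={2: 0.5},
            n_iterations=5, subsample_frac=0.8, seed=0,
        )
        asg = cut_clusters(res, 2, tscore_maps=maps)
        singleton_cluster = asg.labels["d4"]
        np.testing.assert_array_equal(asg.patterns[singleton_cluster], maps["d4"])


class TestPlantedRecovery:
    def test_noise_free_select_k_matches_planted(self):
        # oracle equivalence on small noise-free instances, deterministic
        # clustering via subsample_frac = 1
        # cluster sizes must be large enough that splitting one cluster of
        # identical points moves < 1% of pairs (the plateau rule's granularity)
        for k_true, n_train in ((3, 90), (5, 100), (10, 150)):
            cfg = ScenarioConfig(
                n_train_drugs=n_train, n_test_drugs=2, n_clusters=k_true,
                grid_h=24, grid_w=16, within_cluster_sd=0.0, replicate_sd=0.0,
                seed=k_true,
            )
            lib, truth, _ = simulate_bam_library(cfg)
            train = [d for d, m in truth.membership.items() if m == "training"]
            tpl = make_default_template(cfg.grid_h, cfg.grid_w)
            maps = np.stack([compute_tscore_bam(lib.bams[d]) for d in train])
            model = fit_pca(maps, tpl.mask, min(20, len(train) - 1))
            pp = project_library(maps, model)
            res = consensus_cluster(
                pp, train, k_range=range(2, min(16, len(train) - 1)),
                n_iterations=10, subsample_frac=1.0, seed=0,
            )
            assert select_k(res) == k_true
            asg = cut_clusters(res, k_true)
            planted = [truth.true_cluster[d] for d in train]
            assert adjusted_rand_score(planted, asg.labels.loc[train]) == 1.0

    def test_default_noise_recovery_high_ari(self, default_run):
        planted = [
            default_run.truth.true_cluster[d] for d in default_run.assignment.labels.index
        ]
        ari = adjusted_rand_score(planted, default_run.assignment.labels)
        assert ari >= 0.9

    def test_ari_degrades_monotonically_with_replicate_noise(self):
        # 5-point noise ladder; ARI non-increasing within 0.05 tolerance
        aris = []
        for rep_sd in (0.0, 2.0, 4.0, 8.0, 16.0):
            cfg = ScenarioConfig(
                n_train_drugs=40, n_test_drugs=2, n_clusters=4, grid_h=24,
                grid_w=16, replicate_sd=rep_sd, seed=9,
            )
            lib, truth, _ = simulate_bam_library(cfg)
            train = [d for d, m in truth.membership.items() if m == "training"]
            tpl = make_default_template(cfg.grid_h, cfg.grid_w)
            maps = np.stack([compute_tscore_bam(lib.bams[d]) for d in train])
            model = fit_pca(maps, tpl.mask, 20)
            pp = project_library(maps, model)
            res = consensus_cluster(pp, train, k_range=[4], n_iterations=100, seed=2)
            asg = cut_clusters(res, 4)
            planted = [truth.true_cluster[d] for d in train]
            aris.append(adjusted_rand_score(planted, asg.labels.loc[train]))
        assert all(b <= a + 0.05 for a, b in zip(aris, aris[1:]))


class TestCoherence:
    def test_perfect_separation_is_overwhelming(self):
        # in-cluster consensus all 1, out all 0, sizes 17 vs 161
        n = 179
        m = np.zeros((n, n))
        m[:18, :18] = 1.0
        np.fill_diagonal(m, 1.0)
        ids = [f"d{i}" for i in range(n)]
        labels = pd.Series([1] * 18 + [2] * (n - 18), index=ids, name="cluster")
        res = ConsensusResult(
            drug_ids=ids, ks=[2], consensus={2: m},
            cosample_counts=np.full((n, n), 5), aucs={2: 0.5},
            n_iterations=5, subsample_frac=0.8, seed=0,
        )
        asg = ClusterAssignment(labels=labels, k=2)
        df = coherence_tests(res, asg)
        assert df.loc["d0", "q_consensus"] < 1e-5
        # cross-check one drug against a direct rank-sum computation
        direct = mannwhitneyu(
            m[0, 1:18], m[0, 18:], alternative="greater", method="asymptotic"
        ).pvalue
        assert df.loc["d0", "p_consensus"] == pytest.approx(direct)

    def test_singleton_cluster_reported_missing(self):
        n = 6
        m = np.eye(n)
        ids = [f"d{i}" for i in range(n)]
        labels = pd.Series([1, 1, 1, 2, 2, 3], index=ids, name="cluster")
        res = ConsensusResult(
            drug_ids=ids, ks=[3], consensus={3: m},
            cosample_counts=np.full((n, n), 5), aucs={3: 0.5},
            n_iterations=5, subsample_frac=0.8, seed=0,
        )
        df = coherence_tests(res, ClusterAssignment(labels=labels, k=3))
        assert np.isnan(df.loc["d5", "p_consensus"])
        assert df["p_consensus"].notna().sum() == 5

    def test_type_i_error_calibrated_under_random_labels(self):
        # distance-variant test on an unstructured cloud with random labels:
        # the fraction of raw p < 0.05 should match 0.05 within Monte-Carlo
        # error across seeds
        fractions = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(24, 5))
            ids = [f"d{i}" for i in range(24)]
            labels = pd.Series(rng.permutation([1] * 12 + [2] * 12), index=ids)
            m = np.eye(24)  # consensus unused by the distance variant
            res = ConsensusResult(
                drug_ids=ids, ks=[2], consensus={2: m},
                cosample_counts=np.full((24, 24), 5), aucs={2: 0.5},
                n_iterations=5, subsample_frac=0.8, seed=0,
            )
            df = coherence_tests(res, ClusterAssignment(labels=labels, k=2), phenoprints=x)
            fractions.append((df["p_distance"] < 0.05).mean())
        se = np.std(fractions) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - 0.05) <= max(2 * se, 0.01)
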