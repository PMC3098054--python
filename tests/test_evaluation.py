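import numpy as np
import pytest

from mgclust import (
    POCSConfig,
    ProjectorConfig,
    ReferenceClustering,
    SoftClustering,
    crossval_go,
    estimate_pwk,
    gene_go_similarity_matrix,
    gll,
    nmi,
    read_reference_clusters,
)


def make_ref(memberships, cluster_names=None):
    """memberships: list per gene of cluster-index lists."""
    W = max(max(m) for m in memberships) + 1
    if cluster_names is None:
        cluster_names = [f"c{w}" for w in range(W)]
    Y = np.zeros((len(memberships), len(cluster_names)), dtype=bool)
    for i, ms in enumerate(memberships):
        Y[i, ms] = True
    return ReferenceClustering([f"g{i}" for i in range(len(memberships))], cluster_names, Y)


def make_soft(rows, gene_ids=None):
    rows = np.asarray(rows, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(rows.shape[0])]
    return SoftClustering(gene_ids, rows)


class TestReadReferenceClusters:
    def test_multi_membership_and_universe_restriction(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("gA\tamino\ngA\tenergy\ngB\tamino\ngZ\tenergy\n")
        ref = read_reference_clusters(path, ["gA", "gB", "gC"])
        assert ref.gene_ids == ["gA", "gB"]  # gZ outside universe, gC unlisted
        assert ref.cluster_names == ["amino", "energy"]
        assert ref.Y[0].sum() == 2 and ref.Y[1].sum() == 1
        assert ref.n_w.tolist() == [2, 1]

    def test_cluster_count_matches_table(self, tmp_path):
        lines = [f"g{i}\tcluster{i % 10}" for i in range(50)]
        path = tmp_path / "ref.tsv"
        path.write_text("\n".join(lines) + "\n")
        ref = read_reference_clusters(path, [f"g{i}" for i in range(50)])
        assert len(ref.cluster_names) == 10

    def test_empty_intersection_is_hard_error(self, tmp_path):
        path = tmp_path / "ref.tsv"
        path.write_text("gX\tamino\n")
        with pytest.raises(ValueError, match="universe"):
            read_reference_clusters(path, ["gA"])


class TestEstimatePwk:
    def test_one_hot_members_give_one_hot_distribution(self):
        x = make_soft([[1, 0], [1, 0], [0, 1]])
        ref = make_ref([[0], [0], [1]])
        P = estimate_pwk(x, ref).P
        assert np.allclose(P[0], [1, 0], atol=1e-9)
        assert np.allclose(P[1], [0, 1], atol=1e-9)

    def test_uniform_members_give_uniform_distribution(self):
        x = make_soft(np.full((4, 3), 1 / 3))
        ref = make_ref([[0], [0], [1], [1]])
        assert np.allclose(estimate_pwk(x, ref).P, 1 / 3)

    def test_product_rule_hand_example(self):
        x = make_soft([[0.8, 0.2], [0.6, 0.4]])
        ref = ReferenceClustering(
            ["g0", "g1"], ["w", "z"], np.array([[True, True], [True, True]])
        )
        P = estimate_pwk(x, ref).P
        # p_w ∝ (0.8*0.6, 0.2*0.4) = (0.48, 0.08) -> (6/7, 1/7)
        assert np.allclose(P[0], [0.857142857142857, 0.142857142857143], atol=1e-9)

    def test_mean_rule_variant(self):
        x = make_soft([[0.8, 0.2], [0.6, 0.4]])
        ref = ReferenceClustering(
            ["g0", "g1"], ["w", "z"], np.array([[True, True], [True, True]])
        )
        P = estimate_pwk(x, ref, method="mean").P
        assert np.allclose(P[0], [0.7, 0.3], atol=1e-9)

    def test_empty_reference_cluster_is_error(self):
        x = make_soft([[0.5, 0.5], [0.5, 0.5]])
        ref = ReferenceClustering(
            ["g0", "g1"], ["w", "z"], np.array([[True, False], [True, False]])
        )
        with pytest.raises(ValueError, match="no member"):
            estimate_pwk(x, ref)


class TestGll:
    def test_perfect_one_hot_solution_scores_zero(self):
        x = make_soft(np.eye(3))
        ref = make_ref([[0], [1], [2]])
        # the 1e-12 floor inside estimate_pwk leaves a vanishing residual
        assert gll(x, ref) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_solution_closed_form(self):
        K = 4
        x = make_soft(np.full((6, K), 1 / K))
        ref = make_ref([[0], [0, 1], [1], [2], [2], [0]])
        n_memberships = ref.Y.sum()
        assert gll(x, ref) == pytest.approx(n_memberships * np.log(1 / K), abs=1e-9)

    def test_matches_brute_force_evaluation(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            I, K, W = 10, 3, 4
            x = make_soft(rng.dirichlet(np.ones(K), size=I))
            members = [rng.choice(I, size=rng.integers(1, 4), replace=False) for _ in range(W)]
            Y = np.zeros((I, W), dtype=bool)
            for w, ms in enumerate(members):
                Y[ms, w] = True
            keep = Y.sum(axis=1) > 0
            Y[~keep, 0] = True  # every gene needs >= 1 membership
            ref = ReferenceClustering(x.gene_ids, [f"w{w}" for w in range(W)], Y)
            # independent direct evaluation: p_wk by explicit product loops
            P = np.ones((W, K))
            for w in range(W):
                for i in np.where(Y[:, w])[0]:
                    P[w] *= np.maximum(x.X[i], 1e-12)
                P[w] /= P[w].sum()
            expected = 0.0
            for w in range(W):
                for i in np.where(Y[:, w])[0]:
                    expected += np.log(np.dot(P[w], x.X[i]))
            assert gll(x, ref) == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_and_permutation_invariant(self):
        rng = np.random.default_rng(8)
        x = make_soft(rng.dirichlet(np.ones(4), size=12))
        ref = make_ref([[i % 3] for i in range(12)])
        value = gll(x, ref)
        assert value <= 0.0
        perm = rng.permutation(4)
        xp = make_soft(x.X[:, perm])
        assert gll(xp, ref) == pytest.approx(value, abs=1e-9)

    def test_per_membership_average(self):
        K = 2
        x = make_soft(np.full((4, K), 0.5))
        ref = make_ref([[0], [0], [1], [1]])
        assert gll(x, ref, per_membership=True) == pytest.approx(np.log(0.5), abs=1e-9)


class TestNmi:
    def test_identical_partitions_give_one(self):
        ref = make_ref([[0], [0], [1], [1], [2]])
        labels = [0, 0, 1, 1, 2]
        assert nmi(labels, ref) == 1.0

    def test_single_predicted_cluster_gives_zero(self):
        ref = make_ref([[0], [1], [0], [1]])
        assert nmi([0, 0, 0, 0], ref) == 0.0

    def test_contingency_oracle(self):
        # contingency [[5,0],[1,4]] on 10 single-membership genes
        ref = make_ref([[0]] * 5 + [[1]] * 5)
        labels = [0] * 5 + [0] + [1] * 4
        n = np.array([[5, 0], [1, 4]], dtype=float)
        N = n.sum()
        pw, pk = n.sum(1) / N, n.sum(0) / N
        mi = sum(
            n[w, k] / N * np.log(n[w, k] * N / (n.sum(1)[w] * n.sum(0)[k]))
            for w in range(2)
            for k in range(2)
            if n[w, k] > 0
        )
        hw = -np.sum(pw * np.log(pw))
        hk = -np.sum(pk * np.log(pk))
        assert nmi(labels, ref) == pytest.approx(mi / np.sqrt(hw * hk), abs=1e-12)

    def test_agrees_with_sklearn_on_single_membership(self):
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(4)
        for _ in range(10):
            true = rng.integers(0, 4, size=30)
            pred = rng.integers(0, 3, size=30)
            ref = make_ref([[int(t)] for t in true])
            expected = normalized_mutual_info_score(true, pred, average_method="geometric")
            assert nmi(pred, ref) == pytest.approx(expected, abs=1e-9)

    def test_multi_membership_counts_one_unit_per_pair(self):
        ref = make_ref([[0, 1], [0], [1]])
        # gene 0 contributes a count to both reference rows
        value = nmi([0, 0, 1], ref)
        assert 0.0 <= value <= 1.0
        # equivalent expanded single-membership problem
        expanded = make_ref([[0], [1], [0], [1]])
        assert nmi([0, 0, 0, 1], expanded) == pytest.approx(value, abs=1e-12)

    def test_sum_normalization_variant(self):
        ref = make_ref([[0]] * 5 + [[1]] * 5)
        labels = [0] * 5 + [1] * 5
        assert nmi(labels, ref, normalization="sum") == 1.0
        labels2 = [0] * 6 + [1] * 4
        assert nmi(labels2, ref, normalization="sum") != nmi(labels2, ref)


class TestCrossvalGo:
    @pytest.fixture()
    def inputs(self, small_dataset):
        d = small_dataset
        cfg = POCSConfig(k_clusters=4, m_projections=2, weights=(0.8, 0.2))
        pcfg = ProjectorConfig(j_iterations=3, n_neighbors=6)
        return d, cfg, pcfg

    def test_folds_partition_genes_exactly(self, inputs):
        d, cfg, pcfg = inputs
        res = crossval_go(d["expr"], d["graph"], d["ann"], d["ref"], cfg, pcfg, seed=3)
        sizes = [rec["n_heldout"] for rec in res.folds]
        assert sum(sizes) == d["expr"].n_genes
        assert max(sizes) - min(sizes) <= 1
        assert len(res.folds) == 5

    def test_deterministic_under_fixed_seed(self, inputs):
        d, cfg, pcfg = inputs
        r1 = crossval_go(d["expr"], d["graph"], d["ann"], d["ref"], cfg, pcfg, seed=3)
        r2 = crossval_go(d["expr"], d["graph"], d["ann"], d["ref"], cfg, pcfg, seed=3)
        assert r1.folds == r2.folds
        assert r1.summary == r2.summary

    def test_deleted_annotations_mask_exactly_heldout_go_rows(self, small_dataset):
        d = small_dataset
        held = d["expr"].gene_ids[:8]
        ann_f = d["ann"].without_genes(held)
        sim = gene_go_similarity_matrix(d["graph"], ann_f, d["expr"].gene_ids)
        for i, g in enumerate(d["expr"].gene_ids):
            if g in held:
                assert not sim.mask[i].any()
            else:
                assert sim.mask[i, i]

    def test_summary_matches_folds(self, inputs):
        d, cfg, pcfg = inputs
        res = crossval_go(d["expr"], d["graph"], d["ann"], d["ref"], cfg, pcfg, seed=1)
        nmis = [rec["nmi"] for rec in res.folds]
        assert res.summary["nmi_mean"] == pytest.approx(np.mean(nmis))
        assert res.summary["nmi_sd"] == pytest.approx(np.std(nmis, ddof=1))

    def test_fold_without_evaluable_genes_is_error(self, small_dataset):
        d = small_dataset
        # a reference covering a single gene cannot populate every fold
        tiny = ReferenceClustering(
            d["expr"].gene_ids[:2],
            ["a", "b"],
            np.array([[True, False], [False, True]]),
        )
        cfg = POCSConfig(k_clusters=3, m_projections=1, weights=(0.8, 0.2))
        with pytest.raises(ValueError, match="fold"):
            crossval_go(
                d["expr"], d["graph"], d["ann"], tiny, cfg,
                ProjectorConfig(j_iterations=1, n_neighbors=5), seed=0,
            )
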