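import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score, silhouette_score

from crossatlas.atlas import (
    AtlasParams,
    ClusterAssignment,
    Embedding,
    NormalizedMatrix,
    choose_pcs,
    cluster_louvain,
    embed_pca,
    knn_graph,
    normalize,
    run_atlas,
    select_hvg,
    umap_embed,
)
from crossatlas.io_formats import CountMatrix


def _cm(arr):
    arr = np.asarray(arr)
    return CountMatrix(
        sp.csc_matrix(arr),
        [f"g{i}" for i in range(arr.shape[0])],
        [f"c{i}" for i in range(arr.shape[1])],
    )


def _nm(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(
        values, gene_ids, [f"c{i}" for i in range(values.shape[1])]
    )


class TestNormalize:
    def test_depth_scaling_formula(self):
        cm = _cm([[10], [0], [10]])
        nm = normalize(cm, scale_factor=10_000)
        expected = [np.log1p(5000), 0.0, np.log1p(5000)]
        np.testing.assert_allclose(np.asarray(nm.dense())[:, 0], expected)

    def test_zero_total_cells_become_zero_with_warning(self):
        cm = _cm([[0, 3], [0, 1]])
        with pytest.warns(UserWarning, match="zero total"):
            nm = normalize(cm)
        assert np.all(nm.dense()[:, 0] == 0)

    def test_collinear_covariate_leaves_gene_at_its_mean(self):
        cm = _cm([[1, 2, 3, 4], [5, 5, 5, 5]])
        nm_plain = normalize(cm)
        cov = nm_plain.dense()[0]  # covariate == gene 0's values
        nm = normalize(cm, covariates=cov)
        vals = nm.dense()
        np.testing.assert_allclose(
            vals[0], np.full(4, nm_plain.dense()[0].mean()), atol=1e-10
        )
        assert nm.provenance["regressed_covariates"]

    def test_shape_and_ids_preserved(self, toy_counts):
        nm = normalize(toy_counts)
        assert nm.gene_ids == toy_counts.gene_ids
        assert nm.values.shape == toy_counts.counts.shape


class TestSelectHvg:
    def test_planted_high_variance_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(1.0, 0.05, (30, 100))
        planted = np.where(rng.random(100) < 0.5, 3.0, 0.2)
        values = np.vstack([flat, planted])
        nm = _nm(values)
        assert select_hvg(nm, 1) == ["g30"]

    def test_constant_matrix_warns_and_falls_back_to_lexicographic(self):
        nm = _nm(np.ones((4, 5)), gene_ids=["d", "b", "a", "c"])
        with pytest.warns(UserWarning, match="no informative"):
            got = select_hvg(nm, 3)
        assert got == ["a", "b", "c"]

    def test_n_top_all_is_permutation(self):
        rng = np.random.default_rng(1)
        nm = _nm(rng.random((10, 20)))
        with pytest.warns(UserWarning, match="exceeds"):
            got = select_hvg(nm, 50)
        assert sorted(got) == sorted(nm.gene_ids)


class TestEmbedPca:
    def test_rank_one_data_has_zero_trailing_sds(self):
        t = np.linspace(0, 1, 20)
        values = np.outer([1.0, 2.0, -1.0], t)  # 3 genes on one line
        emb = embed_pca(_nm(values), n_components=3)
        assert emb.sds[1] == pytest.approx(0.0, abs=1e-8)

    def test_pc1_separates_two_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (10, 25))
        b = rng.normal(3, 0.1, (10, 25))
        values = np.hstack([a, b])
        emb = embed_pca(_nm(values), n_components=2)
        labels = [0] * 25 + [1] * 25
        assert silhouette_score(emb.coords[:, :1], labels) > 0.5

    def test_repeat_call_is_identical_including_signs(self, small_pair):
        nm = normalize(small_pair[0])
        genes = select_hvg(nm, 200)
        e1 = embed_pca(nm, genes, n_components=10)
        e2 = embed_pca(nm, genes, n_components=10)
        np.testing.assert_array_equal(e1.coords, e2.coords)

    def test_excess_components_truncated_with_warning(self):
        nm = _nm(np.random.default_rng(2).random((3, 4)))
        with pytest.warns(UserWarning, match="truncating"):
            emb = embed_pca(nm, n_components=10)
        assert emb.coords.shape[1] <= 3


def _choose_pcs_oracle(sds, frac_thr=0.05, drop_thr=0.001):
    """Literal scan of the elbow rule, independent of the implementation."""
    sds = np.asarray(sds, dtype=float)
    total = sds.sum()
    frac = sds / total
    drops = [frac[j] - frac[j + 1] for j in range(len(sds) - 1)]
    for i in range(1, len(sds)):
        if (
            frac[i] < frac_thr
            and all(d < drop_thr for d in drops[i - 1:])
            and sds[i] < sds[0]
        ):
            return i
    return len(sds)


class TestChoosePcs:
    def test_matches_brute_force_scan_on_elbow_spectrum(self):
        sds = np.array([10.0, 5.0, 1.0, 0.1, 0.1, 0.1, 0.1])
        assert choose_pcs(sds) == _choose_pcs_oracle(sds)

    def test_matches_scan_on_random_decreasing_spectra(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sds = np.sort(rng.exponential(1.0, 30))[::-1]
            assert choose_pcs(sds) == _choose_pcs_oracle(sds)

    def test_flat_spectrum_has_no_elbow(self):
        assert choose_pcs(np.ones(40)) == 40

    def test_override_wins(self):
        assert choose_pcs(np.array([3.0, 2.0, 1.0]), override=20) == 20

    def test_short_spectrum_returned_whole(self):
        assert choose_pcs(np.array([1.0])) == 1


class TestKnnGraph:
    @staticmethod
    def _emb(coords):
        coords = np.asarray(coords, dtype=float)
        sds = np.zeros(coords.shape[1])
        return Embedding(coords, sds, [f"c{i}" for i in range(len(coords))])

    def test_three_equidistant_points_form_triangle(self):
        coords = [[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]
        g = knn_graph(self._emb(coords), k=2)
        assert g.ecount() == 3
        assert all(w == pytest.approx(1.0) for w in g.es["weight"])

    def test_far_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(0, 1, (25, 3))
        blob2 = rng.normal(100, 1, (25, 3))
        g = knn_graph(self._emb(np.vstack([blob1, blob2])), k=20)
        for e in g.es:
            assert (e.source < 25) == (e.target < 25)

    def test_k_not_smaller_than_n_rejected(self):
        with pytest.raises(ValueError):
            knn_graph(self._emb([[0, 0], [1, 1]]), k=2)


class TestClusterLouvain:
    def test_two_disconnected_cliques(self):
        import igraph

        g = igraph.Graph.Full(5) + igraph.Graph.Full(5)
        g.es["weight"] = 1.0
        cl = cluster_louvain(g, resolution=1.0, seed=0)
        assert cl.n_clusters == 2
        assert len(set(cl.labels[:5])) == 1 and len(set(cl.labels[5:])) == 1

    def test_tiny_resolution_merges_connected_graph(self):
        import igraph

        g = igraph.Graph.Lattice([20], circular=True)
        g.es["weight"] = 1.0
        cl = cluster_louvain(g, resolution=0.01, seed=0)
        assert cl.n_clusters == 1

    def test_labels_ordered_by_decreasing_size(self):
        import igraph

        g = igraph.Graph.Full(3) + igraph.Graph.Full(7)
        g.es["weight"] = 1.0
        cl = cluster_louvain(g, resolution=1.0, seed=0)
        assert (cl.labels[3:] == 0).all()

    def test_empty_graph_rejected(self):
        import igraph

        with pytest.raises(ValueError):
            cluster_louvain(igraph.Graph(), seed=0)

    def test_fixed_seed_reproducible(self, small_pair):
        res1 = run_atlas(small_pair[0], AtlasParams(n_hvg=300, seed=4))
        res2 = run_atlas(small_pair[0], AtlasParams(n_hvg=300, seed=4))
        np.testing.assert_array_equal(res1.clusters.labels, res2.clusters.labels)


class TestTypeRecovery:
    def test_clusters_recover_planted_types(self, small_pair):
        cm = small_pair[0]
        res = run_atlas(cm, AtlasParams(n_hvg=500, seed=0))
        ari = adjusted_rand_score(cm.cell_meta["cell_type"], res.clusters.labels)
        assert ari >= 0.8


class TestUmap:
    def test_determinism_separation_and_min_size(self):
        rng = np.random.default_rng(0)
        coords = np.vstack(
            [rng.normal(0, 0.3, (15, 5)), rng.normal(5, 0.3, (15, 5))]
        )
        emb = Embedding(coords, np.zeros(5), [f"c{i}" for i in range(30)])
        u1 = umap_embed(emb, seed=1)
        u2 = umap_embed(emb, seed=1)
        np.testing.assert_array_equal(u1, u2)
        c1, c2 = u1[:15].mean(axis=0), u1[15:].mean(axis=0)
        spread = max(u1[:15].std(), u1[15:].std())
        assert np.linalg.norm(c1 - c2) > spread
        tiny = Embedding(coords[:2], np.zeros(5), ["a", "b"])
        with pytest.raises(ValueError):
            umap_embed(tiny, seed=1)
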