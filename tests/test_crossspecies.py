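import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from crossatlas.atlas import NormalizedMatrix, normalize
from crossatlas.crossspecies import (
    composition_matrix,
    hypergeom_pvalue,
    integrate_datasets,
    marker_overlap,
    representation_factor,
    restrict_to_one2one,
)
from crossatlas.io_formats import CountMatrix, OrthologTable
from crossatlas.markers import MARKER_COLUMNS, MarkerTable


def _cm(arr, gene_ids, species=""):
    arr = np.asarray(arr)
    return CountMatrix(
        sp.csc_matrix(arr), gene_ids,
        [f"{species}{i}" for i in range(arr.shape[1])], species=species,
    )


def _ortho(rows):
    return OrthologTable(
        pd.DataFrame(rows, columns=["gene_A", "gene_B", "relation"])
    )


class TestRestrictToOne2One:
    def test_rule_enumeration(self):
        # a1/b1 expressed in both; b2 expressed in one cell only; a3/b3 1:many
        cm_a = _cm([[1, 2], [3, 1], [1, 1]], ["a1", "a2", "a3"], "A")
        cm_b = _cm([[2, 2], [5, 0], [1, 1]], ["b1", "b2", "b3"], "B")
        ot = _ortho(
            [("a1", "b1", "one2one"), ("a2", "b2", "one2one"),
             ("a3", "b3", "one2many")]
        )
        shared = restrict_to_one2one(cm_a, cm_b, ot, min_cells=2)
        assert shared.pairs.values.tolist() == [["a1", "b1"]]
        assert shared.cm_a.gene_ids == ["b1"]  # converted to unified ids
        assert shared.report["n_retained"] == 1

    def test_min_cells_zero_keeps_all_one2one(self):
        cm_a = _cm([[0, 0], [1, 0]], ["a1", "a2"], "A")
        cm_b = _cm([[0, 0], [0, 0]], ["b1", "b2"], "B")
        ot = _ortho([("a1", "b1", "one2one"), ("a2", "b2", "one2one")])
        shared = restrict_to_one2one(cm_a, cm_b, ot, min_cells=0)
        assert shared.n_genes == 2

    def test_disjoint_universes_rejected(self):
        cm_a = _cm([[1, 1]], ["x1"], "A")
        cm_b = _cm([[1, 1]], ["y1"], "B")
        ot = _ortho([("a1", "b1", "one2one")])
        with pytest.raises(ValueError):
            restrict_to_one2one(cm_a, cm_b, ot)


class TestRepresentationFactor:
    def test_expected_overlap_gives_unity(self):
        assert representation_factor(1, 4, 5, 20) == pytest.approx(1.0)

    def test_within_species_universe_example(self):
        assert representation_factor(13, 60, 120, 27818) == pytest.approx(
            50.23, abs=0.01
        )

    def test_zero_overlap(self):
        assert representation_factor(0, 5, 5, 50) == 0.0

    @pytest.mark.parametrize(
        "args", [(1, 30, 5, 20), (0, 0, 5, 20), (6, 5, 10, 20)]
    )
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            representation_factor(*args)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_identity_and_symmetry(self, data):
        N = data.draw(st.integers(2, 500))
        n1 = data.draw(st.integers(1, N))
        n2 = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n1, n2)))
        rf = representation_factor(k, n1, n2, N)
        assert rf * (n1 * n2 / N) == pytest.approx(k)
        assert rf == pytest.approx(representation_factor(k, n2, n1, N))


def enumerate_overlap_tail(k, n1, n2, N):
    """P(|S ∩ T| >= k) by enumerating every n2-subset T of an N-universe."""
    fixed = set(range(n1))
    hits = total = 0
    for subset in itertools.combinations(range(N), n2):
        total += 1
        if len(fixed.intersection(subset)) >= k:
            hits += 1
    return hits / total


class TestHypergeomPvalue:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_pvalue(0, 3, 3, 10) == 1.0

    def test_hand_enumerated_example(self):
        # C(3,2)C(7,1) + C(3,3)C(7,0) over C(10,3) = 22/120
        assert hypergeom_pvalue(2, 3, 3, 10) == pytest.approx(22 / 120)

    def test_full_universe_sets_force_overlap(self):
        for k in range(0, 8):
            assert hypergeom_pvalue(k, 7, 7, 7) == 1.0

    def test_matches_subset_enumeration_small_universe(self):
        for N in (5, 7, 8):
            for n1 in (1, N // 2, N):
                for n2 in (1, N // 2, N):
                    for k in range(0, min(n1, n2) + 1):
                        assert hypergeom_pvalue(k, n1, n2, N) == pytest.approx(
                            enumerate_overlap_tail(k, n1, n2, N), rel=1e-9
                        )

    def test_stable_at_extreme_significance(self):
        # magnitudes like the reported p < 2.921e-19 must not underflow
        p = hypergeom_pvalue(13, 25, 30, 27818)
        assert 0 < p < 1e-18


class TestCompositionMatrix:
    def test_sample_size_weighting_formula(self):
        # species A total 100 cells, B total 200; one cluster of 10 A + 10 B
        labels = np.r_[np.zeros(10), np.ones(90), np.zeros(10), np.ones(190)]
        species = np.r_[["A"] * 100, ["B"] * 200]
        comp = composition_matrix(labels, species, species)
        assert comp.normalized.loc[0.0, "A"] == pytest.approx(2 / 3)

    def test_single_species_fractions_are_one(self):
        labels = np.array([0, 0, 1, 1, 1])
        species = np.array(["A"] * 5)
        comp = composition_matrix(labels, species, species)
        assert (comp.normalized["A"] == 1.0).all()

    def test_origin_direction_partitions_each_origin(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 200)
        origins = rng.choice(["t0", "t1", "t2"], 200)
        species = rng.choice(["A", "B"], 200)
        comp = composition_matrix(
            labels, origins, species, direction="of_origin_cluster"
        )
        np.testing.assert_allclose(comp.normalized.sum(axis=0), 1.0)

    def test_invariant_under_duplicating_one_species(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, 150)
        species = np.r_[["A"] * 50, ["B"] * 100]
        comp1 = composition_matrix(labels, species, species)
        dup_b = np.r_[labels, labels[50:]]
        dup_sp = np.r_[species, species[50:]]
        comp2 = composition_matrix(dup_b, dup_sp, dup_sp)
        pd.testing.assert_frame_equal(comp1.normalized, comp2.normalized)

    def test_unlabeled_cell_rejected(self):
        with pytest.raises(ValueError):
            composition_matrix(
                np.array([0, 1]), np.array(["A", None]), np.array(["A", "A"])
            )


def _marker_table(cluster_genes: dict[int, list[str]]) -> MarkerTable:
    rows = [
        (c, g, 1.0, 0.5, 0.1, 1e-8, 1e-5)
        for c, genes in cluster_genes.items()
        for g in genes
    ]
    return MarkerTable(pd.DataFrame(rows, columns=MARKER_COLUMNS))


def _toy_shared(n_genes=100):
    counts = np.ones((n_genes, 3), dtype=int)
    a_ids = [f"a{i}" for i in range(n_genes)]
    b_ids = [f"b{i}" for i in range(n_genes)]
    ot = _ortho([(a, b, "one2one") for a, b in zip(a_ids, b_ids)])
    return restrict_to_one2one(_cm(counts, a_ids, "A"), _cm(counts, b_ids, "B"), ot)


class TestMarkerOverlap:
    def test_three_by_three_overlap_example(self):
        shared = _toy_shared(100)
        mt_a = _marker_table({0: ["a1", "a2", "a3"]})
        mt_b = _marker_table({0: ["b2", "b3", "b4"]})
        res = marker_overlap(mt_a, [0], mt_b, [0], shared)
        assert (res.k, res.n1, res.n2, res.N) == (2, 3, 3, 100)
        assert res.rf == pytest.approx(2 / (3 * 3 / 100))
        # oracle: P(overlap >= 2) for 3-vs-3 sets in a 100-gene universe
        expected_p = (
            math.comb(3, 2) * math.comb(97, 1) + math.comb(3, 3)
        ) / math.comb(100, 3)
        assert res.p == pytest.approx(expected_p, rel=1e-9)
        assert res.shared_genes == ["b2", "b3"]

    def test_disjoint_sets(self):
        shared = _toy_shared(50)
        res = marker_overlap(
            _marker_table({0: ["a1"]}), [0],
            _marker_table({0: ["b2"]}), [0], shared,
        )
        assert (res.k, res.rf, res.p) == (0, 0.0, 1.0)

    def test_pooling_unions_marker_sets(self):
        shared = _toy_shared(50)
        mt_a = _marker_table({0: ["a1", "a2"], 1: ["a2", "a3"]})
        mt_b = _marker_table({0: ["b1", "b2", "b3"]})
        res = marker_overlap(mt_a, [0, 1], mt_b, [0], shared)
        assert res.n1 == 3 and res.k == 3

    def test_empty_restriction_warns(self):
        shared = _toy_shared(10)
        with pytest.warns(UserWarning, match="empty"):
            res = marker_overlap(
                _marker_table({0: ["unknown"]}), [0],
                _marker_table({0: ["b1"]}), [0], shared,
            )
        assert res.k == 0

    def test_within_species_universe_override(self):
        shared = _toy_shared(10)
        res = marker_overlap(
            _marker_table({0: ["a1"]}), [0],
            _marker_table({0: ["b1"]}), [0],
            shared, N_mode=27818,
        )
        assert res.N == 27818


@pytest.fixture(scope="module")
def mini_nm(small_pair):
    cm_a, cm_b, ot, truth = small_pair
    shared = restrict_to_one2one(cm_a, cm_b, ot)
    return shared, normalize(shared.cm_a), normalize(shared.cm_b)


class TestIntegration:
    def test_duplicated_dataset_is_symmetric(self, mini_nm):
        _, nm_a, _ = mini_nm
        twin = NormalizedMatrix(
            nm_a.values.copy(), list(nm_a.gene_ids),
            [f"dup-{b}" for b in nm_a.barcodes], dict(nm_a.provenance),
        )
        emb, cl, info = integrate_datasets([nm_a, twin], seed=0)
        species = np.r_[["A"] * nm_a.n_cells, ["B"] * nm_a.n_cells]
        comp = composition_matrix(cl, species, species)
        assert ((comp.normalized - 0.5).abs() <= 0.05).all().all()

    def test_constant_shift_removed_by_integration(self, mini_nm):
        from sklearn.metrics import adjusted_rand_score

        _, nm_a, nm_b = mini_nm
        shifted = NormalizedMatrix(
            np.asarray(nm_b.dense()) + 2.0, list(nm_b.gene_ids),
            list(nm_b.barcodes), dict(nm_b.provenance),
        )
        _, cl_plain, _ = integrate_datasets([nm_a, nm_b], seed=0)
        _, cl_shift, _ = integrate_datasets([nm_a, shifted], seed=0)
        assert adjusted_rand_score(cl_plain.labels, cl_shift.labels) >= 0.9

    def test_mismatched_gene_universe_rejected(self, mini_nm):
        _, nm_a, nm_b = mini_nm
        clipped = nm_b.subset_genes(nm_b.gene_ids[:-1])
        with pytest.raises(ValueError):
            integrate_datasets([nm_a, clipped], seed=0)
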