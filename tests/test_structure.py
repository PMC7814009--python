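"""Distances, neighbor joining, PCA, k-means aggregation."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalpop import structure as stx
from clonalpop import synthdata as sd
from clonalpop import variants as va


def matrix_from(dosage, groups=None):
    dosage = np.asarray(dosage)
    return va.GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(dosage.shape[0])],
        contigs=np.array(["c1"] * dosage.shape[1]),
        positions=np.arange(1, dosage.shape[1] + 1),
        dosage=dosage,
        groups=groups or {},
    )


dosage_matrices = st.integers(0, 2**32 - 1).map(
    lambda seed: np.random.default_rng(seed).integers(0, 4, size=(5, 20))
)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        dm = stx.pairwise_distance(matrix_from([[1, 2, 0], [1, 2, 0]]))
        assert dm.values[0, 1] == 0

    def test_manhattan_counts_allele_differences(self):
        dm = stx.pairwise_distance(matrix_from([[0, 0, 3], [0, 0, 0]]), "manhattan")
        assert dm.values[0, 1] == 3

    def test_missing_values_pairwise_complete(self):
        m = matrix_from([[1, va.MISSING, 3], [1, 2, 0]])
        dm = stx.pairwise_distance(m, "manhattan")
        assert dm.values[0, 1] == 3  # middle site dropped for the pair

    def test_single_sample_rejected(self):
        m = matrix_from([[1, 2, 3]])
        with pytest.raises(ValueError):
            stx.pairwise_distance(m)

    @given(dosage_matrices)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_manhattan_dominates_euclidean_and_axioms(self, dosage):
        m = matrix_from(dosage)
        man = stx.pairwise_distance(m, "manhattan").values
        euc = stx.pairwise_distance(m, "euclidean").values
        assert np.all(man >= euc - 1e-12)
        for d in (man, euc):
            assert np.allclose(d, d.T)
            assert np.all(np.diag(d) == 0)
            assert np.all(d >= 0)
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def tree_path_lengths(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    labels = {t.label: t for t in tree.taxon_namespace}
    out = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                out[i, j] = out[j, i] = pdm.distance(labels[a], labels[b])
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # additive matrix with split AB|CD: leaves A:2 B:1 C:1 D:2, internal 4
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 7, 8],
                [3, 0, 6, 7],
                [7, 6, 0, 3],
                [8, 7, 3, 0],
            ],
            dtype=float,
        )
        tree = stx.nj_tree(stx.DistanceMatrix(ids, d))
        assert np.allclose(tree_path_lengths(tree.newick, ids), d)
        dt = dendropy.Tree.get(data=tree.newick, schema="newick")
        splits = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in dt.preorder_edge_iter()
            if e.head_node is not dt.seed_node
        }
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_three_taxon_closed_form(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = stx.nj_tree(stx.DistanceMatrix(ids, d))
        # three-point equations: a=(dAB+dAC-dBC)/2 etc.
        assert tree.raw_branch_lengths["A"] == pytest.approx(3.0)
        assert tree.raw_branch_lengths["B"] == pytest.approx(2.0)
        assert tree.raw_branch_lengths["C"] == pytest.approx(6.0)
        assert np.allclose(tree_path_lengths(tree.newick, ids), d)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_additive_matrices_reproduced_exactly(self, seed):
        """NJ path lengths reproduce any random additive 5-6 taxon matrix."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 7))
        taxa = [f"T{i}" for i in range(n)]
        # random unrooted binary tree by sequential leaf attachment
        tree = dendropy.Tree()
        tns = dendropy.TaxonNamespace(taxa)
        tree.taxon_namespace = tns

        a = tree.seed_node.new_child(edge_length=float(rng.uniform(1, 5)))
        b = tree.seed_node.new_child(edge_length=float(rng.uniform(1, 5)))
        a.taxon, b.taxon = tns[0], tns[1]
        edges = [a.edge, b.edge]
        for k in range(2, n):
            edge = edges[int(rng.integers(0, len(edges)))]
            child = edge.head_node
            parent = edge.tail_node
            split = dendropy.Node(edge_length=float(rng.uniform(1, 5)))
            parent.remove_child(child)
            parent.add_child(split)
            child.edge.length = float(rng.uniform(1, 5))
            split.add_child(child)
            leaf = split.new_child(edge_length=float(rng.uniform(1, 5)))
            leaf.taxon = tns[k]
            edges.extend([split.edge, child.edge, leaf.edge])
        pdm = tree.phylogenetic_distance_matrix()
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.distance(tns[i], tns[j])
        nj = stx.nj_tree(stx.DistanceMatrix(taxa, d))
        assert np.allclose(tree_path_lengths(nj.newick, taxa), d, atol=1e-6)

    def test_two_population_clades_recovered(self, small_world):
        _, truth, _ = small_world
        dm = stx.pairwise_distance(truth, "manhattan")
        tree = stx.nj_tree(dm)
        dt = dendropy.Tree.get(
            data=tree.newick, schema="newick", preserve_underscores=True
        )
        splits = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in dt.preorder_edge_iter()
            if e.head_node is not dt.seed_node
        }
        pops = {}
        for sid, grp in truth.groups.items():
            pops.setdefault(grp, set()).add(sid)
        all_leaves = frozenset(truth.sample_ids)
        for members in pops.values():
            clade = frozenset(members)
            assert clade in splits or (all_leaves - clade) in splits

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            stx.DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]]))


class TestPca:
    def test_mirrored_clusters_separate_on_pc1(self):
        x = np.array([[3, 3, 0, 0], [3, 3, 0, 0], [0, 0, 3, 3], [0, 0, 3, 3]])
        res = stx.pca(matrix_from(x))
        signs = np.sign(res.scores[:, 0])
        assert signs[0] == signs[1] != signs[2] == signs[3]

    def test_variance_explained_sums_to_one(self, rng):
        x = rng.integers(0, 4, size=(6, 10))
        res = stx.pca(matrix_from(x))
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_reconstruction_at_full_rank(self, rng):
        x = rng.integers(0, 4, size=(5, 8)).astype(float)
        res = stx.pca(matrix_from(x.astype(int)))
        recon = res.scores @ res.loadings.T + res.means
        assert np.allclose(recon, x, atol=1e-9)

    def test_scores_orthogonal(self, rng):
        x = rng.integers(0, 4, size=(6, 12))
        res = stx.pca(matrix_from(x))
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0, atol=1e-8)

    def test_matches_sklearn_up_to_sign(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        x = rng.integers(0, 4, size=(7, 9)).astype(float)
        ours = stx.pca(matrix_from(x.astype(int)))
        theirs = SkPCA(n_components=4, svd_solver="full").fit(x)
        assert np.allclose(
            np.abs(ours.scores[:, :4]), np.abs(theirs.transform(x)), atol=1e-8
        )
        assert np.allclose(
            ours.variance_explained[:4], theirs.explained_variance_ratio_, atol=1e-9
        )

    def test_constant_matrix_warns_not_raises(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            res = stx.pca(matrix_from(np.ones((3, 4), dtype=int)))
        assert np.all(res.scores == 0)

    def test_geographic_groups_split_by_pc1_sign(self):
        # 10 + 5 samples with group-specific shared SNVs: PC1 sign = group
        spec = sd.PopulationSpec(
            n_populations=2, samples_per_population=(10, 5), n_sites=4000,
            private_snvs_per_population=200, private_snvs_per_sample=20,
            shared_snvs_all=100, reference_het_fraction=0.1, seed=21,
        )
        ref = sd.generate_reference_profile(4000, 0.1, seed=21)
        truth, _ = sd.generate_clonal_genotypes(spec, ref)
        res = stx.pca(truth)
        signs = np.sign(res.scores[:, 0])
        labels = np.array([truth.groups[s] for s in truth.sample_ids])
        assert len(set(signs[labels == "P1"])) == 1
        assert len(set(signs[labels == "P2"])) == 1
        assert signs[labels == "P1"][0] != signs[labels == "P2"][0]


class TestKmeansAggregate:
    def test_identity_when_k_equals_sites(self, rng):
        x = rng.integers(0, 4, size=(4, 6))
        centroids, order = stx.kmeans_row_aggregate(matrix_from(x), k=6, seed=0)
        assert np.array_equal(centroids, x.T.astype(float))

    def test_two_separated_groups_exact_means(self):
        sites = np.array([[0, 0], [0, 0], [0, 2], [3, 3], [3, 3], [3, 1]]).T
        m = matrix_from(sites)
        centroids, assign = stx.kmeans_row_aggregate(m, k=2, seed=0)
        expected = np.array([[0.0, 2 / 3], [3.0, 7 / 3]])
        got = centroids[np.argsort(centroids[:, 0])]
        assert np.allclose(got, expected)
        assert len(set(assign[:3])) == 1 and len(set(assign[3:])) == 1

    def test_k_larger_than_sites_rejected(self):
        with pytest.raises(ValueError):
            stx.kmeans_row_aggregate(matrix_from(np.zeros((3, 4), int)), k=5)

    def test_deterministic_given_seed(self, rng):
        x = rng.integers(0, 4, size=(5, 40))
        m = matrix_from(x)
        c1, a1 = stx.kmeans_row_aggregate(m, k=5, seed=3)
        c2, a2 = stx.kmeans_row_aggregate(m, k=5, seed=3)
        assert np.array_equal(c1, c2) and np.array_equal(a1, a2)
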