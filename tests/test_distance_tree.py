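"""Chord distances, NJ/UPGMA construction and Newick serialisation."""

import math

import dendropy
import numpy as np
import pytest

from germdiv import (
    Accession,
    DistanceMatrix,
    GenotypeMatrix,
    MAX_CHORD,
    chord_distance,
    distance_matrix,
    nj_tree,
    read_newick,
    read_phylip,
    upgma_tree,
    write_newick,
    write_phylip,
)
from germdiv.distance_tree import IncomparablePairError, tree_distance_matrix


def random_additive_tree(rng, n_leaves):
    """A random binary tree with exponential branch lengths and its exact
    leaf-to-leaf path-length matrix (the additive-distance oracle)."""
    taxa = [f"T{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            child.edge.length = float(rng.exponential(1.0) + 0.05)
            u.add_child(child)
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [u]
    root = dendropy.Node()
    for nd in nodes:
        nd.edge.length = float(rng.exponential(1.0) + 0.05)
        root.add_child(nd)
    tree.seed_node = root
    tree.is_rooted = False
    dm = tree_distance_matrix(tree, taxa)
    return tree, dm


class TestChordDistance:
    def test_identical_profiles_zero(self):
        g = np.array([[155, 155], [160, 162]])
        assert chord_distance(g, g) == 0.0

    def test_disjoint_homozygotes_maximum(self):
        g1 = np.array([[155, 155], [200, 200]])
        g2 = np.array([[161, 161], [204, 204]])
        assert chord_distance(g1, g2) == pytest.approx(MAX_CHORD)
        assert MAX_CHORD == pytest.approx(0.9003, abs=5e-5)

    def test_homozygote_vs_heterozygote_closed_form(self):
        # AA vs AB at one locus: sum sqrt(x*y) = sqrt(0.5)
        g1 = np.array([[155, 155]])
        g2 = np.array([[155, 161]])
        expected = (2 / math.pi) * math.sqrt(2 * (1 - math.sqrt(0.5)))
        assert chord_distance(g1, g2) == pytest.approx(expected)
        assert expected == pytest.approx(0.487, abs=5e-4)

    def test_scale_toggle(self):
        g1 = np.array([[155, 155]])
        g2 = np.array([[161, 161]])
        assert chord_distance(g1, g2, scale="none") == pytest.approx(math.sqrt(2))
        assert chord_distance(g1, g2) == pytest.approx(2 / math.pi * math.sqrt(2))

    def test_missing_loci_skipped_pairwise(self):
        g1 = np.array([[155, 155], [-9, -9]])
        g2 = np.array([[155, 155], [200, 200]])
        assert chord_distance(g1, g2) == 0.0
        with pytest.raises(IncomparablePairError):
            chord_distance(np.array([[-9, -9]]), np.array([[155, 155]]))


class TestDistanceMatrix:
    def test_identical_accessions_zero_matrix(self):
        calls = np.tile(np.array([[155, 161], [200, 200]]), (3, 1, 1))
        gm = GenotypeMatrix([Accession(f"a{i}") for i in range(3)], ["L1", "L2"], calls)
        dm = distance_matrix(gm)
        assert np.allclose(dm.values, 0.0)

    def test_matches_per_pair_recomputation(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        dm = distance_matrix(gm)
        rng = np.random.default_rng(1)
        for _ in range(10):
            i, j = rng.choice(gm.n_accessions, size=2, replace=False)
            d = chord_distance(gm.calls[i], gm.calls[j])
            assert dm.values[i, j] == pytest.approx(d, abs=1e-12)

    def test_between_exceeds_within(self, two_pop_panel):
        gm, source, _ = two_pop_panel
        dm = distance_matrix(gm)
        grp = (source == "P2").to_numpy().astype(int)
        same = np.equal.outer(grp, grp)
        iu = np.triu_indices(len(grp), 1)
        within = dm.values[iu][same[iu]]
        between = dm.values[iu][~same[iu]]
        assert between.mean() > within.mean()

    def test_range_within_theory(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        dm = distance_matrix(gm)
        assert dm.values.min() >= 0.0
        assert dm.values.max() <= MAX_CHORD + 1e-12

    def test_phylip_round_trip(self, tmp_path, two_pop_panel):
        gm, _, _ = two_pop_panel
        dm = distance_matrix(gm)
        p = tmp_path / "d.phy"
        write_phylip(dm, p)
        back = read_phylip(p)
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values, atol=1e-9)


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], values=D))
        back = tree_distance_matrix(tree, ["A", "B", "C"])
        assert np.allclose(back.values, D, atol=1e-9)

    def test_four_taxon_additive_recovery(self):
        # additive matrix from ((A:2,B:3):3,(C:4,D:4):1) against the
        # enumerate-all-topologies oracle: only the AB|CD split is additive
        D = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels=list("ABCD"), values=D))
        back = tree_distance_matrix(tree, list("ABCD"))
        assert np.allclose(back.values, D, atol=1e-9)
        splits = {
            frozenset(lf.taxon.label for lf in e.head_node.leaf_iter())
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        }
        assert frozenset("AB") in splits or frozenset("CD") in splits

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_random_additive_trees_recovered(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(5):
            _, dm = random_additive_tree(rng, n_leaves)
            back = tree_distance_matrix(nj_tree(dm), dm.labels)
            assert np.allclose(back.values, dm.values, atol=1e-9)

    def test_rejects_invalid_matrices(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "B"], values=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(
                labels=["A", "B"], values=np.array([[0, np.nan], [np.nan, 0]])
            )


class TestUPGMA:
    def test_two_taxa_root_at_half_distance(self):
        dm = DistanceMatrix(labels=["A", "B"], values=np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = upgma_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.5, "B": 1.5}

    def test_ultrametric_input_recovered(self):
        # dendrogram heights 1, 2, 3 -> ultrametric matrix
        D = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            float,
        )
        dm = DistanceMatrix(labels=list("ABCD"), values=D)
        back = tree_distance_matrix(upgma_tree(dm), list("ABCD"))
        assert np.allclose(back.values, D, atol=1e-9)

    def test_output_is_ultrametric(self, two_pop_panel):
        gm, _, _ = two_pop_panel
        dm = distance_matrix(gm.subset(ids=gm.ids[:20]))
        tree = upgma_tree(dm)
        depths = [
            lf.distance_from_root() for lf in tree.leaf_node_iter()
        ]
        assert np.allclose(depths, depths[0], atol=1e-9)

    def test_permutation_invariant_up_to_relabeling(self):
        rng = np.random.default_rng(5)
        _, dm = random_additive_tree(rng, 7)
        perm = rng.permutation(7)
        dm2 = DistanceMatrix(
            labels=[dm.labels[i] for i in perm],
            values=dm.values[np.ix_(perm, perm)],
        )
        b1 = tree_distance_matrix(upgma_tree(dm), dm.labels)
        b2 = tree_distance_matrix(upgma_tree(dm2), dm.labels)
        assert np.allclose(b1.values, b2.values, atol=1e-9)


class TestNewick:
    def test_three_taxon_string_form(self, tmp_path):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], values=D))
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        text = p.read_text().strip()
        assert text.startswith("(") and text.endswith(";")
        assert all(lbl in text for lbl in "ABC")

    def test_round_trip_preserves_path_lengths(self, tmp_path):
        rng = np.random.default_rng(11)
        _, dm = random_additive_tree(rng, 9)
        tree = nj_tree(dm)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = tree_distance_matrix(read_newick(p), dm.labels)
        orig = tree_distance_matrix(tree, dm.labels)
        assert np.allclose(back.values, orig.values, atol=1e-4)

    def test_labels_with_spaces_quoted(self, tmp_path):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(
            DistanceMatrix(labels=["tax one", "tax two", "tax three"], values=D)
        )
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        labels = {lf.taxon.label for lf in back.leaf_node_iter()}
        assert labels == {"tax one", "tax two", "tax three"}


def test_nj_agrees_with_reference_implementation():
    """Cross-check against scikit-bio's independent NJ on a non-additive
    (noisy) matrix: identical leaf-to-leaf path lengths."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(2)
    _, dm = random_additive_tree(rng, 8)
    noisy = dm.values + rng.uniform(0, 0.01, dm.values.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0.0)
    dmn = DistanceMatrix(labels=dm.labels, values=noisy)
    ours = tree_distance_matrix(nj_tree(dmn), dm.labels)
    ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
    ref_mat = np.zeros_like(noisy)
    for i, a in enumerate(dm.labels):
        for j in range(i + 1, len(dm.labels)):
            ref_mat[i, j] = ref_mat[j, i] = ref.find(a).distance(ref.find(dm.labels[j]))
    assert np.allclose(ours.values, ref_mat, atol=1e-6)
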