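import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from introprio import phylogeny as ph
from introprio.errors import InputError, InsufficientOverlapError


def gm(samples, calls):
    calls = np.asarray(calls, dtype=np.int8)
    sites = [("chr1", i + 1, "A", "T") for i in range(calls.shape[1])]
    return ph.GenotypeMatrix(list(samples), sites, calls)


class TestGenotypeDistance:
    def test_identical_zero(self):
        d = ph.genotype_distance(gm("ab", [[0, 1, 2, 0], [0, 1, 2, 0]]))
        assert d[("a", "b")] == 0.0

    def test_fully_discordant_one(self):
        d = ph.genotype_distance(gm("ab", [[0, 0, 0, 0], [2, 2, 2, 2]]))
        assert d[("a", "b")] == 1.0

    def test_half_discordant(self):
        d = ph.genotype_distance(gm("ab", [[0, 2, 0, 2], [0, 2, 2, 0]]))
        assert d[("a", "b")] == 0.5

    def test_missing_excluded_from_denominator(self):
        d = ph.genotype_distance(gm("ab", [[0, -1, 2], [2, 0, 2]]))
        assert d[("a", "b")] == 0.5  # 1 of 2 co-observed sites differs

    def test_no_overlap_raises(self):
        with pytest.raises(InsufficientOverlapError):
            ph.genotype_distance(gm("ab", [[0, -1], [-1, 0]]))

    def test_pseudo_metric_on_complete_matrices(self, rng):
        calls = rng.integers(0, 3, size=(6, 40))
        d = ph.genotype_distance(gm("abcdef", calls)).d
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def random_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths via sequential joins."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 1.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.length = float(rng.uniform(0.1, 1.0))
        a, b = nodes[j], nodes[i]
        parent.extend([a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    return root


def tree_matrix(tree, labels):
    return ph.path_length_matrix(tree, labels)


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # additive matrix of the tree ((A:1,B:2):1,(C:3,D:4)): verified by the
        # four-point condition and exact path-length recovery
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        # four-point check on the input: AB|CD is the cherry split
        assert d[0, 1] + d[2, 3] < d[0, 2] + d[1, 3] == d[0, 3] + d[1, 2]
        dm = ph.DistanceMatrix(list("ABCD"), d)
        tree = ph.neighbor_joining(dm)
        assert np.allclose(tree_matrix(tree, list("ABCD")), d, atol=1e-9)
        # external branch lengths
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        # AB form a cherry
        assert tree.find("A").parent is tree.find("B").parent

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = ph.neighbor_joining(ph.DistanceMatrix(list("ABC"), d))
        assert np.allclose(tree_matrix(tree, list("ABC")), d, atol=1e-9)

    def test_ultrametric_split_matches_single_linkage(self):
        # balanced clock tree: (A,B) at depth 1, (C,D) at depth 1, root depth 3
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], dtype=float
        )
        tree = ph.neighbor_joining(ph.DistanceMatrix(list("ABCD"), d))
        assert tree.find("A").parent is tree.find("B").parent or \
            tree.find("C").parent is tree.find("D").parent

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_recovery_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        tree = random_tree(rng, n)
        labels = sorted(t.name for t in tree.tips())
        d = tree_matrix(tree, labels)
        out = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
        assert np.allclose(tree_matrix(out, labels), d, atol=1e-9)
        # topology identical to the generating tree
        assert tree.compare_rfd(out) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_nj_on_additive_input(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(rng, 8)
        labels = sorted(t.name for t in tree.tips())
        d = tree_matrix(tree, labels)
        ours = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
        ref = skbio_nj(SkbioDM(d, labels))
        assert ours.compare_rfd(ref) == 0.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        tree = random_tree(rng, 7)
        labels = sorted(t.name for t in tree.tips())
        d = tree_matrix(tree, labels)
        t1 = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
        perm = list(rng.permutation(len(labels)))
        labels2 = [labels[i] for i in perm]
        d2 = d[np.ix_(perm, perm)]
        t2 = ph.neighbor_joining(ph.DistanceMatrix(labels2, d2))
        assert t1.compare_rfd(t2) == 0.0
        for a in labels:
            for b in labels:
                assert ph.tree_distance(t1, a, b) == pytest.approx(
                    ph.tree_distance(t2, a, b), abs=1e-9
                )

    def test_nonnegative_branch_lengths_on_noisy_input(self, rng):
        d = rng.uniform(0.2, 1.0, size=(8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        tree = ph.neighbor_joining(ph.DistanceMatrix([f"s{i}" for i in range(8)], d))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0

    def test_too_few_taxa_raises(self):
        with pytest.raises(InputError):
            ph.neighbor_joining(ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_newick_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, 6)
        labels = sorted(t.name for t in tree.tips())
        d = tree_matrix(tree, labels)
        out = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
        p = tmp_path / "t.nwk"
        ph.write_newick(out, p)
        back = ph.read_newick(p)
        assert out.compare_rfd(back) == 0.0


class TestAssignOrigin:
    def test_tie_breaks_alphabetically(self):
        tree = TreeNode.read(["((focal:1,x1:1):1,(a1:1,b1:1):1);"])
        calls = ph.assign_origin(tree, "focal", {"x1": "x", "a1": "a", "b1": "b"})
        assert calls[0].species == "x"
        assert [c.species for c in calls[1:]] == ["a", "b"]  # equidistant -> alphabetical

    def test_focal_absent_raises(self):
        tree = TreeNode.read(["((a:1,b:1):1,c:1);"])
        with pytest.raises(InputError):
            ph.assign_origin(tree, "zzz", {"a": "x", "b": "y", "c": "z"})

    def test_donor_ranks_first_on_introgressed_chromosome(self, dataset):
        cfg = dataset.config
        m = ph.read_genotype_matrix(dataset.panel_vcf)
        species_of = {s: s.rsplit("_", 1)[0] for s in m.samples if s != "focal"}
        intro_chroms = {s["chrom"] for s in dataset.truth.segments}
        for chrom in m.chroms:
            sub = m.subset_chrom(chrom)
            tree = ph.neighbor_joining(ph.genotype_distance(sub))
            top = ph.assign_origin(tree, "focal", species_of)[0].species
            if chrom in intro_chroms:
                assert top == cfg.donor_species
            else:
                assert top == "cultivated"
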