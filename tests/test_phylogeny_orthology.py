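import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from wrkykit import phylogeny_orthology as ph
from wrkykit._tree import PhyloNode
from wrkykit.io_gene_models import SequenceRecord, write_newick

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# Brute-force alignment oracle: enumerate every global alignment as a move
# sequence (match, insert, delete) and score it with affine gaps where a gap
# of length L costs open + (L - 1) * extend.


def brute_force_best_score(a, b, gap_open=10.0, gap_extend=0.5):
    best = -np.inf

    def recurse(i, j, score, prev_move):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev_move == "D" else gap_open
            recurse(i + 1, j, score - cost, "D")
        if j < len(b):
            cost = gap_extend if prev_move == "I" else gap_open
            recurse(i, j + 1, score - cost, "I")

    recurse(0, 0, 0.0, None)
    return best


class TestAlignGlobal:
    def test_identity_one(self):
        _, _, identity = ph.align_global("WRKYGQK", "WRKYGQK")
        assert identity == 1.0

    def test_single_substitution_identity(self):
        _, _, identity = ph.align_global("WRKYGQK", "WRKYGEK")
        assert identity == pytest.approx(6 / 7)

    @pytest.mark.parametrize(
        "a,b",
        [
            ("MKV", "MKV"),
            ("MKVLW", "MKW"),
            ("WRKYGQ", "WRKGQ"),
            ("ACDEF", "CDE"),
            ("MKVASD", "MVWASD"),
            ("PQR", "QRPP"),
        ],
    )
    def test_score_matches_brute_force(self, a, b):
        _, score, _ = ph.align_global(a, b)
        assert score == pytest.approx(brute_force_best_score(a, b))

    def test_swap_invariance(self):
        _, s1, i1 = ph.align_global("MKVLWAAK", "MKVWAK")
        _, s2, i2 = ph.align_global("MKVWAK", "MKVLWAAK")
        assert s1 == pytest.approx(s2)
        assert i1 == pytest.approx(i2)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ph.align_global("", "MKV")


class TestDistanceMatrix:
    def test_premetric_properties(self):
        records = [
            SequenceRecord("a", "MKVLWDER"),
            SequenceRecord("b", "MKVLWDEK"),
            SequenceRecord("c", "MGGGWDER"),
        ]
        dm = ph.distance_matrix(records)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert ((dm.data >= 0) & (dm.data <= 1)).all()

    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            ph.DistanceMatrix(labels=("a", "b"), data=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError, match="NaN"):
            ph.DistanceMatrix(labels=("a", "b"), data=np.array([[0, np.nan], [np.nan, 0]]))


# ---------------------------------------------------------------------------
# Neighbour joining


def random_binary_tree(labels, rng):
    nodes = [PhyloNode(name=label) for label in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = PhyloNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def tree_distance_matrix(tree, labels):
    from wrkykit.phylogeny_orthology import tree_distances

    n = len(labels)
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = tree_distances(tree, src)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


def splits(tree):
    """Non-trivial leaf bipartitions (as frozensets of one side)."""
    all_leaves = frozenset(tree.leaf_names())
    out = set()
    for node in tree.traverse():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(n.name for n in node.leaves())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(min(side, all_leaves - side, key=sorted))
    return out


class TestNJTree:
    def test_four_taxon_additive_recovery(self):
        # matrix from ((A:1,B:2):3,(C:1.5,D:2.5))
        d = np.array(
            [
                [0.0, 3.0, 5.5, 6.5],
                [3.0, 0.0, 6.5, 7.5],
                [5.5, 6.5, 0.0, 4.0],
                [6.5, 7.5, 4.0, 0.0],
            ]
        )
        tree = ph.nj_tree(ph.DistanceMatrix(labels=("A", "B", "C", "D"), data=d))
        assert splits(tree) == {frozenset({"A", "B"})}

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = ph.nj_tree(ph.DistanceMatrix(labels=("a", "b", "c"), data=d))
        lengths = {n.name: n.length for n in tree.traverse() if n.is_leaf}
        # three-point formulas: la = (dab + dac - dbc)/2 etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("n_taxa", [5, 8])
    def test_additive_matrix_topology_recovery(self, seed, n_taxa):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(n_taxa)]
        true_tree = random_binary_tree(labels, rng)
        d = tree_distance_matrix(true_tree, labels)
        recovered = ph.nj_tree(ph.DistanceMatrix(labels=tuple(labels), data=d))
        assert splits(recovered) == splits(true_tree)
        # additive distances are reproduced by path lengths in the NJ tree
        d2 = tree_distance_matrix(recovered, labels)
        assert np.allclose(d, d2, atol=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            ph.nj_tree(ph.DistanceMatrix(labels=("a", "b"), data=np.zeros((2, 2))))

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.1, 1.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = ph.nj_tree(ph.DistanceMatrix(labels=tuple("abcdef"), data=d))
        assert all(
            (n.length or 0.0) >= 0.0 for n in tree.traverse() if n is not tree
        )

    def test_newick_writable(self):
        d = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 3.0], [3.0, 3.0, 0.0]])
        tree = ph.nj_tree(ph.DistanceMatrix(labels=("a", "b", "c"), data=d))
        assert write_newick(tree).endswith(";")


def leaf_depths(tree):
    depths = {}

    def walk(node, depth):
        depth += node.length or 0.0
        if node.is_leaf:
            depths[node.name] = depth
        for child in node.children:
            walk(child, depth)

    walk(tree, -(tree.length or 0.0))
    return depths


class TestMidpointRoot:
    def test_midpoint_balances_deepest_leaves(self):
        d = np.array(
            [
                [0.0, 3.0, 5.5, 6.5],
                [3.0, 0.0, 6.5, 7.5],
                [5.5, 6.5, 0.0, 4.0],
                [6.5, 7.5, 4.0, 0.0],
            ]
        )
        labels = ("A", "B", "C", "D")
        tree = ph.nj_tree(ph.DistanceMatrix(labels=labels, data=d))
        rooted = ph.midpoint_root(tree)
        assert len(rooted.children) == 2
        assert sorted(rooted.leaf_names()) == sorted(labels)
        depths = leaf_depths(rooted)
        diameter = max(
            ph.tree_distances(tree, x)[y] for x in labels for y in labels
        )
        # the deepest leaf sits exactly half the diameter from the root
        assert max(depths.values()) == pytest.approx(diameter / 2)
        # leaf-to-leaf path lengths are preserved by rerooting
        for x in labels:
            before = ph.tree_distances(tree, x)
            after = ph.tree_distances(rooted, x)
            for y in labels:
                assert after[y] == pytest.approx(before[y])


# ---------------------------------------------------------------------------
# BBH


def rec(name, seq):
    return SequenceRecord(name, seq)


class TestBBH:
    def test_single_mutual_best(self):
        set_a = [(rec("a1", "MKVLWDERYSTAGL"), "spA")]
        set_b = [(rec("b1", "MKVLWDERYSTAGL"), "spB")]
        (pair,) = ph.bbh(set_a, set_b)
        assert (pair.id_a, pair.id_b, pair.relation) == ("a1", "b1", "ortholog")

    def test_tie_means_no_pair(self):
        query = "MKVLWDERYSTAGL"
        set_a = [(rec("a1", query), "spA")]
        set_b = [(rec("b1", query), "spB"), (rec("b2", query), "spB")]
        assert ph.bbh(set_a, set_b) == []

    def test_paralogs_same_set(self):
        seqs = [
            rec("g1", "MKVLWDERYSTAGLMKVLWDERYSTAGL"),
            rec("g2", "MKVLWDERYSTAGLMKVLWDERYSTAGV"),
            rec("g3", "PPPPQQQQNNNNSSSSTTTTGGGGAAAA"),
            rec("g4", "PPPPQQQQNNNNSSSSTTTTGGGGAAAV"),
        ]
        tagged = [(s, "sp") for s in seqs]
        pairs = ph.bbh(tagged, tagged)
        assert {(p.id_a, p.id_b) for p in pairs} == {("g1", "g2"), ("g3", "g4")}
        assert all(p.relation == "paralog" for p in pairs)

    def test_one_to_one(self):
        rng = np.random.default_rng(11)
        alphabet = list("ADEFGIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(alphabet, 25)) for _ in range(6)]
        set_a = [(rec(f"a{i}", s), "spA") for i, s in enumerate(seqs)]
        set_b = [(rec(f"b{i}", s), "spB") for i, s in enumerate(rng.permutation(seqs))]
        pairs = ph.bbh(set_a, set_b)
        for side in (0, 1):
            ids = [p.id_a if side == 0 else p.id_b for p in pairs]
            assert len(ids) == len(set(ids))

    def test_planted_duplicated_family_recovered(self):
        from wrkykit import synthetic_data as syn

        proteins, _, _ = syn.make_family(
            4, {"group2c": 1.0}, seed=21
        )
        # duplicate each gene with a single conservative substitution
        dup = []
        for p in proteins:
            seq = p.seq.replace("L", "I", 1) if "L" in p.seq else p.seq[:-1] + "A"
            dup.append(SequenceRecord(p.id + "_dup", seq))
        tagged = [(s, "sp") for s in list(proteins) + dup]
        pairs = ph.bbh(tagged, tagged)
        expected = {(p.id, p.id + "_dup") for p in proteins}
        assert {(p.id_a, p.id_b) for p in pairs} == expected
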