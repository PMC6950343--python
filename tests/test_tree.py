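"""Distance matrices, UPGMA, PHYLIP/Newick serialization."""

import io

import dendropy
import numpy as np
import pytest

from _oracles import naive_upgma_merges
from conftest import random_distance_matrix
from coemit.align import pair_forward
from coemit.simulate import make_toy_hmms
from coemit.tree import (
    DistanceMatrix,
    TreeError,
    all_vs_all,
    read_phylip,
    score_to_distance,
    upgma,
    write_newick,
    write_phylip,
)


def _clades(tree):
    """(frozenset of leaf labels, height) for every internal node."""
    out = set()

    def rec(node):
        if node.is_leaf:
            return frozenset([node.label])
        leaves = frozenset()
        for c in node.children:
            leaves |= rec(c)
        out.add((leaves, node.height))
        return leaves

    rec(tree.root)
    return out


class TestDistanceMatrix:
    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(TreeError, match="symmetric"):
            DistanceMatrix(["a", "b"], m)

    def test_negative_rejected(self):
        m = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(TreeError, match="non-negative"):
            DistanceMatrix(["a", "b"], m)

    def test_nonzero_diagonal_rejected(self):
        m = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.raises(TreeError, match="diagonal"):
            DistanceMatrix(["a", "b"], m)


class TestScoreToDistance:
    def test_identical_models_distance_zero(self):
        s = np.array([[8.0, 8.0], [8.0, 8.0]])
        d = score_to_distance(s, ["a", "b"])
        assert d.matrix[0, 1] == 0.0

    def test_nonpositive_score_clips_to_one(self):
        s = np.array([[5.0, -2.0], [-2.0, 7.0]])
        d = score_to_distance(s, ["a", "b"])
        assert d.matrix[0, 1] == 1.0

    def test_matches_formula_elementwise(self, rng):
        n = 6
        s = rng.normal(2.0, 3.0, size=(n, n))
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, rng.uniform(5.0, 10.0, size=n))
        labels = [f"m{i}" for i in range(n)]
        d = score_to_distance(s, labels)
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert d.matrix[i, j] == 0.0
                else:
                    want = 1.0 - max(0.0, s[i, j]) / max(s[i, i], s[j, j])
                    want = min(1.0, max(0.0, want))
                    assert d.matrix[i, j] == pytest.approx(want, abs=1e-12)

    def test_missing_pairs_get_matrix_maximum(self):
        s = np.array([[9.0, 6.0, np.nan], [6.0, 9.0, 3.0], [np.nan, 3.0, 9.0]])
        d = score_to_distance(s, ["a", "b", "c"])
        assert d.matrix[0, 2] == d.matrix.max()

    def test_nonpositive_self_score_names_model(self):
        s = np.array([[5.0, 1.0], [1.0, -0.5]])
        with pytest.raises(TreeError, match="b"):
            score_to_distance(s, ["a", "b"])


class TestUpgma:
    def test_textbook_three_leaves(self, tmp_path):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = upgma(d)
        buf = io.StringIO()
        write_newick(tree, buf)
        assert buf.getvalue().strip() == "((A:1,B:1):1,C:2);"

    def test_all_equal_distances_give_indexed_caterpillar(self):
        n = 5
        m = np.full((n, n), 3.0)
        np.fill_diagonal(m, 0.0)
        labels = [f"L{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(labels, m))
        clades = sorted(_clades(tree), key=lambda kv: len(kv[0]))
        # ties resolved by smallest index: L0+L1, then +L2, +L3, +L4
        for size, (leaves, height) in enumerate(clades, start=2):
            assert leaves == frozenset(labels[:size])
            assert height == pytest.approx(1.5)

    def test_matches_naive_oracle_on_random_matrices(self, rng):
        """Candidate-list UPGMA == full-rescan UPGMA, exactly."""
        for trial in range(30):
            n = int(rng.integers(3, 30))
            m = random_distance_matrix(rng, n)
            if trial % 3 == 0:  # force ties
                m = np.round(m, 1)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, m))
            got = {
                (frozenset(int(x[1:]) for x in leaves), h)
                for leaves, h in _clades(tree)
            }
            want = set(naive_upgma_merges(m))
            assert got == want

    def test_output_is_ultrametric_with_monotone_merges(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 40))
            m = random_distance_matrix(rng, n)
            labels = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, m))
            depths = list(tree.leaf_depths().values())
            assert max(depths) - min(depths) <= 1e-9
            assert sorted(tree.leaf_labels()) == sorted(labels)
            heights = tree.merge_heights()

            def check(node, parent_h):
                assert node.height <= parent_h + 1e-12
                for c in node.children:
                    check(c, node.height)

            check(tree.root, tree.root.height)

    def test_single_item_rejected(self):
        with pytest.raises(TreeError):
            upgma(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestPhylip:
    def test_two_by_two_round_trip(self, tmp_path):
        d = DistanceMatrix(["alpha", "beta"],
                           np.array([[0.0, 0.25], [0.25, 0.0]]))
        path = tmp_path / "d.phylip"
        write_phylip(d, path)
        assert path.read_text().splitlines()[0] == "2"
        back = read_phylip(path)
        assert back.labels == ["alpha", "beta"]
        np.testing.assert_allclose(back.matrix, d.matrix, atol=1e-6)

    def test_random_matrix_round_trip(self, rng, tmp_path):
        n = 12
        m = random_distance_matrix(rng, n)
        d = DistanceMatrix([f"model_{i}" for i in range(n)], m)
        path = tmp_path / "d.phylip"
        write_phylip(d, path)
        back = read_phylip(path)
        np.testing.assert_allclose(back.matrix, d.matrix, atol=1e-6)

    def test_strict_mode_truncates_with_unique_suffix(self, tmp_path):
        labels = ["abcdefghijkl", "abcdefghijxy", "short"]
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = m[0, 2] = m[2, 0] = m[1, 2] = m[2, 1] = 0.5
        buf = io.StringIO()
        write_phylip(DistanceMatrix(labels, m), buf, strict=True)
        lines = buf.getvalue().splitlines()
        names = [ln.split()[0] for ln in lines[1:]]
        assert names[0] == "abcdefghij"
        assert names[1] == "abcdefghi1"
        assert len(set(names)) == 3

    def test_whitespace_labels_sanitized(self, tmp_path):
        d_labels = ["a b", "c"]
        m = np.array([[0.0, 0.5], [0.5, 0.0]])
        buf = io.StringIO()
        with pytest.warns(UserWarning, match="whitespace"):
            write_phylip(DistanceMatrix(d_labels, m), buf)
        assert "a_b" in buf.getvalue()


class TestNewick:
    def test_round_trip_preserves_path_lengths(self, rng, tmp_path):
        n = 10
        m = random_distance_matrix(rng, n)
        labels = [f"leaf{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(labels, m))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        expected = tree.leaf_depths()
        for leaf in parsed.leaf_node_iter():
            depth = leaf.distance_from_root()
            assert depth == pytest.approx(expected[leaf.taxon.label],
                                          rel=1e-4)
        assert {t.label for t in parsed.taxon_namespace} == set(labels)

    def test_single_cherry(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        buf = io.StringIO()
        write_newick(upgma(d), buf)
        assert buf.getvalue().strip() == "(A:0.5,B:0.5);"

    def test_special_characters_quoted(self):
        d = DistanceMatrix(["a(1)", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        buf = io.StringIO()
        write_newick(upgma(d), buf)
        assert "'a(1)':0.5" in buf.getvalue()


class TestAllVsAll:
    def test_two_models_mirrored(self, toy_models):
        labels, s = all_vs_all(toy_models[:2])
        assert s.shape == (2, 2)
        assert s[0, 1] == s[1, 0]
        assert np.isfinite(s).all()

    def test_matches_independent_pair_calls(self, toy_models):
        library = toy_models[:5]
        labels, s = all_vs_all(library)
        for i in range(5):
            for j in range(i, 5):
                want = pair_forward(library[i], library[j]).forward_bits
                assert s[i, j] == pytest.approx(want, abs=1e-12)

    def test_duplicate_names_rejected(self, toy_models):
        a = toy_models[0]
        with pytest.raises(TreeError, match="duplicate"):
            all_vs_all([a, a])
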