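"""Nei standard distance and UPGMA construction."""

import math

import numpy as np
import pytest

import ssrkit as sk
from ssrkit.distance import IncomparableUnitsError, TreeNode

from _oracles import nei_distance_single_locus


def _matrix(rows, loci=("locA",), populations=None):
    calls = np.array(
        [[g if g is not None else (0, 0) for g in row] for row in rows]
    )
    n = len(rows)
    return sk.GenotypeMatrix(
        tuple(f"s{i}" for i in range(n)),
        tuple(populations or ["p"] * n),
        tuple(loci),
        calls,
    )


class TestNeiDistance:
    def test_identical_units_distance_zero(self):
        m = _matrix([[(1, 2)], [(1, 2)]])
        assert sk.nei_standard_distance(m, "s0", "s1") == pytest.approx(0.0)

    def test_fixed_versus_heterozygous(self):
        # X fixed (p=1), Y with p=(0.5, 0.5): D = -ln(0.5 / sqrt(0.5))
        m = _matrix([[(1, 1)], [(1, 2)]])
        d = sk.nei_standard_distance(m, "s0", "s1")
        assert d == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-9)
        assert d == pytest.approx(0.3466, abs=5e-5)

    def test_no_shared_allele_is_infinite(self):
        m = _matrix([[(1, 1)], [(2, 2)]])
        assert sk.nei_standard_distance(m, "s0", "s1") == math.inf

    def test_no_common_locus_is_an_error_not_infinity(self):
        m = _matrix([[(1, 1), None], [None, (2, 2)]], loci=("locA", "locB"))
        with pytest.raises(IncomparableUnitsError):
            sk.nei_standard_distance(m, "s0", "s1")

    def test_matches_single_locus_oracle(self):
        m = _matrix([[(1, 2)], [(2, 3)]])
        expected = nei_distance_single_locus(
            {1: 0.5, 2: 0.5}, {2: 0.5, 3: 0.5}
        )
        assert sk.nei_standard_distance(m, "s0", "s1") == pytest.approx(
            expected
        )

    def test_population_level_uses_pooled_frequencies(self):
        m = _matrix(
            [[(1, 1)], [(1, 2)], [(2, 2)]],
            populations=["pa", "pa", "pb"],
        )
        d = sk.nei_standard_distance(m, "pa", "pb", level="population")
        assert d == pytest.approx(
            nei_distance_single_locus({1: 0.75, 2: 0.25}, {2: 1.0})
        )


class TestPairwiseDistances:
    def test_packaged_dataset_shape_and_duplicates(self, passiflora):
        with pytest.warns(UserWarning, match="capped"):
            d = sk.pairwise_distances(passiflora)
        assert d.values.shape == (87, 87)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        same = d[
            '11-P. edulis "man tian xing"', '12-P. edulis "man tian xing"'
        ]
        assert same == 0.0

    def test_infinite_entries_capped_above_max_finite(self):
        m = _matrix([[(1, 1)], [(1, 2)], [(3, 3)]])
        with pytest.warns(UserWarning, match="capped"):
            d = sk.pairwise_distances(m)
        finite_max = sk.nei_standard_distance(m, "s0", "s1")
        assert d["s0", "s2"] == pytest.approx(finite_max + 1.0)

    def test_permutation_equivariance(self, passiflora):
        sub = passiflora.subset(list(passiflora.sample_ids[:6]))
        d = sk.pairwise_distances(sub)
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = sub.subset([sub.sample_ids[i] for i in perm])
        # subset keeps matrix order, so rebuild in permuted order directly
        m2 = sk.GenotypeMatrix(
            tuple(sub.sample_ids[i] for i in perm),
            tuple(sub.populations[i] for i in perm),
            sub.locus_names,
            sub.calls[perm],
        )
        d2 = sk.pairwise_distances(m2)
        for a in sub.sample_ids:
            for b in sub.sample_ids:
                assert d[a, b] == pytest.approx(d2[a, b])


def _heights(node, acc):
    acc.append(node.height)
    for c in node.children:
        _heights(c, acc)
    return acc


class TestUpgma:
    def test_three_leaves(self):
        d = sk.DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]),
        )
        tree = sk.upgma(d)
        assert tree.root.height == pytest.approx(2.0)
        assert tree.cophenetic("A", "B") == pytest.approx(2.0)
        assert tree.cophenetic("A", "C") == pytest.approx(4.0)
        assert sk.to_newick(tree) == "((A:1,B:1):1,C:2);"

    def test_equidistant_ties_resolved_lexicographically(self):
        labels = ("d", "b", "c", "a")
        d = sk.DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4))
        tree = sk.upgma(d)
        assert set(_heights(tree.root, [])) <= {0.0, 0.5}
        first = tree.root
        while first.children:
            first = first.children[0]
        assert first.label == "a"  # smallest label merges first

    def test_two_leaves_single_cherry(self):
        d = sk.DistanceMatrix(("A", "B"), np.array([[0, 1.0], [1, 0]]))
        tree = sk.upgma(d)
        assert tree.root.height == pytest.approx(0.5)
        assert sk.to_newick(tree) == "(A:0.5,B:0.5);"

    def test_output_is_exactly_ultrametric(self, passiflora):
        with pytest.warns(UserWarning):
            d = sk.pairwise_distances(passiflora)
        tree = sk.upgma(d)

        def depth_to_leaves(node):
            if node.is_leaf:
                return {0.0}
            out = set()
            for c in node.children:
                out |= {
                    x + (node.height - c.height)
                    for x in depth_to_leaves(c)
                }
            return out

        depths = depth_to_leaves(tree.root)
        assert max(depths) - min(depths) < 1e-9

    def test_reproduces_ultrametric_input_exactly(self):
        # cophenetic matrix of a known ultrametric tree
        labels = ("A", "B", "C", "D")
        vals = np.array(
            [
                [0.0, 2.0, 6.0, 6.0],
                [2.0, 0.0, 6.0, 6.0],
                [6.0, 6.0, 0.0, 4.0],
                [6.0, 6.0, 4.0, 0.0],
            ]
        )
        tree = sk.upgma(sk.DistanceMatrix(labels, vals))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert tree.cophenetic(a, b) == pytest.approx(vals[i, j])

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_agrees_with_scipy_average_linkage(self, n):
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(42 + n)
        for _ in range(20):
            # continuous draws: no ties even among derived averages
            condensed = rng.uniform(1.0, 2.0, n * (n - 1) // 2)
            full = squareform(condensed)
            labels = tuple(f"L{i}" for i in range(n))
            tree = sk.upgma(sk.DistanceMatrix(labels, full))
            coph = cophenet(average(condensed))
            ours = squareform(
                np.array(
                    [
                        [tree.cophenetic(a, b) for b in labels]
                        for a in labels
                    ]
                )
            )
            assert np.allclose(ours, coph)


class TestNewick:
    def test_metacharacter_labels_survive_round_trip(self):
        import skbio

        labels = ("P. edulis 'zi xiang'", "plain", "with:colon")
        d = sk.DistanceMatrix(
            labels,
            np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0.0]]),
        )
        nwk = sk.to_newick(sk.upgma(d))
        tree = skbio.TreeNode.read([nwk])
        tips = {t.name for t in tree.tips()}
        assert tips == set(labels)

    def test_parse_serialize_idempotent(self):
        import dendropy

        d = sk.DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]),
        )
        nwk = sk.to_newick(sk.upgma(d))
        t = dendropy.Tree.get(data=nwk, schema="newick")
        again = t.as_string(schema="newick").strip()
        t2 = dendropy.Tree.get(data=again, schema="newick")
        d1 = {
            (a.taxon.label, b.taxon.label)
            for a in t.leaf_node_iter()
            for b in t2.leaf_node_iter()
            if a.taxon.label == b.taxon.label
        }
        assert len(d1) == 3

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            sk.DistanceMatrix(
                ("A", "B"), np.array([[0, 1.0], [2.0, 0]])
            )
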