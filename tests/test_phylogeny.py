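"""Distances, NJ reconstruction, bootstrap and Newick round-trips."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peroxscan.phylogeny import (
    MSA,
    DistanceMatrix,
    NewickParseError,
    SaturationError,
    UndefinedDistanceError,
    bootstrap_support,
    distance_matrix,
    is_undefined,
    nj_tree,
    p_distance,
    poisson_correct,
    read_newick,
    write_newick,
)


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = MSA(("a", "b"), ("ACDE", "ACDE"))
        assert p_distance(msa, 0, 1) == 0.0

    def test_pairwise_deletion_drops_gap_columns(self):
        msa = MSA(("a", "b"), ("AC-D", "ACED"))
        assert p_distance(msa, 0, 1) == 0.0  # compared columns 1,2,4 all equal

    def test_direct_count(self):
        msa = MSA(("a", "b"), ("AAAA", "AATT"))
        assert p_distance(msa, 0, 1) == 0.5

    def test_no_comparable_columns_undefined(self):
        msa = MSA(("a", "b", "c"), ("A--A", "-AA-", "AAAA"))
        assert is_undefined(p_distance(msa, 0, 1))


class TestPoissonCorrection:
    @pytest.mark.parametrize("p,d", [(0.0, 0.0), (0.1, 0.105361), (0.5, 0.693147)])
    def test_closed_form(self, p, d):
        assert poisson_correct(p) == pytest.approx(d, abs=1e-6)

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            poisson_correct(1.0)

    def test_monotone_and_dominates_identity(self):
        grid = np.linspace(0, 0.98, 197)
        d = [poisson_correct(p) for p in grid]
        assert all(b > a for a, b in zip(d, d[1:]))
        assert all(di >= pi for di, pi in zip(d, grid))


class TestNJ:
    def test_three_taxon_exact(self):
        m = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), m))
        lengths = {n.name: n.branch_length for n in tree.root.children}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0}

    def test_four_taxon_additive_recovery(self):
        # distances generated by ((A:1,B:2):1,(C:3,D:4))
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), m))
        bip = tree.bipartitions()
        assert set(map(frozenset, bip)) == {frozenset({"C", "D"})}  # AB|CD split
        internal = bip[frozenset({"C", "D"})]
        leaf_lengths = {n.name: n.branch_length for n in tree.root.walk() if n.is_leaf}
        assert internal.branch_length == pytest.approx(1.0, abs=1e-9)
        for name, expect in {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}.items():
            assert leaf_lengths[name] == pytest.approx(expect, abs=1e-9)
        # total length of an additive-recovered tree equals the generating tree's
        assert tree.total_length() == pytest.approx(11.0, abs=1e-9)

    def test_equal_distances_degenerate(self):
        m = np.full((4, 4), 2.0)
        np.fill_diagonal(m, 0.0)
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), m))
        for node in tree.bipartitions().values():
            assert node.branch_length == pytest.approx(0.0, abs=1e-12)

    def test_undefined_entries_rejected(self):
        m = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(UndefinedDistanceError):
            nj_tree(DistanceMatrix(("A", "B", "C"), m))

    def test_identical_rows_give_zero_tree(self):
        msa = MSA(("a", "b", "c"), ("ACDE", "ACDE", "ACDE"))
        dm = distance_matrix(msa)
        assert np.allclose(dm.matrix, 0.0)
        tree = nj_tree(dm)
        assert tree.total_length() == 0.0


class TestDistanceMatrix:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True)
    def test_matches_scalar_path(self, seed):
        # the vectorized matrix must agree with p_distance + poisson_correct
        rng = np.random.default_rng(seed)
        rows = tuple(
            "".join(rng.choice(list("ACD-"), size=30)) for _ in range(4)
        )
        try:
            msa = MSA(("a", "b", "c", "d"), rows)
        except ValueError:
            return
        dm = distance_matrix(msa)
        for i in range(4):
            for j in range(i + 1, 4):
                p = p_distance(msa, i, j)
                if is_undefined(p) or p >= 0.99:
                    assert is_undefined(dm.matrix[i, j])
                else:
                    assert dm.matrix[i, j] == pytest.approx(poisson_correct(p))


def split_msa(n_const=10, n_major=18, n_minor=2):
    """4-taxon MSA: n_major columns support AB|CD, n_minor support AC|BD."""
    x = ["A", "A", "C", "C"]
    y = ["A", "C", "A", "C"]
    rows = tuple("G" * n_const + x[r] * n_major + y[r] * n_minor for r in range(4))
    return MSA(("A", "B", "C", "D"), rows)


class TestBootstrap:
    def test_unanimous_columns_support_100(self):
        msa = split_msa(n_minor=0)
        tree = bootstrap_support(msa, 200, seed=3)
        (node,) = tree.bipartitions().values()
        assert node.support == 100

    def test_same_seed_same_supports(self):
        msa = split_msa()
        t1 = bootstrap_support(msa, 300, seed=9)
        t2 = bootstrap_support(msa, 300, seed=9)
        s1 = {k: n.support for k, n in t1.bipartitions().items()}
        s2 = {k: n.support for k, n in t2.bipartitions().items()}
        assert s1 == s2

    def test_supports_within_range(self):
        msa = split_msa(n_major=12, n_minor=8)
        tree = bootstrap_support(msa, 300, seed=1)
        for node in tree.bipartitions().values():
            assert 0 <= node.support <= 100

    def test_leaf_order_permutation_invariance(self):
        msa = split_msa()
        perm = [2, 0, 3, 1]
        msa_p = MSA(tuple(msa.ids[i] for i in perm), tuple(msa.rows[i] for i in perm))
        s1 = {k: n.support for k, n in bootstrap_support(msa, 300, 5).bipartitions().items()}
        s2 = {k: n.support for k, n in bootstrap_support(msa_p, 300, 5).bipartitions().items()}
        assert set(s1) == set(s2)
        for k in s1:
            assert abs(s1[k] - s2[k]) <= 6  # resampling stream differs with row order


class TestNewick:
    def test_three_leaf_output(self):
        m = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), m))
        assert write_newick(tree) == "(A:1.000000,B:2.000000,C:4.000000);"

    def test_round_trip(self):
        text = "(A:1.000000,(B:0.500000,C:0.250000)87:2.000000,D:3.000000);"
        tree = read_newick(text)
        assert write_newick(tree) == text

    def test_malformed_rejected(self):
        with pytest.raises(NewickParseError):
            read_newick("(A,B")

    def test_display_filter_hides_low_support(self):
        text = "(A:1.000000,(B:0.500000,C:0.250000)42:2.000000,D:3.000000);"
        out = write_newick(read_newick(text), min_support=50)
        assert "42" not in out

    def test_dendropy_round_trip_oracle(self):
        # independent parser: dendropy must see the same topology,
        # lengths and supports that we wrote
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), m))
        for k, node in tree.bipartitions().items():
            node.support = 93
        text = write_newick(tree)
        dt = dendropy.Tree.get(data=text, schema="newick")
        leaves = sorted(l.taxon.label for l in dt.leaf_node_iter())
        assert leaves == ["A", "B", "C", "D"]
        dt.encode_bipartitions()
        splits = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in dt.preorder_edge_iter()
            if e.head_node.is_internal() and e.head_node.parent_node is not None
        }
        # either side of the AB|CD split identifies the same bipartition
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits
        lengths = sorted(
            e.length for e in dt.preorder_edge_iter() if e.length is not None
        )
        assert lengths == pytest.approx([1.0, 1.0, 2.0, 3.0, 4.0])
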