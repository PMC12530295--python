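"""Distances, neighbour joining, bootstrap, monophyly."""

import math
from collections import Counter

import dendropy
import numpy as np
import pytest

from oakpop.phylo import (
    Alignment,
    DistanceConfig,
    DistanceMatrix,
    INESTIMABLE,
    bootstrap_support,
    distance_matrix,
    is_monophyletic,
    neighbor_joining,
    p_distance,
    tn93_distance,
)
from conftest import random_pair


class TestPDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", (0.0, 4)),
            ("ACGT", "AAGT", (0.25, 4)),
            ("ACGN", "A-GT", (0.0, 2)),  # pairwise deletion of sites 2 and 4
        ],
    )
    def test_examples(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_zero_compared_sites_is_inestimable(self):
        d, n = p_distance("NNNN", "ACGT")
        assert n == 0 and d == INESTIMABLE

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG")

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = random_pair(rng, length=500, divergence=0.1)
            assert p_distance(a, b) == p_distance(b, a)


def tn93_reference(s1: str, s2: str, alpha: float | None = None) -> float:
    """Independent textbook evaluation of the Tamura-Nei (1993) distance,
    coded directly from per-site string comparison."""
    pairs = [(x, y) for x, y in zip(s1, s2) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    counts = Counter()
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
    g = {b: counts[b] / (2 * n) for b in "ACGT"}
    P1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    Q = (
        sum(1 for x, y in pairs if x != y and {x, y} not in ({"A", "G"}, {"C", "T"}))
        / n
    )
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    k1 = 2 * g["A"] * g["G"] / gR
    k2 = 2 * g["T"] * g["C"] / gY
    k3 = 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["T"] * g["C"] * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if alpha is not None:
        return alpha * (
            k1 * (w1 ** (-1 / alpha) - 1)
            + k2 * (w2 ** (-1 / alpha) - 1)
            + k3 * (w3 ** (-1 / alpha) - 1)
        )
    return -(k1 * math.log(w1) + k2 * math.log(w2) + k3 * math.log(w3))


class TestTN93:
    def test_identical_sequences_give_zero(self):
        s = "ACGTACGTACGTCCGGTTAA" * 10
        assert tn93_distance(s, s) == 0.0

    def test_correction_inflates_over_p_distance(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = random_pair(rng, length=3000, divergence=0.1)
            p, _ = p_distance(a, b)
            assert tn93_distance(a, b) >= p

    def test_matches_independent_reference_to_1e12(self):
        rng = np.random.default_rng(2)
        for i in range(100):
            a, b = random_pair(rng, length=2000, divergence=0.02 + 0.001 * i)
            assert tn93_distance(a, b) == pytest.approx(
                tn93_reference(a, b), abs=1e-12
            )

    def test_gamma_variant_matches_reference(self):
        rng = np.random.default_rng(3)
        cfg = DistanceConfig(model="tn93g", gamma_shape=0.7)
        for _ in range(20):
            a, b = random_pair(rng, length=2000, divergence=0.08)
            assert tn93_distance(a, b, cfg) == pytest.approx(
                tn93_reference(a, b, alpha=0.7), abs=1e-12
            )

    def test_reduces_to_p_distance_at_low_divergence(self):
        rng = np.random.default_rng(4)
        a, b = random_pair(rng, length=200_000, divergence=1e-3)
        p, _ = p_distance(a, b)
        assert p <= 1.5e-3
        assert tn93_distance(a, b) / p == pytest.approx(1.0, rel=5e-3)

    def test_saturation_flagged_not_nan(self):
        # maximally diverged pair drives a log argument non-positive
        a = "AG" * 300
        b = "GA" * 300
        d = tn93_distance(a, b)
        assert d == INESTIMABLE and not math.isnan(d)


def _matrix(ids, rows):
    m = np.asarray(rows, dtype=float)
    return DistanceMatrix(ids, m, np.full_like(m, 1000, dtype=np.int64))


def _path_length_matrix(tree, ids):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = _matrix(["a", "b", "c"], [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_five_taxon_additive_matrix_recovered_exactly(self):
        """NJ is consistent on additive matrices: the output tree's
        path-length matrix equals the input to 1e-9."""
        # known tree: ((a:2,b:3):1,(c:1,d:4):2,e:6)
        ids = ["a", "b", "c", "d", "e"]
        D = _matrix(
            ids,
            [
                [0, 5, 6, 9, 9],
                [5, 0, 7, 10, 10],
                [6, 7, 0, 5, 9],
                [9, 10, 5, 0, 12],
                [9, 10, 9, 12, 0],
            ],
        )
        tree = neighbor_joining(D)
        path = _path_length_matrix(tree, ids)
        np.testing.assert_allclose(path, D.values, atol=1e-9)

    def test_identical_taxa_form_zero_length_cherry(self):
        dm = _matrix(
            ["a", "b", "c", "d"],
            [[0, 0, 8, 8], [0, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
        )
        tree = neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.0)
        assert lengths["b"] == pytest.approx(0.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(_matrix(["a", "b"], [[0, 1], [1, 0]]))

    def test_inestimable_entries_rejected(self):
        dm = _matrix(["a", "b", "c"], [[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="inestimable"):
            neighbor_joining(dm)

    def test_tie_break_is_deterministic(self):
        # fully symmetric matrix: every pair ties on the Q criterion
        n = 4
        ids = ["d", "c", "b", "a"]
        dm = _matrix(ids, np.ones((n, n)) - np.eye(n))
        t1 = neighbor_joining(dm).as_string(schema="newick")
        t2 = neighbor_joining(dm).as_string(schema="newick")
        assert t1 == t2


@pytest.fixture(scope="module")
def signal_alignment(two_clade_cohort):
    aln = Alignment.from_genomes(two_clade_cohort.genomes)
    return Alignment(aln.ids, aln.data[:, :40_000])


class TestBootstrap:
    def test_single_replicate_supports_binary(self, signal_alignment):
        tree = bootstrap_support(signal_alignment, n_reps=1, seed=0)
        supports = [
            node.support
            for node in tree.preorder_node_iter()
            if hasattr(node, "support")
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_deep_split_fully_supported(self, signal_alignment):
        tree = bootstrap_support(signal_alignment, n_reps=100, seed=1)
        ok, support = is_monophyletic(
            tree, {"A_s01", "A_s02", "A_s03"}, outgroup="B_s01"
        )
        assert ok and support >= 95

    def test_permuted_columns_destroy_support(self, signal_alignment):
        rng = np.random.default_rng(7)
        data = signal_alignment.data.copy()
        for col in range(data.shape[1]):  # permute strains independently per column
            data[:, col] = data[rng.permutation(data.shape[0]), col]
        aln = Alignment(list(signal_alignment.ids), data)
        tree = bootstrap_support(aln, n_reps=50, seed=2)
        supports = [
            node.support
            for node in tree.preorder_node_iter()
            if hasattr(node, "support")
        ]
        assert np.mean(supports) < 80

    def test_seed_determinism(self, signal_alignment):
        t1 = bootstrap_support(signal_alignment, n_reps=20, seed=9)
        t2 = bootstrap_support(signal_alignment, n_reps=20, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


@pytest.fixture(scope="module")
def tree():
    return dendropy.Tree.get(
        data="((a:1,b:1)90:1,(c:1,d:1)40:1,e:3);", schema="newick"
    )


class TestMonophyly:
    def test_all_leaves_trivially_monophyletic(self, tree):
        assert is_monophyletic(tree, {"a", "b", "c", "d", "e"}) == (True, 100.0)

    def test_single_tip_trivially_monophyletic(self, tree):
        assert is_monophyletic(tree, {"c"}) == (True, 100.0)

    def test_supported_clade_passes(self, tree):
        ok, support = is_monophyletic(tree, {"a", "b"}, min_support=90, outgroup="e")
        assert ok and support == 90.0
        # at the default 95% requirement the same clade is insufficient
        assert is_monophyletic(tree, {"a", "b"}, outgroup="e") == (False, 90.0)

    def test_weakly_supported_clade_fails(self, tree):
        ok, support = is_monophyletic(tree, {"c", "d"}, outgroup="e")
        assert not ok and support == 40.0

    def test_non_clade_fails(self, tree):
        assert is_monophyletic(tree, {"a", "c"}, outgroup="e") == (False, 0.0)

    def test_unrooted_tree_requires_outgroup(self, tree):
        with pytest.raises(ValueError, match="outgroup"):
            is_monophyletic(tree, {"a", "b"})

    def test_tips_outside_tree_rejected(self, tree):
        with pytest.raises(ValueError, match="subset"):
            is_monophyletic(tree, {"a", "zz"}, outgroup="e")


def test_distance_matrix_symmetry_and_zero_diagonal(two_clade_cohort):
    aln = Alignment.from_genomes(two_clade_cohort.genomes)
    sub = Alignment(aln.ids, aln.data[:, :30_000])
    dm = distance_matrix(sub, DistanceConfig(model="tn93"))
    np.testing.assert_allclose(dm.values, dm.values.T)
    np.testing.assert_allclose(np.diag(dm.values), 0.0)
    assert (dm.values >= 0).all()
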