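"""Neighbor joining: additive recovery, tie-breaks, oracle equivalence, bootstrap."""

import itertools

import numpy as np
import pytest

from hoxsurvey.distances import encode_nuc, k2p_matrix
from hoxsurvey.trees import Tree, bipartition, bootstrap_support, nj_tree


def random_additive_case(rng, n_taxa):
    """A random binary tree and its exact path-length matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # random sequential attachment ("stepwise addition") with random lengths
    edges = []
    next_node = n_taxa
    blen = lambda: float(rng.uniform(0.1, 2.0))
    # start from a 2-star via an internal node joining t0, t1, t2
    center = next_node
    next_node += 1
    edges = [(center, 0, blen()), (center, 1, blen()), (center, 2, blen())]
    for leaf in range(3, n_taxa):
        u, v, w = edges[rng.integers(len(edges))]
        edges.remove((u, v, w))
        mid = next_node
        next_node += 1
        w1 = w * float(rng.uniform(0.2, 0.8))
        edges.extend([(u, mid, w1), (mid, v, w - w1), (mid, leaf, blen())])
    tree = Tree(labels, edges, next_node)
    return tree, tree.path_distances()


def test_nj_four_taxon_additive_exact():
    # ((A:1,B:2):1,(C:3,D:4)) as an additive matrix
    d = np.array(
        [[0, 3, 5, 6],
         [3, 0, 6, 7],
         [5, 6, 0, 7],
         [6, 7, 7, 0]], dtype=float)
    tree = nj_tree(d, list("ABCD"))
    assert tree.bipartitions() == {bipartition({"A", "B"}, "ABCD")}
    assert np.allclose(tree.path_distances(), d, atol=1e-9)


def test_nj_three_point_formulas():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = nj_tree(d, list("ABC"))
    adj = tree.adjacency()
    lengths = {}
    for u, v, w in tree.edges:
        leaf = min(u, v)
        lengths[tree.leaf_labels[leaf]] = w
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def test_nj_all_equal_distances_tie_break_is_deterministic():
    d = np.ones((5, 5)) - np.eye(5)
    labels = list("EDCBA")
    t1 = nj_tree(d, labels)
    t2 = nj_tree(d.copy(), list(labels))
    assert t1.newick() == t2.newick()
    assert np.allclose(t1.path_distances().diagonal(), 0)


def test_nj_two_taxa_degenerate():
    t = nj_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
    assert t.path_distances()[0, 1] == pytest.approx(3.0)


def test_nj_rejects_bad_input():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 3)), ["a", "b"])
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "a"])


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(4, 9))
        true_tree, d = random_additive_case(rng, n)
        est = nj_tree(d, true_tree.leaf_labels)
        assert est.bipartitions() == true_tree.bipartitions()
        assert np.allclose(est.path_distances(), d, atol=1e-8)


def _ls_fit_error(d, labels, splits):
    """Least-squares branch fit of a topology given by its splits; 0 iff additive on it."""
    n = len(labels)
    # edges: one per leaf + one per split
    cols = []
    universe = frozenset(labels)
    groups = [frozenset({l}) for l in labels] + list(splits)
    pairs = list(itertools.combinations(range(n), 2))
    a = np.zeros((len(pairs), len(groups)))
    y = np.array([d[i, j] for i, j in pairs])
    for e, g in enumerate(groups):
        for r, (i, j) in enumerate(pairs):
            # edge on path iff it separates i from j
            if (labels[i] in g) != (labels[j] in g):
                a[r, e] = 1.0
    x, *_ = np.linalg.lstsq(a, y, rcond=None)
    return float(((a @ x - y) ** 2).sum())


def all_five_taxon_topologies(labels):
    """The 15 unrooted binary topologies on 5 leaves, as split sets.

    Every such topology has exactly two cherries; enumerate cherry pairs.
    """
    seen = set()
    for cherry1 in itertools.combinations(labels, 2):
        for cherry2 in itertools.combinations([l for l in labels if l not in cherry1], 2):
            splits = frozenset(
                {bipartition(set(cherry1), labels), bipartition(set(cherry2), labels)}
            )
            seen.add(splits)
    return sorted(seen, key=sorted)


def test_nj_equals_minimum_evolution_on_additive_five_taxon():
    """On additive 5-taxon matrices the zero-error topology is unique and NJ finds it."""
    rng = np.random.default_rng(7)
    labels = [f"t{i}" for i in range(5)]
    for _ in range(40):
        true_tree, d = random_additive_case(rng, 5)
        best = min(
            all_five_taxon_topologies(labels),
            key=lambda splits: _ls_fit_error(d, labels, splits),
        )
        assert _ls_fit_error(d, labels, best) < 1e-12
        assert set(best) == nj_tree(d, labels).bipartitions()


def test_newick_roundtrips_through_dendropy():
    rng = np.random.default_rng(3)
    _, d = random_additive_case(rng, 6)
    tree = nj_tree(d, [f"t{i}" for i in range(6)])
    import dendropy

    parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
    assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(tree.leaf_labels)


# -- bootstrap -----------------------------------------------------------------

def _nt_builder(labels):
    def build(cols):
        return nj_tree(k2p_matrix(cols), labels)

    return build


def test_bootstrap_two_clean_clades_high_support(rng):
    a = "ACGT" * 30
    b = "TGCA" * 30
    seqs = {
        "a1": a, "a2": a[:-1] + "G",
        "b1": b, "b2": b[:-1] + "C",
    }
    labels = list(seqs)
    cols = np.vstack([encode_nuc(seqs[l]) for l in labels])
    tree, support = bootstrap_support(cols, labels, _nt_builder(labels), 100, seed=5)
    split = bipartition({"a1", "a2"}, labels)
    assert support[split] >= 95


def test_bootstrap_single_replicate_support_is_binary(rng):
    cols = rng.integers(0, 4, size=(5, 40)).astype(np.int8)
    labels = [f"s{i}" for i in range(5)]
    _, support = bootstrap_support(cols, labels, _nt_builder(labels), 1, seed=9)
    assert set(support.values()) <= {0.0, 100.0}


def test_bootstrap_reproducible_for_fixed_seed(rng):
    cols = rng.integers(0, 4, size=(6, 60)).astype(np.int8)
    labels = [f"s{i}" for i in range(6)]
    _, s1 = bootstrap_support(cols, labels, _nt_builder(labels), 50, seed=11)
    _, s2 = bootstrap_support(cols, labels, _nt_builder(labels), 50, seed=11)
    assert s1 == s2


def test_bootstrap_rejects_degenerate_alignment():
    with pytest.raises(ValueError):
        bootstrap_support(np.zeros((3, 1), dtype=np.int8), list("abc"),
                          _nt_builder(list("abc")), 10, seed=1)
    with pytest.raises(ValueError):
        bootstrap_support(np.zeros((3, 10), dtype=np.int8), list("abc"),
                          _nt_builder(list("abc")), 0, seed=1)
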