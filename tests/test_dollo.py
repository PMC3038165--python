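"""Dollo parsimony: loss counting, ancestral reconstruction, topology tests."""

import itertools

import numpy as np
import pytest

from hoxsurvey.dollo import (
    compare_topologies,
    dollo_min_losses,
    load_topologies,
    parse_tree,
    reconstruct_ancestral,
)
from hoxsurvey.inventory import load_presence_matrix, reported_inventories
from hoxsurvey.pipeline import amniote_states, amphibian_states

AMNIOTES = ["mammal", "turtle", "squamate", "bird", "crocodile"]
HOXC3 = {"mammal": 0, "turtle": 0, "squamate": 1, "bird": 0, "crocodile": 0}


def exhaustive_min_losses(tree, states, root_state):
    """Oracle: minimise over every single-gain, irreversible-loss history.

    A history is a set of loss edges below the gain node; it is consistent
    iff a leaf is absent exactly when some loss edge lies on its root path
    (unknown leaves are unconstrained).
    """
    tree = parse_tree(tree)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    present = {l for l in leaves if states[l] == 1}
    absent = {l for l in leaves if states[l] == 0}
    gain = tree.seed_node if root_state == "present" else tree.mrca(taxon_labels=present)
    # candidate loss edges: every node in the gain subtree (cutting its
    # parent edge) including the gain node itself
    nodes = [n for n in gain.preorder_iter()]
    leafsets = []
    for n in nodes:
        leafsets.append(frozenset(l.taxon.label for l in n.leaf_iter()))
    below_gain = frozenset(l.taxon.label for l in gain.leaf_iter())
    absent_inside = absent & below_gain  # leaves outside the gain clade are absent for free
    best = None
    for r in range(len(nodes) + 1):
        if best is not None:
            break
        for combo in itertools.combinations(range(len(nodes)), r):
            lost = set().union(*(leafsets[i] for i in combo)) if combo else set()
            if absent_inside <= lost and not (lost & present):
                best = r
                break
    return best


def random_tree_and_states(rng, n_leaves):
    import dendropy

    taxa = [f"t{i}" for i in range(n_leaves)]
    # random coalescent-style topology
    nodes = [dendropy.Node() for _ in taxa]
    ns = dendropy.TaxonNamespace(taxa)
    for node, label in zip(nodes, taxa):
        node.taxon = ns.get_taxon(label)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[0])
    states = {t: int(rng.random() < 0.5) for t in taxa}
    return tree, states


def test_all_present_no_losses():
    tree = "(a,(b,(c,d)));"
    count = dollo_min_losses(tree, {t: 1 for t in "abcd"})
    assert count.losses == 0


def test_hoxc3_hypothesis_a_three_losses():
    topo = load_topologies()["hypothesis_A"]
    count = dollo_min_losses(topo, HOXC3, root_state="present")
    assert count.losses == 3
    assert frozenset({"mammal"}) in count.loss_clades
    assert frozenset({"bird", "crocodile"}) in count.loss_clades


def test_hoxc3_hypothesis_c_two_losses():
    topo = load_topologies()["hypothesis_C"]
    count = dollo_min_losses(topo, HOXC3, root_state="present")
    assert count.losses == 2
    assert frozenset({"turtle", "bird", "crocodile"}) in count.loss_clades


def test_all_absent_with_forced_root_is_single_loss():
    count = dollo_min_losses("(a,(b,c));", {"a": 0, "b": 0, "c": 0},
                             root_state="present")
    assert count.losses == 1
    with pytest.raises(ValueError):
        dollo_min_losses("(a,(b,c));", {"a": 0, "b": 0, "c": 0},
                         root_state="derive")


def test_unknown_leaves_absorb_no_events():
    states = {"a": 1, "b": None, "c": 0, "d": None}
    count = dollo_min_losses("((a,b),(c,d));", states, root_state="present")
    assert count.losses == 1
    assert count.loss_clades == [frozenset({"c", "d"})] or count.loss_clades == [
        frozenset({"c"})
    ]


def test_derive_places_gain_at_mrca():
    states = {"a": 0, "b": 1, "c": 1, "d": 0}
    count = dollo_min_losses("(a,((b,c),d));", states, root_state="derive")
    assert count.gain_clade == frozenset({"b", "c"})
    assert count.losses == 0


def test_missing_leaf_state_is_an_error():
    with pytest.raises(KeyError):
        dollo_min_losses("(a,b);", {"a": 1})


def test_dollo_matches_exhaustive_oracle_on_random_trees():
    rng = np.random.default_rng(101)
    checked = 0
    for _ in range(400):
        n = int(rng.integers(3, 9))
        tree, states = random_tree_and_states(rng, n)
        for root_state in ("present", "derive"):
            if root_state == "derive" and not any(states.values()):
                continue
            got = dollo_min_losses(tree, states, root_state=root_state).losses
            want = exhaustive_min_losses(tree, states, root_state)
            assert got == want, (tree.as_string(schema="newick"), states, root_state)
            checked += 1
    assert checked >= 400


def test_loss_count_monotone_under_absence_pruning():
    rng = np.random.default_rng(55)
    for _ in range(50):
        tree, states = random_tree_and_states(rng, 7)
        absent = [t for t, v in states.items() if v == 0]
        if not absent:
            continue
        full = dollo_min_losses(tree, states, root_state="present").losses
        pruned_tree = parse_tree(tree.as_string(schema="newick"))
        drop = absent[0]
        pruned_tree.prune_taxa_with_labels([drop])
        sub = {t: v for t, v in states.items() if t != drop}
        pruned = dollo_min_losses(pruned_tree, sub, root_state="present").losses
        assert pruned <= full


# -- ancestral reconstruction ---------------------------------------------------

def test_reconstruction_conserves_leaf_states():
    matrix = load_presence_matrix()
    topo = load_topologies()["accepted"]
    recon = reconstruct_ancestral(topo, matrix)
    for taxon in matrix.taxa:
        leaf_genes = recon.node_sets[frozenset({taxon})]
        assert leaf_genes == matrix.gene_set(taxon).genes, taxon


def test_sarcopterygian_root_retains_lost_genes():
    matrix = load_presence_matrix()
    recon = reconstruct_ancestral(
        load_topologies()["accepted"], matrix, root_state="present"
    )
    root = recon.node_sets[frozenset(matrix.taxa)]
    assert {"A14", "B10", "C1", "C3", "D12", "D13", "B13"} <= root
    assert len(root) == 43


def test_reconstruction_requires_matching_leaf_set():
    matrix = load_presence_matrix()
    with pytest.raises(ValueError):
        reconstruct_ancestral("(lungfish,frog);", matrix)


def test_single_taxon_tree_reproduces_inventory():
    matrix = load_presence_matrix()
    sub = type(matrix)(matrix.frame.loc[["frog"]])
    recon = reconstruct_ancestral("(frog);", sub)
    assert recon.node_sets[frozenset({"frog"})] == reported_inventories()["frog"].genes


# -- topology comparisons --------------------------------------------------------

def test_hoxc3_evaluation_over_four_hypotheses():
    topo = load_topologies()
    trees = {k: topo[f"hypothesis_{k}"] for k in "ABCD"}
    counts, best = compare_topologies(HOXC3, trees, root_state="present")
    assert counts.to_dict() == {"A": 3, "B": 3, "C": 2, "D": 2}
    assert best == {"C", "D"}


def test_hoxc1_favors_batrachia():
    matrix = load_presence_matrix()
    topo = load_topologies()
    states = amphibian_states(matrix, "C1")
    counts, best = compare_topologies(
        states,
        {"batrachia": topo["batrachia"],
         "caecilian_salamander": topo["caecilian_salamander"]},
        root_state="present",
    )
    assert counts["batrachia"] < counts["caecilian_salamander"]
    assert best == {"batrachia"}


def test_identical_trees_identical_counts():
    topo = load_topologies()["hypothesis_A"]
    counts, _ = compare_topologies(
        HOXC3, {"x": topo, "y": parse_tree(topo.as_string(schema="newick"))}
    )
    assert counts["x"] == counts["y"]


def test_compare_topologies_rejects_leaf_mismatch():
    with pytest.raises(ValueError):
        compare_topologies({"a": 1, "b": 0}, {"t1": "(a,b);", "t2": "(a,c);"})


def test_amniote_states_collapse():
    matrix = load_presence_matrix()
    assert amniote_states(matrix, "C3") == HOXC3
    assert amniote_states(matrix, "A13") == {t: 1 for t in AMNIOTES}
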