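"""Dollo parsimony over gene presence/absence characters.

Under Dollo's principle a gene is gained exactly once and losses are
irreversible, so for a single character on a rooted tree the minimal history
is fully determined: the gain sits at the root (when outgroup evidence forces
ancestral presence) or at the MRCA of the present leaves, and the loss events
are the maximal subtrees below the gain containing no present leaf. Leaves
with unknown state are ignored for that character.

Topologies are exchanged as Newick via dendropy; the packaged table carries
the four turtle-placement hypotheses, the working sarcopterygian tree and
the alternative amphibian arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .inventory import PresenceMatrix, UNIVERSE

__all__ = [
    "load_topologies",
    "parse_tree",
    "DolloCount",
    "dollo_min_losses",
    "DolloReconstruction",
    "reconstruct_ancestral",
    "compare_topologies",
]


def parse_tree(newick: str | dendropy.Tree) -> dendropy.Tree:
    """Parse a rooted Newick topology."""
    if isinstance(newick, dendropy.Tree):
        newick.is_rooted = True
        return newick
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def load_topologies() -> dict[str, dendropy.Tree]:
    """Packaged named topologies (turtle hypotheses A-D, accepted tree, ...)."""
    text = resources.files("hoxsurvey").joinpath("data/topologies.tsv").read_text()
    out: dict[str, dendropy.Tree] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, newick = line.split("\t")
        out[name] = parse_tree(newick)
    return out


@dataclass
class DolloCount:
    losses: int
    loss_clades: list[frozenset[str]]   # leaf sets under each loss edge
    gain_clade: frozenset[str]          # leaf set under the gain node
    root_present: bool


def _leaf_states(
    tree: dendropy.Tree, states: Mapping[str, int | None]
) -> dict:
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = leaves - set(states)
    if missing:
        raise KeyError(f"no state for leaf taxa: {sorted(missing)}")
    return {leaf: states[leaf] for leaf in leaves}


def dollo_min_losses(
    tree: str | dendropy.Tree,
    states: Mapping[str, int | None],
    root_state: str = "derive",
) -> DolloCount:
    """Minimum-loss Dollo history of one presence/absence character.

    ``root_state='present'`` forces ancestral presence (used when outgroups
    outside the tree carry the gene); ``'derive'`` places the gain at the
    MRCA of the present leaves. Returns the loss count, the leaf set under
    each loss edge, and the gain clade. Unknown (None) leaves constrain
    nothing and absorb no events.
    """
    if root_state not in ("present", "derive"):
        raise ValueError("root_state must be 'present' or 'derive'")
    tree = parse_tree(tree)
    st = _leaf_states(tree, states)
    present = {l for l, v in st.items() if v == 1}
    if root_state == "derive" and not present:
        raise ValueError("all-absent character: gain node undefined under 'derive'")

    # annotate subtree composition
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            node.n_present = 1 if st[lab] == 1 else 0
            node.n_absent = 1 if st[lab] == 0 else 0
            node.leafset = frozenset({lab})
        else:
            node.n_present = sum(c.n_present for c in node.child_nodes())
            node.n_absent = sum(c.n_absent for c in node.child_nodes())
            node.leafset = frozenset().union(*(c.leafset for c in node.child_nodes()))

    if root_state == "present":
        gain = tree.seed_node
    else:
        gain = tree.mrca(taxon_labels=present)

    loss_clades: list[frozenset[str]] = []

    def collect(node) -> None:
        # maximal subtrees with no present leaf and at least one absent leaf
        if node.n_present == 0:
            if node.n_absent > 0:
                loss_clades.append(node.leafset)
            return
        for child in node.child_nodes():
            collect(child)

    collect(gain)
    loss_clades.sort(key=lambda s: (len(s), sorted(s)))
    return DolloCount(
        losses=len(loss_clades),
        loss_clades=loss_clades,
        gain_clade=gain.leafset,
        root_present=(gain is tree.seed_node),
    )


@dataclass
class DolloReconstruction:
    """Per-node ancestral gene sets and per-gene loss events on one topology."""

    tree: dendropy.Tree
    node_sets: dict[frozenset[str], frozenset[str]]     # clade leafset -> genes
    losses: dict[str, list[frozenset[str]]]             # gene -> loss clades
    gains: dict[str, frozenset[str]]                    # gene -> gain clade
    loss_counts: dict[str, int] = field(default_factory=dict)

    def ancestral_genes(self, taxa: Iterable[str]) -> frozenset[str]:
        """Gene set at the MRCA-defined node for an exact clade leaf set."""
        return self.node_sets[frozenset(taxa)]

    def losses_table(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "losses": len(clades),
             "loss_clades": ";".join(",".join(sorted(c)) for c in clades)}
            for g, clades in sorted(self.losses.items())
        ]
        return pd.DataFrame(rows)

    def annotated_newick(self) -> str:
        """Newick with per-edge loss events as comments."""
        tree = self.tree.clone(depth=1)
        by_clade: dict[frozenset[str], list[str]] = {}
        for gene, clades in self.losses.items():
            for c in clades:
                by_clade.setdefault(c, []).append(gene)
        for node in tree.postorder_node_iter():
            leafset = frozenset(
                l.taxon.label for l in node.leaf_iter()
            )
            lost = by_clade.get(leafset)
            if lost:
                label = "-" + ",-".join(sorted(lost))
                if node.is_leaf():
                    node.taxon.label = f"{node.taxon.label}[{label}]"
                else:
                    node.label = f"[{label}]"
        return tree.as_string(schema="newick").strip()


def reconstruct_ancestral(
    tree: str | dendropy.Tree,
    matrix: PresenceMatrix,
    root_state: Mapping[str, str] | str = "derive",
) -> DolloReconstruction:
    """Compose per-gene Dollo histories into ancestral inventories.

    ``root_state`` may be a single policy or a per-gene mapping. Leaf rows of
    the matrix are reproduced exactly (conservation); ancestral nodes carry a
    gene iff they lie inside its gain clade and outside every loss clade.
    """
    tree = parse_tree(tree)
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaves != set(matrix.taxa):
        raise ValueError(
            f"tree leaves and matrix taxa differ: {sorted(leaves ^ set(matrix.taxa))}"
        )
    losses: dict[str, list[frozenset[str]]] = {}
    gains: dict[str, frozenset[str]] = {}
    for gene in matrix.genes:
        states = matrix.states(gene)
        if not any(v == 1 for v in states.values()):
            continue
        policy = root_state if isinstance(root_state, str) else root_state.get(gene, "derive")
        count = dollo_min_losses(tree, states, root_state=policy)
        losses[gene] = count.loss_clades
        gains[gene] = count.gain_clade

    node_sets: dict[frozenset[str], frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        leafset = frozenset(l.taxon.label for l in node.leaf_iter())
        genes = set()
        for gene, gain_clade in gains.items():
            if not leafset <= gain_clade:
                continue
            if any(leafset <= lc for lc in losses[gene]):
                continue
            if node.is_leaf():
                # reproduce observed leaf states exactly, unknowns excluded
                taxon = next(iter(leafset))
                state = matrix.states(gene)[taxon]
                if state == 1:
                    genes.add(gene)
                continue
            genes.add(gene)
        node_sets[leafset] = frozenset(genes)
    counts = {g: len(c) for g, c in losses.items()}
    return DolloReconstruction(tree, node_sets, losses, gains, counts)


def compare_topologies(
    states: Mapping[str, int | None],
    trees: Mapping[str, str | dendropy.Tree],
    root_state: str = "present",
) -> tuple[pd.Series, set[str]]:
    """Dollo loss counts of one character across named alternative topologies.

    Returns the per-topology counts and the argmin set. All topologies must
    share one leaf set.
    """
    leafsets = set()
    parsed = {name: parse_tree(t) for name, t in trees.items()}
    for t in parsed.values():
        leafsets.add(frozenset(l.taxon.label for l in t.leaf_node_iter()))
    if len(leafsets) != 1:
        raise ValueError("topologies do not share a common leaf set")
    counts = pd.Series(
        {
            name: dollo_min_losses(t, states, root_state=root_state).losses
            for name, t in parsed.items()
        },
        dtype=int,
    )
    best = set(counts[counts == counts.min()].index)
    return counts, best
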