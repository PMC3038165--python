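"""Synthetic survey worlds with known ground truth.

Every input the pipeline consumes can be generated here: per-gene 180-nt
homeobox roots whose primer-motif blocks sit at canonical homeodomain
coordinates, a reference panel evolved from those roots along a small guide
tree, genomic templates for a taxon with a chosen true inventory, and
degenerate-PCR clone libraries containing allelic variants (synonymous,
multi-clone) and PCR/sequencing errors (non-synonymous singletons).

The root set is a fixed, deterministic "stated world": each paralogue group
carries its diagnostic N-arm and recognition-helix motifs (so the packaged
primer table amplifies it with the survey's product sizes), members of a
group differ at a handful of free residues, and the central groups (2, 6-8)
are deliberately protein-identical within the group — distinguishable only
by synonymous codon choices — which is what forces the nucleotide-level
assignment path. Codon positions under primer motifs are held fixed during
evolution (the purifying selection that makes degenerate priming work);
motif codons with restricted degeneracy are sampled from the allowed subset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assign import HOMEOBOX_NT, OUTGROUP_GENE, PanelEntry, ReferencePanel
from .clones import CloneRecord, FilterResult
from .inventory import PresenceMatrix, UNIVERSE, gene_pg
from .primers import (
    Amplicon,
    DegeneratePrimer,
    in_silico_pcr,
    pair_primers,
    validate_primer_motif,
)
from .seq import STANDARD_CODE, translate

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "root_proteins",
    "root_homeoboxes",
    "anchored_positions",
    "default_guide_tree",
    "evolve_panel",
    "make_templates",
    "simulate_library",
    "simulate_taxon_libraries",
    "recovery_report",
    "filter_metrics",
    "SURVEY_TAXA",
    "write_ground_truth_tsv",
]

_ROOT_SEED = 7919  # the stated world: fixed, independent of user seeds

#: Canonical 60-residue homeodomain scaffold.
_SCAFFOLD = "RKRGRQTYTRYQTLELEKEFHFNRYLTRRRRIEIAHALCLTERQIKIWFQNRRMKWKKEN"
assert len(_SCAFFOLD) == 60

_CODE = STANDARD_CODE
_MGV_R = ("AGA", "AGG", "CGA", "CGC", "CGG")   # MGV-compatible Arg codons
_TCN_S = ("TCA", "TCC", "TCG", "TCT")          # TCN-only Ser codons

#: Lineages surveyed by sequencing in the demo world.
SURVEY_TAXA = ("lungfish", "caecilian", "salamander", "snake", "turtle", "crocodile")


def _motif(pos: int, residues: str, anchored: bool = True):
    return (pos, residues, anchored)


#: Family layouts: member genes, motif placements (1-based homeodomain
#: positions; anchored motifs are frozen during evolution because a survey
#: primer reads them), and codon restrictions imposed by partially
#: degenerate primer codons.
_FAMILIES: dict[str, dict] = {
    "PG1": {
        "genes": ("A1", "B1", "C1", "D1"),
        "motifs": [_motif(6, "NFTTKQLT"), _motif(14, "LELEKEFH")],
        "constraints": {},
    },
    "PG2": {
        "genes": ("A2", "B2"),
        "motifs": [_motif(5, "RTAYTNTQT"), _motif(14, "LELEKEFH")],
        "constraints": {5: ("AGG", "CGG")},
        "protein_identical": True,
    },
    "PG3": {
        "genes": ("A3", "B3", "C3", "D3"),
        "motifs": [_motif(6, "AYTSAQLV"), _motif(14, "LELEKEFH"),
                   _motif(29, "RPRRVEMA")],
        "constraints": {9: ("AGC", "AGT"), 29: _MGV_R, 31: _MGV_R, 32: _MGV_R},
    },
    "PG4": {
        "genes": ("A4", "B4", "C4", "D4"),
        "motifs": [_motif(5, "TAYTRQQVT"), _motif(14, "LELEKEFH")],
        "constraints": {},
    },
    "PG5": {
        "genes": ("A5", "B5"),
        "motifs": [_motif(1, "GKRARTA"), _motif(14, "LELEKEFH")],
        "constraints": {3: ("AGG", "CGC", "CGG"), 5: ("AGG", "CGC", "CGG")},
    },
    "C5": {
        # the divergent member the general primers miss: no QTYTRYQT arm and
        # a D17 that breaks the ELEKEF-block primers; only HoxFC5 finds it
        "genes": ("C5",),
        "motifs": [_motif(2, "KRSRTSYT"), _motif(14, "LELDKEFH")],
        "constraints": {3: ("CGA", "CGC", "CGG", "CGT"), 4: ("TCC", "TCT"),
                        5: ("AGA", "CGA"), 7: ("AGC", "AGT")},
    },
    "PG6": {
        "genes": ("A6", "B6", "C6"),
        "motifs": [_motif(6, "QTYTRYQT"), _motif(14, "LELEKEFH")],
        "constraints": {},
        "protein_identical": True,
    },
    "PG7": {
        "genes": ("A7", "B7"),
        "motifs": [_motif(6, "QTYTRYQT"), _motif(14, "LELEKEFH")],
        "constraints": {},
        "protein_identical": True,
    },
    "PG8": {
        "genes": ("B8", "C8", "D8"),
        "motifs": [_motif(6, "NTFTRYQT", anchored=False),
                   _motif(14, "LELEKEFLFNP")],
        "constraints": {},
        "protein_identical": True,
    },
    "PG9": {
        "genes": ("A9", "B9", "C9", "D9"),
        "motifs": [_motif(1, "TRKKRCPYTKHQT"), _motif(14, "LELEKEFLFNM")],
        "constraints": {},
    },
    "PG10": {
        "genes": ("A10", "B10", "C10", "D10"),
        "motifs": [_motif(1, "TRKKRCPYTKHQT"), _motif(14, "LELEKEFLFNS")],
        "constraints": {},
    },
    "PG11": {
        "genes": ("A11", "C11", "D11"),
        "motifs": [_motif(1, "TRKKRCPYTKHQT"), _motif(14, "LELEREFFFN")],
        "constraints": {},
    },
    "C12": {
        "genes": ("C12",),
        "motifs": [_motif(1, "SRKKRKPYSKLQI"), _motif(14, "LELEKEFH")],
        "constraints": {1: _TCN_S, 2: _MGV_R, 5: _MGV_R, 7: ("CCC", "CCG"),
                        9: _TCN_S},
    },
    "D12": {
        "genes": ("D12",),
        "motifs": [_motif(1, "SRKKRKPYTKQQI"), _motif(14, "LELEKEFH")],
        "constraints": {1: _TCN_S, 2: _MGV_R, 5: _MGV_R, 7: ("CCC", "CCG")},
    },
    "A13": {
        "genes": ("A13",),
        "motifs": [_motif(1, "GRKKRVPY"), _motif(9, "TKHQ", anchored=False),
                   _motif(13, "QLKELEREY")],
        "constraints": {14: ("CTA", "CTG", "TTA", "TTG"),
                        17: ("CTA", "CTC", "CTG", "CTT")},
        "helix": "WFQNRRVK",
    },
    "B13": {
        "genes": ("B13",),
        "motifs": [_motif(1, "GRKKRIPY"), _motif(9, "TKHQ", anchored=False),
                   _motif(13, "QLKELENEY")],
        "constraints": {14: ("CTA", "CTG", "TTA", "TTG"),
                        17: ("CTA", "CTC", "CTG", "CTT")},
        "helix": "WFQNRRVK",
    },
    "CD13": {
        "genes": ("C13", "D13"),
        "motifs": [_motif(1, "GRKKRVPY"), _motif(9, "TKHQ", anchored=False),
                   _motif(13, "QLKELENEY")],
        "constraints": {14: ("CTA", "CTG", "TTA", "TTG"),
                        17: ("CTA", "CTC", "CTG", "CTT")},
        "helix": "WFQNRRVK",
    },
    "A14": {
        "genes": ("A14",),
        "motifs": [_motif(1, "GRKKRVPY"), _motif(23, "ENRFLTPE")],
        "constraints": {25: ("CGA", "CGC", "CGG", "CGT"),
                        27: ("CTA", "CTC", "CTG", "CTT")},
        "helix": "WFQNRRTK",
    },
}

_N_PG_SUBS = 4       # residues distinguishing paralogue groups
_N_GENE_SUBS = 6     # residues distinguishing members within a group
_RESIDUE_POOL = "ADEFGHIKLMNPQRSTVY"


def _rng_for(*parts) -> np.random.Generator:
    digest = zlib.crc32("|".join(str(p) for p in parts).encode()) % (2**31)
    return np.random.default_rng((_ROOT_SEED, digest))


def _family_of(gene: str) -> str:
    for fam, spec in _FAMILIES.items():
        if gene in spec["genes"]:
            return fam
    raise KeyError(gene)


def _family_template(fam: str) -> tuple[list[str], set[int], dict]:
    """(60-residue template, anchored 0-based codon positions, constraints)."""
    spec = _FAMILIES[fam]
    prot = list(_SCAFFOLD)
    anchored: set[int] = set()
    helix = spec.get("helix", "WFQNRRMK")
    motifs = list(spec["motifs"]) + [_motif(48, helix)]
    for pos, residues, anc in motifs:
        for k, aa in enumerate(residues):
            prot[pos - 1 + k] = aa
            if anc:
                anchored.add(pos - 1 + k)
    return prot, anchored, {p - 1: tuple(c) for p, c in spec["constraints"].items()}


@lru_cache(maxsize=1)
def root_proteins() -> dict[str, str]:
    """Deterministic 60-aa root homeodomains for the 43 genes plus the outgroup."""
    out: dict[str, str] = {}
    for fam, spec in _FAMILIES.items():
        prot, anchored, _ = _family_template(fam)
        fixed = set(anchored) | {
            i for i, aa in enumerate(prot) if aa != _SCAFFOLD[i]
        }
        free = sorted(set(range(60)) - fixed)
        fam_rng = _rng_for("family", fam)
        fam_pos = fam_rng.choice(free, size=_N_PG_SUBS, replace=False)
        fam_res = fam_rng.choice(list(_RESIDUE_POOL), size=_N_PG_SUBS)
        for gene in spec["genes"]:
            p = list(prot)
            for pos, aa in zip(fam_pos, fam_res):
                p[pos] = aa
            if not spec.get("protein_identical"):
                grng = _rng_for("gene", gene)
                remaining = [x for x in free if x not in set(fam_pos)]
                gpos = grng.choice(remaining, size=_N_GENE_SUBS, replace=False)
                for pos in gpos:
                    choices = [r for r in _RESIDUE_POOL if r != p[pos]]
                    p[pos] = grng.choice(choices)
            out[gene] = "".join(p)
    # a distant homeobox to root assignment trees
    orng = _rng_for("gene", OUTGROUP_GENE)
    p = list(_SCAFFOLD)
    opos = orng.choice(sorted(set(range(60)) - set(range(47, 55))), size=16,
                       replace=False)
    for pos in opos:
        p[pos] = orng.choice([r for r in _RESIDUE_POOL if r != p[pos]])
    out[OUTGROUP_GENE] = "".join(p)
    return out


@lru_cache(maxsize=1)
def root_homeoboxes() -> dict[str, str]:
    """Deterministic 180-nt roots; codon choices are gene-specific, so members
    of protein-identical groups differ synonymously."""
    prots = root_proteins()
    out: dict[str, str] = {}
    for gene, prot in prots.items():
        fam = _family_of(gene) if gene != OUTGROUP_GENE else None
        constraints = _family_template(fam)[2] if fam else {}
        grng = _rng_for("codons", gene)
        codons = []
        for i, aa in enumerate(prot):
            allowed = constraints.get(i) or sorted(_CODE.codons_for[aa])
            codons.append(str(grng.choice(list(allowed))))
        nt = "".join(codons)
        assert translate(nt, 0) == prot
        out[gene] = nt
    return out


@lru_cache(maxsize=None)
def anchored_positions(gene: str) -> frozenset[int]:
    """0-based nucleotide positions frozen during evolution (primer anchors)."""
    if gene == OUTGROUP_GENE:
        return frozenset()
    _, anchored, constraints = _family_template(_family_of(gene))
    codons = anchored | set(constraints)
    return frozenset(p for c in codons for p in (3 * c, 3 * c + 1, 3 * c + 2))


# --------------------------------------------------------------------------
# Configuration and ground truth
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Stated-world parameters for the synthetic survey.

    Rates are substitutions per site per unit branch length; branch lengths
    live on the guide tree / ``taxon_branch``. Defaults model shallow
    divergences of a strongly conserved coding region.
    """

    kappa: float = 2.0                   # transition/transversion rate ratio
    panel_guide_tree: str = "((sp1:0.02,sp2:0.02):0.02,sp3:0.04);"
    taxon_branch: float = 0.04           # surveyed taxon depth from the roots
    clones_mean: float = 8.0             # zero-truncated Poisson per amplicon
    p_allele: float = 0.3                # second haplotype per amplified locus
    p_error: float = 0.05                # per-clone PCR/sequencing error
    flank_len: tuple[int, int] = (60, 120)
    min_len: int = 80
    max_len: int = 165
    max_mismatch: int = 0
    tiers: tuple[str, ...] = ("general", "pg_specific", "member_specific")


@dataclass
class GroundTruth:
    """Provenance of everything the generator emitted."""

    taxa: dict[str, frozenset[str]] = field(default_factory=dict)
    clone_provenance: dict[str, str] = field(default_factory=dict)
    fragment_truth: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    #                 (library, sequence) -> (gene, faithful|allelic|error)

    def merge(self, other: "GroundTruth") -> None:
        self.taxa.update(other.taxa)
        self.clone_provenance.update(other.clone_provenance)
        self.fragment_truth.update(other.fragment_truth)


# --------------------------------------------------------------------------
# Sequence evolution (K2P process)
# --------------------------------------------------------------------------

_NT = "ACGT"
_IDX = {c: i for i, c in enumerate(_NT)}


def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after branch length d."""
    beta = d / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta)
    e2 = np.exp(-2.0 * (alpha + beta))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def evolve_sequence(
    seq: str,
    distance: float,
    kappa: float,
    rng: np.random.Generator,
    frozen: frozenset[int] = frozenset(),
    avoid_stops: bool = True,
) -> str:
    """One K2P draw per site over ``distance``; frozen sites never change.

    Codons that would become stops are reverted (purifying selection against
    nonsense changes, and panel proteins must translate cleanly).
    """
    if distance < 0:
        raise ValueError("negative branch length")
    arr = np.array([_IDX[c] for c in seq], dtype=np.int8)
    p_ts, p_tv = _k2p_probs(distance, kappa)
    u = rng.random(len(arr))
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    new = arr.copy()
    new[ts] = arr[ts] ^ 2                       # A<->G, C<->T
    new[tv1] = (arr[tv1] + 1) % 4               # to the other purine/pyrimidine pair
    new[tv2] = (arr[tv2] + 3) % 4
    if frozen:
        idx = np.fromiter(frozen, dtype=int)
        new[idx] = arr[idx]
    out = "".join(_NT[i] for i in new)
    if avoid_stops and len(out) % 3 == 0:
        chars = list(out)
        for c0 in range(0, len(chars), 3):
            codon = "".join(chars[c0 : c0 + 3])
            if _CODE.forward[codon] == "*":
                chars[c0 : c0 + 3] = seq[c0 : c0 + 3]
        out = "".join(chars)
    return out


def default_guide_tree() -> str:
    return SimulationConfig().panel_guide_tree


def evolve_panel(
    guide_tree: str | None = None,
    roots: Mapping[str, str] | None = None,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> ReferencePanel:
    """Evolve each gene root along the guide tree into a reference panel.

    Branch lengths of the guide tree are substitution distances. Primer
    anchor codons stay fixed so every panel entry remains amplifiable.
    """
    import dendropy

    cfg = cfg or SimulationConfig()
    roots = dict(roots) if roots is not None else root_homeoboxes()
    tree = dendropy.Tree.get(
        data=guide_tree or cfg.panel_guide_tree, schema="newick",
        rooting="force-rooted",
    )
    entries = []
    for gene in sorted(roots):
        root_nt = roots[gene]
        if translate(root_nt, 0) != root_proteins().get(gene, translate(root_nt, 0)):
            raise ValueError(f"root for {gene} violates its protein template")
        frozen = anchored_positions(gene)
        rng = np.random.default_rng(
            (int(seed) % (2**31), zlib.crc32(gene.encode()) % (2**31))
        )
        seqs: dict[int, str] = {id(tree.seed_node): root_nt}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent_seq = seqs[id(node.parent_node)]
            seqs[id(node)] = evolve_sequence(
                parent_seq, node.edge.length or 0.0, cfg.kappa, rng, frozen
            )
        for leaf in tree.leaf_node_iter():
            nt = seqs[id(leaf)]
            entries.append(
                PanelEntry(gene, leaf.taxon.label, nt, translate(nt, 0))
            )
    return ReferencePanel(entries)


# --------------------------------------------------------------------------
# Templates and clone libraries
# --------------------------------------------------------------------------

def make_templates(
    taxon: str,
    inventory: Iterable[str],
    cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """One genomic template per present gene: the taxon's homeobox (evolved
    from the gene root along ``taxon_branch``) embedded in random flanks."""
    cfg = cfg or SimulationConfig()
    genes = sorted(set(inventory))
    bad = set(genes) - set(UNIVERSE)
    if bad:
        raise ValueError(f"inventory outside the universe: {sorted(bad)}")
    roots = root_homeoboxes()
    out = []
    for gene in genes:
        rng = np.random.default_rng(
            (int(seed) % (2**31),
             zlib.crc32(f"{taxon}|{gene}".encode()) % (2**31))
        )
        hb = evolve_sequence(
            roots[gene], cfg.taxon_branch, cfg.kappa, rng, anchored_positions(gene)
        )
        lo, hi = cfg.flank_len
        left = "".join(rng.choice(list(_NT), size=int(rng.integers(lo, hi + 1))))
        right = "".join(rng.choice(list(_NT), size=int(rng.integers(lo, hi + 1))))
        out.append((f"{taxon}|{gene}", left + hb + right))
    return out


def _synonymous_single_site_options(seq: str, frame: int) -> list[tuple[int, str]]:
    opts = []
    start = frame
    while start + 3 <= len(seq):
        codon = seq[start : start + 3]
        aa = _CODE.forward[codon]
        for k in range(3):
            for b in _NT:
                if b == codon[k]:
                    continue
                alt = codon[:k] + b + codon[k + 1 :]
                if _CODE.forward[alt] == aa:
                    opts.append((start + k, b))
        start += 3
    return opts


def _nonsynonymous_single_site_options(seq: str, frame: int) -> list[tuple[int, str]]:
    opts = []
    start = frame
    while start + 3 <= len(seq):
        codon = seq[start : start + 3]
        aa = _CODE.forward[codon]
        for k in range(3):
            for b in _NT:
                if b == codon[k]:
                    continue
                alt = codon[:k] + b + codon[k + 1 :]
                if _CODE.forward[alt] != aa:
                    opts.append((start + k, b))
        start += 3
    return opts


def _apply(seq: str, changes: Sequence[tuple[int, str]]) -> str:
    chars = list(seq)
    for pos, b in changes:
        chars[pos] = b
    return "".join(chars)


def _pick_changes(
    options: list[tuple[int, str]], k: int, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """k single-nt changes in k distinct codons (independent differences)."""
    by_codon: dict[int, list[tuple[int, str]]] = {}
    for pos, b in options:
        by_codon.setdefault(pos // 3, []).append((pos, b))
    codons = list(by_codon)
    rng.shuffle(codons)
    picked = []
    for c in codons[:k]:
        opts = by_codon[c]
        picked.append(opts[int(rng.integers(len(opts)))])
    return picked


def _zt_poisson(mean: float, rng: np.random.Generator) -> int:
    n = 0
    while n == 0:
        n = int(rng.poisson(mean))
    return n


def simulate_library(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    taxon: str,
    templates: Sequence[tuple[str, str]],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[CloneRecord], int, GroundTruth]:
    """Clones for one species x primer-pair library.

    Returns (clones, frame_offset, truth slice). Each amplified locus yields
    a zero-truncated-Poisson clone count; with probability ``p_allele`` a
    second haplotype carrying 1-3 synonymous changes is present in >= 2
    clones; each clone independently acquires a 1-2 nt non-synonymous
    PCR/sequencing error with probability ``p_error`` (always a singleton
    haplotype in expectation).
    """
    library_id = f"{taxon}|{fwd.name}+{rev.name}"
    frame = validate_primer_motif(fwd) if fwd.aa_motif else 0
    truth = GroundTruth()
    clones: list[CloneRecord] = []
    counter = 0

    def emit(seq: str, provenance: str) -> None:
        nonlocal counter
        counter += 1
        cid = f"{library_id}|c{counter}"
        clones.append(CloneRecord(cid, library_id, seq))
        truth.clone_provenance[cid] = provenance

    for tid, tseq in templates:
        gene = tid.split("|")[-1]
        for amp in in_silico_pcr(
            fwd, rev, tseq, tid, cfg.min_len, cfg.max_len, cfg.max_mismatch
        ):
            n = _zt_poisson(cfg.clones_mean, rng)
            haplotypes = [(amp.sequence, n, "faithful")]
            if rng.random() < cfg.p_allele:
                n = max(n, 4)
                k = int(rng.integers(1, 4))
                opts = _synonymous_single_site_options(amp.sequence, frame)
                changes = _pick_changes(opts, k, rng)
                if changes:
                    minor = _apply(amp.sequence, changes)
                    n_minor = max(2, min(n - 2, int(round(n * 0.4))))
                    haplotypes = [
                        (amp.sequence, n - n_minor, "faithful"),
                        (minor, n_minor, "allelic"),
                    ]
            for hseq, hcount, kind in haplotypes:
                truth.fragment_truth[(library_id, hseq)] = (gene, kind)
                for _ in range(hcount):
                    if rng.random() < cfg.p_error:
                        k = int(rng.integers(1, 3))
                        opts = _nonsynonymous_single_site_options(hseq, frame)
                        for _attempt in range(10):
                            eseq = _apply(hseq, _pick_changes(opts, k, rng))
                            if (library_id, eseq) not in truth.fragment_truth:
                                break
                        else:
                            emit(hseq, kind)
                            continue
                        truth.fragment_truth[(library_id, eseq)] = (gene, "error")
                        emit(eseq, "error")
                    else:
                        emit(hseq, kind)
    return clones, frame, truth


def simulate_taxon_libraries(
    taxon: str,
    inventory: Iterable[str],
    primers: Sequence[DegeneratePrimer],
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    templates: Sequence[tuple[str, str]] | None = None,
) -> tuple[dict[str, tuple[list[CloneRecord], int]], GroundTruth]:
    """All primer-pair libraries for one taxon with a known true inventory."""
    cfg = cfg or SimulationConfig()
    if templates is None:
        templates = make_templates(taxon, inventory, cfg, seed)
    truth = GroundTruth(taxa={taxon: frozenset(inventory)})
    libraries: dict[str, tuple[list[CloneRecord], int]] = {}
    for fwd, rev in pair_primers(primers):
        if fwd.tier not in cfg.tiers:
            continue
        rng = np.random.default_rng(
            (int(seed) % (2**31),
             zlib.crc32(f"{taxon}|{fwd.name}|{rev.name}".encode()) % (2**31))
        )
        clones, frame, t = simulate_library(fwd, rev, taxon, templates, cfg, rng)
        if clones:
            libraries[f"{taxon}|{fwd.name}+{rev.name}"] = (clones, frame)
            truth.merge(t)
    return libraries, truth


# --------------------------------------------------------------------------
# Recovery metrics
# --------------------------------------------------------------------------

def recovery_report(inferred: PresenceMatrix, truth: GroundTruth) -> pd.DataFrame:
    """Per-taxon inventory accuracy against the generator's truth.

    Accuracy is the fraction of the 43 universe genes whose presence/absence
    call matches the truth; false absences are genes present in truth but not
    called, false presences the reverse.
    """
    rows = []
    for taxon in inferred.taxa:
        if taxon not in truth.taxa:
            raise KeyError(f"no ground truth for taxon {taxon!r}")
        true_genes = truth.taxa[taxon]
        called = inferred.gene_set(taxon).genes
        fa = sorted(true_genes - called)
        fp = sorted(called - true_genes)
        correct = len(UNIVERSE) - len(fa) - len(fp)
        rows.append(
            {
                "taxon": taxon,
                "accuracy": correct / len(UNIVERSE),
                "false_absences": len(fa),
                "false_presences": len(fp),
                "missed_genes": ",".join(fa),
                "spurious_genes": ",".join(fp),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def filter_metrics(
    results: Mapping[str, FilterResult], truth: GroundTruth
) -> dict[str, float]:
    """Precision/recall of artifact exclusion against clone provenance."""
    tp = fp = fn = 0
    for library_id, res in results.items():
        def _is_error(seq: str) -> bool:
            rec = truth.fragment_truth.get((library_id, seq))
            return rec is not None and rec[1] == "error"

        for frag in res.artifacts:
            if _is_error(frag.sequence):
                tp += 1
            else:
                fp += 1
        for frag in res.fragments:
            if _is_error(frag.sequence):
                fn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}


def write_ground_truth_tsv(path, truth: GroundTruth) -> None:
    """Ground truth as TSV: per-taxon inventories and per-fragment provenance."""
    with open(path, "w") as fh:
        fh.write("record\tkey\tvalue\n")
        for taxon in sorted(truth.taxa):
            fh.write(f"taxon_inventory\t{taxon}\t{','.join(sorted(truth.taxa[taxon]))}\n")
        for (lib, seq), (gene, kind) in sorted(truth.fragment_truth.items()):
            fh.write(f"fragment\t{lib}|{seq}\t{gene}:{kind}\n")
        for cid in sorted(truth.clone_provenance):
            fh.write(f"clone\t{cid}\t{truth.clone_provenance[cid]}\n")
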