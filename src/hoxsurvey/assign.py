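"""Ortholog assignment of homeobox fragments against a reference panel.

The panel is an ungapped positional alignment of 180-nt homeoboxes (the
homeobox is a fixed-length, indel-free region, so gapped multiple alignment
is unnecessary). A validated fragment is first anchored: the ungapped offset
(and orientation) maximising protein-level identity to the panel consensus
determines which alignment columns it covers; fragments below the identity
floor or covering fewer than 20 codons are rejected, the in-silico analog of
a failed database screen.

Assignment is two-level, as in the survey it models: (1) a neighbor-joining
tree of fragment + panel on JTT ML protein distances; if the smallest clade
containing the fragment whose other leaves all carry one gene label has
bootstrap support >= ``min_support``, assign at the protein level; (2)
otherwise repeat with K2P distances on the nucleotide columns (the posterior
and central paralogue groups are often protein-identical); (3) otherwise the
fragment stays "ambiguous". Trees are rooted on the panel outgroup entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distances import (
    DEFAULT_D_MAX,
    encode_nuc,
    encode_prot,
    jtt_matrix,
    jtt_row,
    k2p_matrix,
    k2p_row,
)
from .seq import normalize_nuc, read_fasta_with_descriptions, reverse_complement, translate, write_fasta
from .trees import Tree, bipartition, nj_tree

__all__ = [
    "PanelEntry",
    "ReferencePanel",
    "ScreeningError",
    "Anchor",
    "trim_and_anchor",
    "AssignConfig",
    "Assignment",
    "assign_fragment",
    "Assigner",
]

HOMEOBOX_NT = 180
OUTGROUP_GENE = "OUT"


class ScreeningError(ValueError):
    """Fragment does not look like a homeobox (fails panel screening)."""


@dataclass(frozen=True)
class PanelEntry:
    gene: str          # 'A1'..'D13', extras, or 'OUT' for the outgroup
    species: str
    nuc: str
    prot: str

    @property
    def label(self) -> str:
        return f"{self.gene}|{self.species}"


class ReferencePanel:
    """Aligned 180-nt homeobox references labelled by gene."""

    def __init__(self, entries: Sequence[PanelEntry]):
        if not entries:
            raise ValueError("empty panel")
        for e in entries:
            if len(e.nuc) != HOMEOBOX_NT:
                raise ValueError(f"{e.label}: homeobox must be {HOMEOBOX_NT} nt")
            if translate(e.nuc, 0) != e.prot or len(e.prot) != HOMEOBOX_NT // 3:
                raise ValueError(f"{e.label}: protein is not the frame-0 translation")
        self.entries = list(entries)
        self.labels = [e.label for e in entries]
        self.nt = np.vstack([encode_nuc(e.nuc) for e in entries])
        self.aa = np.vstack([encode_prot(e.prot) for e in entries])

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return sorted({e.gene for e in self.entries if e.gene != OUTGROUP_GENE})

    @property
    def outgroup_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.gene == OUTGROUP_GENE]

    def consensus_prot(self) -> str:
        """Column-majority residue over non-outgroup entries."""
        rows = [i for i, e in enumerate(self.entries) if e.gene != OUTGROUP_GENE]
        from .distances import _AA_INDEX  # local import: simple reverse lookup

        inv = {v: k for k, v in _AA_INDEX.items()}
        cons = []
        for col in self.aa[rows].T:
            vals, counts = np.unique(col[col >= 0], return_counts=True)
            cons.append(inv[int(vals[counts.argmax()])] if len(vals) else "X")
        return "".join(cons)

    @classmethod
    def from_fasta(cls, path) -> "ReferencePanel":
        """Headers carry ``gene=<label> species=<tag>`` tokens."""
        entries = []
        for _, desc, seq in read_fasta_with_descriptions(path):
            meta = dict(
                tok.split("=", 1) for tok in desc.split() if "=" in tok
            )
            entries.append(
                PanelEntry(meta["gene"], meta["species"], seq, translate(seq, 0))
            )
        return cls(entries)

    def to_fasta(self, path) -> None:
        write_fasta(
            path,
            (
                (f"{e.label} gene={e.gene} species={e.species}", e.nuc)
                for e in self.entries
            ),
        )

    def drop(self, label: str) -> "ReferencePanel":
        return ReferencePanel([e for e in self.entries if e.label != label])


@dataclass(frozen=True)
class Anchor:
    """Placement of a fragment on the panel's homeobox coordinate system."""

    offset: int                 # first covered alignment column (nt)
    end: int                    # past-the-end column
    oriented: str               # fragment sequence in panel orientation
    frame: int                  # fragment index of the first complete codon
    codon_start: int            # first covered complete codon (aa column)
    codon_end: int              # past-the-end aa column
    identity: float
    reverse_complemented: bool


def trim_and_anchor(
    fragment: str,
    panel: ReferencePanel,
    min_codons: int = 20,
    min_identity: float = 0.4,
) -> Anchor:
    """Best ungapped placement of a fragment on the panel coordinate system.

    Both orientations and all offsets are scored by protein identity against
    the best-matching panel entry (the analog of a best database hit — a
    column consensus would under-score lineage-restricted genes in the
    variable arm regions). Ties prefer the plus strand, then the smaller
    offset.
    """
    fragment = normalize_nuc(fragment)
    if len(fragment) > HOMEOBOX_NT:
        # primer overhangs beyond the homeobox are not modelled; refuse
        # clearly over-long input rather than silently truncating
        raise ScreeningError(f"fragment longer than the {HOMEOBOX_NT}-nt homeobox")
    from .distances import encode_prot as _encode_prot

    best: tuple[float, int, int] | None = None  # (identity, rc, offset)
    for rc in (0, 1):
        seq = reverse_complement(fragment) if rc else fragment
        for offset in range(0, HOMEOBOX_NT - len(seq) + 1):
            lead = (-offset) % 3
            ncod = (len(seq) - lead) // 3
            if ncod < min_codons:
                continue
            prot = _encode_prot(translate(seq[lead : lead + 3 * ncod], 0))
            col0 = (offset + lead) // 3
            block = panel.aa[:, col0 : col0 + ncod]
            ident = float((block == prot[None, :]).mean(axis=1).max())
            if best is None or ident > best[0] + 1e-12:
                best = (ident, rc, offset)
    if best is None or best[0] < min_identity:
        raise ScreeningError("fragment does not anchor to the homeobox panel")
    ident, rc, offset = best
    seq = reverse_complement(fragment) if rc else fragment
    lead = (-offset) % 3
    ncod = (len(seq) - lead) // 3
    col0 = (offset + lead) // 3
    return Anchor(
        offset=offset,
        end=offset + len(seq),
        oriented=seq,
        frame=lead,
        codon_start=col0,
        codon_end=col0 + ncod,
        identity=ident,
        reverse_complemented=bool(rc),
    )


@dataclass
class AssignConfig:
    min_support: float = 70.0        # bootstrap % needed to accept a clade
    n_bootstrap: int = 1000          # replicates (survey default; desk runs use 100)
    d_max: float = DEFAULT_D_MAX     # saturation ceiling for distances
    min_codons: int = 20
    min_identity: float = 0.4
    prescreen_pgs: int | None = 3    # nearest paralogue groups kept for trees; None = all


@dataclass(frozen=True)
class Assignment:
    fragment_id: str
    gene: str | None                 # None = ambiguous
    level: str                       # 'protein' | 'nucleotide' | 'ambiguous'
    support: float | None
    anchor: Anchor | None = None

    @property
    def assigned(self) -> bool:
        return self.gene is not None


def _first_pure_clade(
    tree: Tree, fragment_label: str, root_label: str, gene_of: dict[str, str]
) -> tuple[str, frozenset[str]] | None:
    """Walk rootward from the fragment; first ancestor whose other leaves share a gene."""
    root, children, leafsets = tree.rooted_at(root_label)
    parent: dict[int, int] = {}
    for node, kids in children.items():
        for k in kids:
            parent[k] = node
    frag = tree.leaf_labels.index(fragment_label)
    node = frag
    while node in parent:
        node = parent[node]
        others = leafsets[node] - {fragment_label}
        if not others:
            continue
        genes = {gene_of[l] for l in others}
        if len(genes) == 1:
            gene = genes.pop()
            if gene == OUTGROUP_GENE:
                return None
            return gene, leafsets[node]
        return None
    return None


class Assigner:
    """Batch fragment assigner with cached panel-side bootstrap computation.

    Bootstrap column draws are derandomised per (column interval, replicate)
    from the master seed, so fragments covering the same columns share panel
    distance matrices across replicates; this is purely an optimisation and
    does not change any single fragment's result for a given seed.
    """

    def __init__(self, panel: ReferencePanel, cfg: AssignConfig, seed: int = 0):
        if not panel.outgroup_indices:
            raise ValueError("panel must contain an outgroup entry (gene=OUT)")
        self.panel = panel
        self.cfg = cfg
        self.seed = int(seed) % (2**31)
        self._col_draws: dict[tuple, np.ndarray] = {}
        self._panel_mat: dict[tuple, np.ndarray] = {}

    # -- bootstrap plumbing -------------------------------------------------
    def _draws(self, key: tuple, n_cols: int) -> np.ndarray:
        if key not in self._col_draws:
            import zlib

            digest = zlib.crc32(repr(key).encode()) % (2**31)
            rng = np.random.default_rng((self.seed, digest))
            self._col_draws[key] = rng.integers(
                0, n_cols, size=(self.cfg.n_bootstrap, n_cols)
            )
        return self._col_draws[key]

    def _panel_matrix(self, kind: str, rows: tuple, cols: tuple, rep: int,
                      sub: np.ndarray) -> np.ndarray:
        key = (kind, rows, cols, rep)
        if key not in self._panel_mat:
            self._panel_mat[key] = (
                k2p_matrix(sub, self.cfg.d_max)
                if kind == "nt"
                else jtt_matrix(sub, self.cfg.d_max)
            )
        return self._panel_mat[key]

    @staticmethod
    def _with_fragment_row(pmat: np.ndarray, row: np.ndarray) -> np.ndarray:
        n = pmat.shape[0]
        out = np.empty((n + 1, n + 1))
        out[:n, :n] = pmat
        out[:n, n] = row
        out[n, :n] = row
        out[n, n] = 0.0
        return out

    # -- per-level machinery -------------------------------------------------
    def _level(
        self,
        kind: str,
        frag_vec: np.ndarray,
        rows: list[int],
        col_lo: int,
        col_hi: int,
        fragment_id: str,
    ) -> tuple[str, float] | None:
        panel_block = (self.panel.nt if kind == "nt" else self.panel.aa)[
            np.array(rows)
        ][:, col_lo:col_hi]
        labels = [self.panel.labels[i] for i in rows] + [fragment_id]
        gene_of = {self.panel.labels[i]: self.panel.entries[i].gene for i in rows}
        gene_of[fragment_id] = "?"
        root_label = next(
            self.panel.labels[i] for i in rows if self.panel.entries[i].gene == OUTGROUP_GENE
        )
        rows_key = tuple(rows)
        cols_key = (kind, col_lo, col_hi)
        row_fn = k2p_row if kind == "nt" else jtt_row
        pmat_full = self._panel_matrix(kind, rows_key, cols_key, -1, panel_block)
        dist = self._with_fragment_row(
            pmat_full, row_fn(panel_block, frag_vec, self.cfg.d_max)
        )
        tree = nj_tree(dist, labels)
        hit = _first_pure_clade(tree, fragment_id, root_label, gene_of)
        if hit is None:
            return None
        gene, _clade = hit
        # the supported claim is "the fragment belongs inside this gene's
        # clade": score the split fragment + all candidate leaves of the
        # gene, which is insensitive to which species the fragment pairs
        # with inside that clade
        target = bipartition(
            {fragment_id} | {l for l in labels if gene_of[l] == gene}, labels
        )
        if len(labels) < 4:
            return gene, 100.0
        n_cols = col_hi - col_lo
        draws = self._draws(cols_key, n_cols)
        support_hits = 0
        for rep in range(self.cfg.n_bootstrap):
            idx = draws[rep]
            pmat = self._panel_matrix(kind, rows_key, cols_key, rep, panel_block[:, idx])
            dfull = self._with_fragment_row(
                pmat, row_fn(panel_block[:, idx], frag_vec[idx], self.cfg.d_max)
            )
            rep_tree = nj_tree(dfull, labels)
            if target in rep_tree.bipartitions():
                support_hits += 1
        support = 100.0 * support_hits / self.cfg.n_bootstrap
        if support >= self.cfg.min_support:
            return gene, support
        return None

    # -- public API -----------------------------------------------------------
    def assign(self, fragment_id: str, fragment_seq: str) -> Assignment:
        try:
            anchor = trim_and_anchor(
                fragment_seq, self.panel, self.cfg.min_codons, self.cfg.min_identity
            )
        except ScreeningError:
            return Assignment(fragment_id, None, "ambiguous", None, None)

        nt_lo, nt_hi = anchor.offset, anchor.end
        aa_lo, aa_hi = anchor.codon_start, anchor.codon_end
        frag_nt = np.full(HOMEOBOX_NT, -1, dtype=np.int8)
        frag_nt[nt_lo:nt_hi] = encode_nuc(anchor.oriented)
        frag_aa_str = translate(
            anchor.oriented[anchor.frame : anchor.frame + 3 * (aa_hi - aa_lo)], 0
        )
        frag_aa = np.full(HOMEOBOX_NT // 3, -1, dtype=np.int8)
        frag_aa[aa_lo:aa_hi] = encode_prot(frag_aa_str)

        rows = self._candidate_rows(frag_nt, nt_lo, nt_hi)
        result = self._level(
            "aa", frag_aa[aa_lo:aa_hi], rows, aa_lo, aa_hi, fragment_id
        )
        if result is not None:
            return Assignment(fragment_id, result[0], "protein", result[1], anchor)
        result = self._level(
            "nt", frag_nt[nt_lo:nt_hi], rows, nt_lo, nt_hi, fragment_id
        )
        if result is not None:
            return Assignment(fragment_id, result[0], "nucleotide", result[1], anchor)
        return Assignment(fragment_id, None, "ambiguous", None, anchor)

    def _candidate_rows(self, frag_nt: np.ndarray, lo: int, hi: int) -> list[int]:
        """Panel rows used for tree building.

        The K2P-nearest paralogue groups (whole groups, so every plausible
        member is present) plus the outgroup — the panel-based analog of the
        database screening step. Keeping the candidate set a function of the
        paralogue group makes the cached bootstrap panel matrices shared by
        every fragment of that group.
        """
        from .inventory import gene_pg

        k = self.cfg.prescreen_pgs
        if not k:
            return list(range(len(self.panel)))
        d = k2p_row(self.panel.nt[:, lo:hi], frag_nt[lo:hi], self.cfg.d_max)
        per_pg: dict[int, float] = {}
        for i, e in enumerate(self.panel.entries):
            if e.gene == OUTGROUP_GENE:
                continue
            pg = gene_pg(e.gene)
            per_pg[pg] = min(per_pg.get(pg, np.inf), d[i])
        keep_pgs = {pg for pg, _ in sorted(per_pg.items(), key=lambda kv: (kv[1], kv[0]))[:k]}
        return [
            i
            for i, e in enumerate(self.panel.entries)
            if e.gene == OUTGROUP_GENE or gene_pg(e.gene) in keep_pgs
        ]


def assign_fragment(
    fragment_id: str,
    fragment_seq: str,
    panel: ReferencePanel,
    cfg: AssignConfig | None = None,
    seed: int = 0,
) -> Assignment:
    """One-shot assignment (see :class:`Assigner` for batch use)."""
    return Assigner(panel, cfg or AssignConfig(), seed).assign(
        fragment_id, fragment_seq
    )
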