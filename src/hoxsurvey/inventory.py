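"""Hox gene identities, per-taxon inventories, and presence/absence matrices.

The gene universe is the 43-gene sarcopterygian set: the 39-gene placental
core plus the four genes secondarily lost on the way to mammals (A14, B10,
C1, C3). Inventories are expressed as deltas against the core, which is how
the survey results are stated (e.g. the African lungfish: core + A14, B10,
C1, C3 - D12 = 42 genes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CORE_39",
    "EXTRA_GENES",
    "UNIVERSE",
    "gene_pg",
    "gene_cluster",
    "GeneSet",
    "build_inventory",
    "PresenceMatrix",
    "REPORTED_DELTAS",
    "reported_inventories",
    "load_presence_matrix",
]

_GENE_RE = re.compile(r"([A-D])(\d{1,2})")


def _genes(spec: str) -> list[str]:
    """Expand 'A1-A7,A9' style shorthand into gene labels."""
    out: list[str] = []
    for tok in spec.split(","):
        tok = tok.strip()
        if "-" in tok:
            a, b = tok.split("-")
            ca, pa = _GENE_RE.fullmatch(a).groups()
            cb, pb = _GENE_RE.fullmatch(b).groups()
            assert ca == cb
            out.extend(f"{ca}{i}" for i in range(int(pa), int(pb) + 1))
        else:
            out.append(tok)
    return out


#: The 39-gene placental mammal core inventory.
CORE_39: tuple[str, ...] = tuple(
    _genes("A1-A7,A9-A11,A13") + _genes("B1-B9,B13")
    + _genes("C4-C6,C8-C13") + _genes("D1,D3,D4,D8-D13")
)
#: Genes present in the sarcopterygian universe but lost before mammals.
EXTRA_GENES: tuple[str, ...] = ("A14", "B10", "C1", "C3")
#: The 43-gene sarcopterygian universe, cluster-major order.
UNIVERSE: tuple[str, ...] = tuple(
    sorted(CORE_39 + EXTRA_GENES, key=lambda g: (g[0], int(g[1:])))
)

assert len(CORE_39) == 39 and len(UNIVERSE) == 43


def gene_pg(gene: str) -> int:
    """Paralogue group (1..14) of a gene label like 'C5'."""
    m = _GENE_RE.fullmatch(gene)
    if not m or not 1 <= int(m.group(2)) <= 14:
        raise ValueError(f"bad gene label {gene!r}")
    return int(m.group(2))


def gene_cluster(gene: str) -> str:
    gene_pg(gene)
    return gene[0]


class DeltaError(ValueError):
    """A gain/loss delta is inconsistent with the base inventory."""


@dataclass
class GeneSet:
    """A taxon's gene inventory with per-gene evidence tags."""

    taxon: str
    genes: frozenset[str]
    evidence: dict[str, str] = field(default_factory=dict)  # detected|inferred|unknown

    def __post_init__(self) -> None:
        extra = self.genes - set(UNIVERSE)
        if extra:
            raise ValueError(f"genes outside the 43-gene universe: {sorted(extra)}")

    @property
    def count(self) -> int:
        return len(self.genes)


def build_inventory(
    taxon: str,
    gains: Iterable[str] = (),
    losses: Iterable[str] = (),
    core: Iterable[str] = CORE_39,
) -> GeneSet:
    """Apply stated gains/losses to the core; |result| = |core| + |gains| - |losses|."""
    core_set = frozenset(core)
    gains = frozenset(gains)
    losses = frozenset(losses)
    if gains & core_set:
        raise DeltaError(f"gain(s) already in core: {sorted(gains & core_set)}")
    if not losses <= core_set:
        raise DeltaError(f"loss(es) not in core: {sorted(losses - core_set)}")
    return GeneSet(taxon, (core_set | gains) - losses)


#: Per-lineage gains/losses against the placental core, as stated by the survey.
REPORTED_DELTAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "lungfish": (("A14", "B10", "C1", "C3"), ("D12",)),
    "coelacanth": (("A14", "B10", "C1", "C3"), ("D13",)),
    "caecilian": (("C1", "C3"), ("D12", "B13")),
    "salamander": (("C3",), ("D12",)),
    "frog": (("C3",), ("B13", "D12")),
    "snake": (("C3",), ("D12",)),
    "lizard": (("C3",), ()),
    "turtle": ((), ()),
    "crocodile": ((), ()),
    "bird": ((), ()),
    "placental": ((), ()),
}


def reported_inventories() -> dict[str, GeneSet]:
    """The stated per-lineage inventories (lungfish 42, ..., frogs 38, ...)."""
    return {
        taxon: build_inventory(taxon, gains, losses)
        for taxon, (gains, losses) in REPORTED_DELTAS.items()
    }


class PresenceMatrix:
    """Taxa x gene binary states with optional unknowns, over the 43-gene universe.

    Backed by a pandas DataFrame with values 1.0 / 0.0 / NaN (unknown).
    Unknown states are excluded per character from parsimony counting.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [g for g in frame.columns if g not in UNIVERSE]
        if missing:
            raise ValueError(f"columns outside the universe: {missing}")
        self.frame = frame.astype(float)

    @classmethod
    def from_gene_sets(
        cls, gene_sets: Mapping[str, GeneSet] | Iterable[GeneSet]
    ) -> "PresenceMatrix":
        if isinstance(gene_sets, Mapping):
            gene_sets = list(gene_sets.values())
        data = {
            gs.taxon: [1.0 if g in gs.genes else 0.0 for g in UNIVERSE]
            for gs in gene_sets
        }
        frame = pd.DataFrame.from_dict(
            data, orient="index", columns=list(UNIVERSE)
        )
        return cls(frame)

    @classmethod
    def from_tsv(cls, path_or_buffer) -> "PresenceMatrix":
        frame = pd.read_csv(
            path_or_buffer, sep="\t", comment="#", index_col="taxon",
            dtype=str,
        )
        frame = frame.replace({"?": None}).astype(float)
        return cls(frame)

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out = out.map(lambda v: "?" if pd.isna(v) else str(int(v)))
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.columns)

    def states(self, gene: str) -> dict[str, int | None]:
        """Leaf states for one gene: 1 / 0 / None (unknown)."""
        col = self.frame[gene]
        return {
            taxon: (None if pd.isna(v) else int(v)) for taxon, v in col.items()
        }

    def gene_set(self, taxon: str) -> GeneSet:
        row = self.frame.loc[taxon]
        genes = frozenset(g for g in self.frame.columns if row[g] == 1.0)
        evidence = {
            g: ("unknown" if pd.isna(row[g]) else "detected")
            for g in self.frame.columns
        }
        return GeneSet(taxon, genes, evidence)

    def counts(self) -> pd.Series:
        """Genes present per taxon (unknowns not counted)."""
        return (self.frame == 1.0).sum(axis=1)


def load_presence_matrix() -> PresenceMatrix:
    """The packaged survey presence/absence matrix over 13 lineages."""
    with resources.files("hoxsurvey").joinpath("data/presence_matrix.tsv").open() as fh:
        return PresenceMatrix.from_tsv(fh)
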