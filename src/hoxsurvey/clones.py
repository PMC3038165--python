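"""Collapse sequenced clones and separate alleles from PCR/sequencing artifacts.

Within one library (one species x primer-pair cloning experiment), identical
clone sequences are collapsed to unique fragments with clone counts. Pairs of
unique fragments of equal length are then classified:

* 1-3 nucleotide differences, all synonymous in the shared reading frame,
  each variant seen in more than one clone -> allelic variants of one locus;
* 1-2 nucleotide differences, not all synonymous, one of the variants seen
  in only a single clone -> that singleton is a PCR/sequencing error and is
  excluded;
* anything else -> distinct fragments (separate candidate loci).

Cases the source rules leave open are resolved conservatively: a synonymous
singleton is merged into the majority variant (counts summed); two
non-synonymous variants each backed by >=2 clones are kept as distinct
candidates; a mixed synonymous+non-synonymous difference set follows the
non-synonymous branch; a 3-difference non-synonymous singleton is kept as
distinct but flagged for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .seq import GeneticCode, STANDARD_CODE, normalize_nuc

__all__ = [
    "CloneRecord",
    "UniqueFragment",
    "FilterResult",
    "collapse_clones",
    "classify_pair",
    "filter_library",
    "read_clone_fasta",
    "write_clone_fasta",
    "write_fragments_tsv",
]


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    library_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_nuc(self.sequence))


@dataclass
class UniqueFragment:
    sequence: str
    clone_count: int
    library_id: str
    frame_offset: int = 0
    status: str = "candidate"       # candidate | distinct | allelic_variant_of:<n> | artifact_excluded
    locus_id: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_nuc(self.sequence)
        if self.clone_count < 1:
            raise ValueError("clone_count must be >= 1")


def collapse_clones(
    library: Sequence[CloneRecord], frame_offset: int = 0
) -> list[UniqueFragment]:
    """One fragment per distinct sequence; counts sum to the library size.

    Fragments are returned in a deterministic order: clone count descending,
    then sequence.
    """
    if not library:
        return []
    lib_ids = {c.library_id for c in library}
    if len(lib_ids) != 1:
        raise ValueError(f"records from multiple libraries: {sorted(lib_ids)}")
    counts: dict[str, int] = {}
    for c in library:
        counts[c.sequence] = counts.get(c.sequence, 0) + 1
    frags = [
        UniqueFragment(seq, n, library.__iter__().__next__().library_id, frame_offset)
        for seq, n in counts.items()
    ]
    frags.sort(key=lambda f: (-f.clone_count, f.sequence))
    return frags


def _diff_positions(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _all_synonymous(
    a: str, b: str, positions: Sequence[int], frame: int, code: GeneticCode
) -> bool:
    """Whether every difference is silent in the shared reading frame.

    Differences inside the partial leading/trailing codons cannot alter the
    encoded protein of the fragment and count as synonymous.
    """
    for pos in positions:
        if pos < frame:
            continue
        cstart = frame + 3 * ((pos - frame) // 3)
        if cstart + 3 > len(a):
            continue
        if not code.is_synonymous(a[cstart : cstart + 3], b[cstart : cstart + 3]):
            return False
    return True


def classify_pair(
    a: UniqueFragment,
    b: UniqueFragment,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Classify two unique fragments: 'allelic_variants' | 'artifact' | 'distinct'.

    Fragments of unequal length or different reading frame are 'distinct' by
    precondition. Identical sequences are a caller error (they should have
    been collapsed).
    """
    if len(a.sequence) != len(b.sequence) or a.frame_offset != b.frame_offset:
        return "distinct"
    diffs = _diff_positions(a.sequence, b.sequence)
    k = len(diffs)
    if k == 0:
        raise ValueError("identical fragments must be collapsed before classification")
    syn = _all_synonymous(a.sequence, b.sequence, diffs, a.frame_offset, code)
    if syn and k <= 3 and min(a.clone_count, b.clone_count) >= 2:
        return "allelic_variants"
    if not syn and k <= 2 and min(a.clone_count, b.clone_count) == 1:
        return "artifact"
    return "distinct"


@dataclass
class FilterResult:
    """Validated fragments plus the bookkeeping needed downstream.

    ``loci`` maps a locus id to the fragments it absorbs (reference first);
    artifacts are excluded from ``fragments`` but retained for audit.
    """

    fragments: list[UniqueFragment]
    artifacts: list[UniqueFragment]
    loci: dict[str, list[UniqueFragment]]
    events: list[dict]

    @property
    def locus_count(self) -> int:
        return len(self.loci)


def filter_library(
    fragments: Sequence[UniqueFragment],
    code: GeneticCode = STANDARD_CODE,
    max_pair_diffs: int = 3,
) -> FilterResult:
    """Apply the allele/artifact rules across a collapsed library.

    Fragments are visited by clone count (highest first); each is compared
    against every already-retained fragment within ``max_pair_diffs``
    (equal length, equal frame) — references first in count order, then
    linked allelic variants — so transitive chains cluster against the
    highest-count fragment and an error riding on a minor allelic haplotype
    is still recognised. Idempotent: refiltering the surviving set
    reproduces it.
    """
    ordered = sorted(fragments, key=lambda f: (-f.clone_count, f.sequence))
    refs: list[UniqueFragment] = []
    retained: list[UniqueFragment] = []     # refs and linked variants, in placement order
    loci: dict[str, list[UniqueFragment]] = {}
    artifacts: list[UniqueFragment] = []
    events: list[dict] = []
    lib = ordered[0].library_id if ordered else ""

    for frag in ordered:
        frag = replace(frag, flags=list(frag.flags), status="candidate")
        placed = False
        for ref in retained:
            if len(ref.sequence) != len(frag.sequence):
                continue
            if ref.frame_offset != frag.frame_offset:
                continue
            diffs = _diff_positions(ref.sequence, frag.sequence)
            if not diffs or len(diffs) > max_pair_diffs:
                continue
            syn = _all_synonymous(
                ref.sequence, frag.sequence, diffs, frag.frame_offset, code
            )
            if syn and min(ref.clone_count, frag.clone_count) >= 2:
                frag.status = f"allelic_variant_of:{ref.locus_id}"
                frag.locus_id = ref.locus_id
                loci[ref.locus_id].append(frag)
                events.append(
                    {"library": lib, "action": "allelic_merge",
                     "locus": ref.locus_id, "count": frag.clone_count}
                )
                retained.append(frag)
                placed = True
                break
            if syn and frag.clone_count == 1:
                # singleton silent variant: fold into the majority haplotype
                # (locus clone totals are summed over linked fragments)
                frag.status = f"allelic_variant_of:{ref.locus_id}"
                frag.locus_id = ref.locus_id
                frag.flags.append("singleton_synonymous_merged")
                loci[ref.locus_id].append(frag)
                events.append(
                    {"library": lib, "action": "synonymous_singleton_merge",
                     "locus": ref.locus_id}
                )
                retained.append(frag)
                placed = True
                break
            if not syn and len(diffs) <= 2 and frag.clone_count == 1:
                frag.status = "artifact_excluded"
                artifacts.append(frag)
                events.append(
                    {"library": lib, "action": "artifact_excluded",
                     "locus": ref.locus_id, "diffs": len(diffs)}
                )
                placed = True
                break
            if not syn and len(diffs) == 3 and frag.clone_count == 1:
                frag.flags.append("nonsynonymous_triple_singleton")
        if not placed:
            frag.status = "distinct"
            frag.locus_id = f"{lib}:L{len(refs) + 1}"
            refs.append(frag)
            retained.append(frag)
            loci[frag.locus_id] = [frag]

    surviving = [f for locus in loci.values() for f in locus]
    return FilterResult(surviving, artifacts, loci, events)


# --------------------------------------------------------------------------
# File interfaces
# --------------------------------------------------------------------------

def read_clone_fasta(path) -> dict[str, list[CloneRecord]]:
    """Read clones from FASTA, grouped by library.

    Headers carry ``library=<id>`` and optionally ``count=<n>`` tokens; a
    record with a count stands for that many identical clones.
    """
    from .seq import read_fasta_with_descriptions

    libraries: dict[str, list[CloneRecord]] = {}
    for rid, desc, seq in read_fasta_with_descriptions(path):
        meta = dict(tok.split("=", 1) for tok in desc.split() if "=" in tok)
        lib = meta.get("library", "default")
        n = int(meta.get("count", 1))
        for k in range(n):
            cid = rid if n == 1 else f"{rid}.{k + 1}"
            libraries.setdefault(lib, []).append(CloneRecord(cid, lib, seq))
    return libraries


def write_clone_fasta(path, clones: Sequence[CloneRecord]) -> None:
    from .seq import write_fasta

    write_fasta(
        path, ((f"{c.clone_id} library={c.library_id}", c.sequence) for c in clones)
    )


def write_fragments_tsv(path, result: FilterResult) -> None:
    """Validated fragments and exclusions as TSV (sequence, count, status, locus)."""
    with open(path, "w") as fh:
        fh.write("sequence\tclone_count\tstatus\tlocus_id\n")
        for frag in list(result.fragments) + list(result.artifacts):
            fh.write(
                f"{frag.sequence}\t{frag.clone_count}\t{frag.status}\t"
                f"{frag.locus_id or ''}\n"
            )
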