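"""Degenerate primer model and in-silico PCR for the tiered Hox survey.

The survey primers are degenerate oligos designed against conserved
homeodomain (or exon1) protein motifs. Three tiers mirror the wet-lab
strategy: first-round paralogue-group-set primers ("general"), then
PG-specific primers, then member-specific primers for genes still missing.

Coordinates are 0-based half-open on the plus strand throughout. Forward
primers are scanned directly on the plus strand; reverse primers are matched
as their reverse complement. A binding-site window qualifies when at most
``max_mismatch`` positions fail IUPAC compatibility, with mismatches in the
primer's 3'-terminal 3 nt disqualifying by default (polymerase extension is
most sensitive there).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq import (
    GeneticCode,
    IUPAC_DNA,
    STANDARD_CODE,
    normalize_nuc,
    reverse_complement,
)

__all__ = [
    "DegeneratePrimer",
    "PrimerBindingSite",
    "Amplicon",
    "MotifMismatchError",
    "load_primer_table",
    "validate_primer_motif",
    "find_binding_sites",
    "in_silico_pcr",
    "pair_primers",
    "tiered_survey",
    "SurveyReport",
    "TIERS",
]

TIERS = ("general", "pg_specific", "member_specific")

DEFAULT_MIN_LEN = 80
DEFAULT_MAX_LEN = 165


class MotifMismatchError(ValueError):
    """Primer sequence cannot encode its annotated protein motif in any frame."""


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    sequence: str
    direction: str                      # 'forward' | 'reverse'
    target_pgs: frozenset[int]          # whole paralogue groups addressed
    target_genes: frozenset[str]        # specific members addressed (e.g. 'C5')
    aa_motif: str | None                # None for 5'UTR primers
    product_len: int | None             # nominal product size (bp)
    product_len_range: tuple[int, int] | None
    tier: str
    region: str = "homeobox"            # 'homeobox' | 'exon1'
    pairs_with: frozenset[str] = frozenset()
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_nuc(self.sequence))
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.tier not in TIERS:
            raise ValueError(f"bad tier {self.tier!r}")
        if self.product_len is not None and self.product_len <= 0:
            raise ValueError("expected product length must be positive")

    def targets_pg(self, pg: int) -> bool:
        return pg in self.target_pgs or any(
            _gene_pg(g) == pg for g in self.target_genes
        )

    def targets_gene(self, gene: str) -> bool:
        if gene in self.target_genes:
            return True
        return _gene_pg(gene) in self.target_pgs


@dataclass(frozen=True)
class PrimerBindingSite:
    template_id: str
    start: int
    end: int
    strand: str                         # '+' for forward primers, '-' for reverse
    mismatches: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid site interval")


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    sequence: str
    primer_pair: tuple[str, str]
    frame_offset: int | None = None     # reading frame of the product, from the fwd primer

    def __len__(self) -> int:
        return self.end - self.start


def _gene_pg(gene: str) -> int:
    m = re.fullmatch(r"[A-D](\d{1,2})", gene)
    if not m:
        raise ValueError(f"bad gene label {gene!r}")
    return int(m.group(1))


def _parse_targets(tok: str) -> tuple[frozenset[int], frozenset[str]]:
    pgs: set[int] = set()
    genes: set[str] = set()
    for part in tok.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.fullmatch(r"PG(\d+)-PG(\d+)", part)
        if m:
            pgs.update(range(int(m.group(1)), int(m.group(2)) + 1))
        elif re.fullmatch(r"PG\d+", part):
            pgs.add(int(part[2:]))
        else:
            _gene_pg(part)  # validates
            genes.add(part)
    return frozenset(pgs), frozenset(genes)


def load_primer_table(path=None) -> list[DegeneratePrimer]:
    """Load the packaged survey primer table (or a user table in the same TSV format)."""
    if path is None:
        text = (
            resources.files("hoxsurvey").joinpath("data/primers.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    primers: list[DegeneratePrimer] = []
    seen: set[str] = set()
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        name = row["name"]
        if name in seen:
            raise ValueError(f"duplicate primer name {name!r}")
        seen.add(name)
        pl, pl_range = None, None
        tok = row.get("product_len", "").strip()
        if tok:
            if "-" in tok:
                lo, hi = tok.split("-")
                pl_range = (int(lo), int(hi))
            else:
                pl = int(tok)
        motif = row.get("aa_motif", "").strip() or None
        if motif == "5UTR":
            motif = None
        pgs, genes = _parse_targets(row["targets"])
        primers.append(
            DegeneratePrimer(
                name=name,
                sequence=row["sequence"],
                direction=row["direction"],
                target_pgs=pgs,
                target_genes=genes,
                aa_motif=motif,
                product_len=pl,
                product_len_range=pl_range,
                tier=row["tier"],
                region=row.get("region", "homeobox"),
                pairs_with=frozenset(
                    x for x in row.get("pairs_with", "").split("|") if x
                ),
                note=row.get("note", ""),
            )
        )
    return primers


# --------------------------------------------------------------------------
# Motif validation
# --------------------------------------------------------------------------

def validate_primer_motif(
    primer: DegeneratePrimer, code: GeneticCode = STANDARD_CODE
) -> int:
    """Return the frame offset at which the primer encodes its motif.

    The primer (forward) or its reverse complement (reverse) is read from
    each offset 0..2; every complete degenerate codon must be able to encode
    the corresponding residue of some contiguous window of the motif
    (partial edge codons are unconstrained here; they are checked at the
    nucleotide level during binding). Failure flags a mistranscribed primer
    or motif.
    """
    if primer.aa_motif is None:
        raise ValueError(f"{primer.name} is a UTR primer and carries no motif")
    seq = (
        primer.sequence
        if primer.direction == "forward"
        else reverse_complement(primer.sequence)
    )
    motif = primer.aa_motif
    for offset in range(3):
        ncod = (len(seq) - offset) // 3
        if ncod < 1:
            continue
        codons = [seq[offset + 3 * k : offset + 3 * k + 3] for k in range(ncod)]
        for m in range(len(motif) - ncod + 1):
            if all(
                code.codon_can_encode(c, motif[m + k]) for k, c in enumerate(codons)
            ):
                return offset
    raise MotifMismatchError(
        f"{primer.name}: sequence cannot encode motif {motif!r} in any frame"
    )


# --------------------------------------------------------------------------
# Binding-site scan and in-silico PCR
# --------------------------------------------------------------------------

_SYMBOLS = "ACGTRYSWKMBDHVN"
_SYM_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}
_COMPAT = np.zeros((len(_SYMBOLS), 4), dtype=bool)
for _s, _bases in IUPAC_DNA.items():
    for _b in _bases:
        _COMPAT[_SYM_INDEX[_s], "ACGT".index(_b)] = True


def _encode_symbols(seq: str) -> np.ndarray:
    return np.fromiter((_SYM_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def find_binding_sites(
    primer: DegeneratePrimer,
    template: str,
    template_id: str = "template",
    max_mismatch: int = 0,
    require_3prime_match: bool = True,
) -> list[PrimerBindingSite]:
    """Exhaustive scan for qualifying plus-strand windows, sorted by start.

    The template must be concrete (A/C/G/T). Templates shorter than the
    primer yield an empty list.
    """
    template = normalize_nuc(template)
    if set(template) - set("ACGT"):
        raise ValueError("template must be a concrete sequence")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    pattern = (
        primer.sequence
        if primer.direction == "forward"
        else reverse_complement(primer.sequence)
    )
    plen = len(pattern)
    if len(template) < plen:
        return []
    tarr = np.fromiter(("ACGT".index(c) for c in template), dtype=np.int8,
                       count=len(template))
    parr = _encode_symbols(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, plen)
    ok = _COMPAT[parr[None, :], windows]          # (n_windows, plen)
    mism = (~ok).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatch)
    if require_3prime_match and max_mismatch > 0:
        # the primer 3' end is the window end for forward primers and the
        # window start for reverse primers (rc pattern)
        tail = ok[:, -3:] if primer.direction == "forward" else ok[:, :3]
        hits = hits[tail[hits].all(axis=1)]
    strand = "+" if primer.direction == "forward" else "-"
    return [
        PrimerBindingSite(template_id, int(s), int(s) + plen, strand, int(mism[s]))
        for s in hits
    ]


def in_silico_pcr(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    template: str,
    template_id: str = "template",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_mismatch: int = 0,
    code: GeneticCode = STANDARD_CODE,
) -> list[Amplicon]:
    """Predict products of a primer pair on a concrete template.

    One amplicon per (forward site, downstream non-overlapping reverse site)
    pair whose span is within [min_len, max_len]; the product is the
    plus-strand template slice from the forward-site start to the
    reverse-site end. Ordered by (start, end).
    """
    if fwd.direction != "forward" or rev.direction != "reverse":
        raise ValueError("in_silico_pcr(fwd, rev, ...) requires a forward/reverse pair")
    template = normalize_nuc(template)
    fsites = find_binding_sites(fwd, template, template_id, max_mismatch)
    if not fsites:
        return []
    rsites = find_binding_sites(rev, template, template_id, max_mismatch)
    if not rsites:
        return []
    try:
        frame = validate_primer_motif(fwd, code) if fwd.aa_motif else None
    except MotifMismatchError:
        frame = None
    out = []
    for fs in fsites:
        for rs in rsites:
            if rs.start < fs.end:
                continue
            span = rs.end - fs.start
            if min_len <= span <= max_len:
                out.append(
                    Amplicon(
                        template_id,
                        fs.start,
                        rs.end,
                        template[fs.start : rs.end],
                        (fwd.name, rev.name),
                        frame,
                    )
                )
    return sorted(out, key=lambda a: (a.start, a.end))


def pair_primers(
    primers: Sequence[DegeneratePrimer], region: str = "homeobox"
) -> list[tuple[DegeneratePrimer, DegeneratePrimer]]:
    """Form survey primer pairs: shared targets, or an explicit pairing note."""
    fwds = [p for p in primers if p.direction == "forward" and p.region == region]
    revs = [p for p in primers if p.direction == "reverse" and p.region == region]
    pairs = []
    for r in revs:
        for f in fwds:
            explicit = f.name in r.pairs_with or r.name in f.pairs_with
            shared = bool(
                (f.target_pgs & r.target_pgs)
                or (f.target_genes & r.target_genes)
                or {_gene_pg(g) for g in f.target_genes} & r.target_pgs
                or {_gene_pg(g) for g in r.target_genes} & f.target_pgs
            )
            if explicit or (shared and not r.pairs_with):
                pairs.append((f, r))
    return pairs


# --------------------------------------------------------------------------
# Tiered survey
# --------------------------------------------------------------------------

@dataclass
class SurveyReport:
    """Outcome of a tiered in-silico survey of a template pool."""

    rows: list[dict] = field(default_factory=list)       # one per (pg, template)
    events: list[dict] = field(default_factory=list)     # escalation decisions
    amplicons: list[Amplicon] = field(default_factory=list)

    def detected(self, pg: int | None = None) -> dict[str, str]:
        """template_id -> tier of first detection (optionally for one PG)."""
        out: dict[str, str] = {}
        for row in self.rows:
            if pg is not None and row["pg"] != pg:
                continue
            if row["tier"] is not None and row["template_id"] not in out:
                out[row["template_id"]] = row["tier"]
        return out

    def to_rows(self) -> list[dict]:
        return list(self.rows)


def default_expected_members() -> dict[int, int]:
    from .inventory import UNIVERSE, gene_pg

    counts: dict[int, int] = {}
    for g in UNIVERSE:
        counts[gene_pg(g)] = counts.get(gene_pg(g), 0) + 1
    return counts


def tiered_survey(
    primers: Sequence[DegeneratePrimer],
    template_pool: Sequence[tuple[str, str]],
    expected_members: Mapping[int, int] | None = None,
    template_pg: Mapping[str, int] | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_mismatch: int = 0,
) -> SurveyReport:
    """Run the escalating survey over a pool of templates.

    First-round PG-set pairs are applied to every template; a paralogue group
    is escalated to PG-specific and then member-specific primers while the
    number of distinct templates detected for it falls short of the expected
    member count (by default, the PG's membership in the 43-gene
    sarcopterygian universe — the survey's reference inventories).

    ``template_pg`` attributes templates to paralogue groups; when omitted,
    template ids are parsed as gene labels (the synthetic-world convention).
    """
    if not primers:
        raise ValueError("empty primer table")
    if expected_members is None:
        expected_members = default_expected_members()
    if template_pg is None:
        template_pg = {}
        for tid, _ in template_pool:
            gene = tid.split("|")[-1]
            template_pg[tid] = _gene_pg(gene)
    pairs = pair_primers(primers)
    report = SurveyReport()
    detected: dict[int, dict[str, str]] = {pg: {} for pg in expected_members}

    for pg in sorted(expected_members):
        for tier in TIERS:
            tier_pairs = [(f, r) for f, r in pairs if f.tier == tier and f.targets_pg(pg)]
            if tier != "general" and len(detected[pg]) >= expected_members[pg]:
                break
            if tier != "general":
                report.events.append(
                    {
                        "pg": pg,
                        "action": "escalate",
                        "to_tier": tier,
                        "detected_so_far": len(detected[pg]),
                        "expected": expected_members[pg],
                    }
                )
            if not tier_pairs:
                continue
            for tid, seq in template_pool:
                if template_pg.get(tid) != pg:
                    continue
                for f, r in tier_pairs:
                    amps = in_silico_pcr(
                        f, r, seq, tid, min_len, max_len, max_mismatch
                    )
                    if amps and tid not in detected[pg]:
                        detected[pg][tid] = tier
                    report.amplicons.extend(amps)

    for pg in sorted(expected_members):
        pool_members = [tid for tid, _ in template_pool if template_pg.get(tid) == pg]
        for tid in pool_members:
            report.rows.append(
                {"pg": pg, "template_id": tid, "tier": detected[pg].get(tid)}
            )
        if not pool_members:
            report.rows.append({"pg": pg, "template_id": None, "tier": None})
    return report
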