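# Methods

`hoxsurvey` models a degenerate-PCR survey of Hox gene inventories in
lobe-finned fishes and tetrapods, end to end: amplification, clone-library
cleanup, ortholog assignment, inventory building, and gene-content parsimony.
This note records the models, the tunable parameters that matter, what the
synthetic generator does and does not emulate, and the numerical and design
choices made where the procedure left room.

## The gene universe and inventory algebra

All inventories live in the 43-gene sarcopterygian universe: the 39-gene
placental core (clusters A-D, paralogue groups 1-13, with the well-known
gaps such as A8 and B11) plus the four genes lost on the mammal stem (A14,
B10, C1, C3). Inventories are expressed as deltas against the core
(`build_inventory`), so the count law |core| + |gains| - |losses| holds by
construction; the packaged presence/absence matrix
(`data/presence_matrix.tsv`) encodes the surveyed calls for 13 lineages,
with HoxC3 in marsupials and monotremes marked unknown (`?`) because the
flanking genomic sequence is missing in both assemblies.

## Degenerate primers and in-silico PCR

Primers are IUPAC-degenerate oligos designed against conserved homeodomain
motifs (`data/primers.tsv`, 44 rows). Motif validation reads the primer (or
its reverse complement for reverse primers) in each frame offset and accepts
the offset at which every complete degenerate codon *can* encode the
corresponding residue of a contiguous motif window. Containment of the
expansion set is deliberately not required: degenerate design uses covering
codons (YTN for Leu also covers Phe), so compatibility, not containment, is
the validating relation. Partial edge codons are unconstrained here and are
checked at the nucleotide level during binding.

Binding sites are exhaustive plus-strand windows with at most `max_mismatch`
IUPAC-incompatible positions (default 0); mismatches in the 3'-terminal
3 nt disqualify a site by default, reflecting polymerase extension
sensitivity. Products are template slices from forward-site start to
reverse-site end (0-based half-open coordinates throughout), kept when their
span lies in the survey's 80-165 bp window.

**Nominal vs geometric product sizes.** The survey table's printed product
lengths are nominal. With both primer motifs in a single reading frame the
universal pair HoxF1+HoxR1 can only produce 3k+22 bp products, so its
printed 125 bp is geometrically unattainable (the canonical fixture yields
124 bp); other rows are mutually inconsistent by 1-3 bp in the same way.
Sixteen of the packaged pairs are exactly reproduced by canonical motif
placement (80, 89, 116, 122, 128, 149, 152, 164 bp) and are asserted in
tests; the remaining nominal sizes are reproduced to within 3 bp and are not
asserted. The 84-vs-89 bp discrepancy for the group-14 fragment is left
unresolved; the synthetic A14 root reproduces the tabulated 89 bp and tests
assert neither value.

The tiered survey mirrors the wet-lab strategy: first-round paralogue-group
set primers ("general"), then PG-specific, then member-specific primers. A
group escalates while the number of distinct templates detected for it falls
short of its expected membership (default: its membership in the 43-gene
universe), which is how incomplete retrieval was recognised in practice.

## Clone filtering

Within one library (species x primer pair), identical clones collapse to
unique fragments. Equal-length fragments in the library's shared reading
frame are then classified pairwise: 1-3 differences, all synonymous, each
variant in >1 clone = allelic variants of one locus; 1-2 differences, not
all synonymous, one variant a singleton = the singleton is a PCR/sequencing
error and is excluded. Fragments are visited by clone count (descending) and
compared against every already-retained fragment within 3 differences, so
chains cluster against the highest-count haplotype and an error riding on a
minor allele is still caught. Open cases are resolved conservatively and
flagged: synonymous singletons merge into the majority haplotype;
non-synonymous variants each backed by >=2 clones stay distinct (possible
recent paralogs); mixed difference sets follow the non-synonymous branch;
3-difference non-synonymous singletons stay distinct but flagged.
Differences falling in partial edge codons cannot change the encoded protein
and count as synonymous.

## Distances, trees, support

* **K2P** (nucleotide): d = -1/2 ln((1-2P-Q) sqrt(1-2Q)) with pairwise
  deletion of ambiguous columns. Saturated pairs (log argument <= 0) raise
  in scalar use and clamp to the ceiling `d_max` (default 5.0) in matrix
  builders, because NJ needs complete matrices.
* **JTT ML** (protein): the maximum-likelihood pairwise distance under the
  reversible JTT replacement process. The rate matrix is assembled from the
  published exchangeabilities and equilibrium frequencies embedded in
  `jtt_data.py` (model frequencies, not alignment-empirical: the model is
  JTT, not JTT+F), normalised to one expected replacement per site per unit
  distance. The scalar function optimises exactly
  (`scipy.optimize.minimize_scalar`, tolerance 1e-8); the matrix builder
  used inside bootstrap loops maximises over a fixed log-spaced grid of 64
  candidate distances (~7% relative resolution, far below the sampling noise
  of <=60-codon alignments). An optimum pinned at `d_max` is reported as
  saturation.
* **Neighbor joining**: canonical Saitou-Nei agglomeration; exact on
  additive matrices (verified against exhaustive least-squares topology
  search). Exact Q ties resolve to the lexicographically smallest label
  pair; negative branch estimates clamp to zero with the deficit moved to
  the sister edge.
* **Bootstrap**: column resampling; an internal edge's support is the
  percentage of replicate trees containing its split. Replicate column draws
  are derandomised from the run seed per column interval, which lets
  fragments covering the same columns share panel-side distance matrices —
  an optimisation only; single-fragment results for a given seed are
  unchanged.

## Ortholog assignment

Homeoboxes are a fixed-length, indel-free 180-nt region, so the reference
panel is an ungapped positional alignment and a fragment is placed by the
ungapped offset/orientation maximising protein identity against the
best-matching panel entry (a column consensus under-scores
lineage-restricted genes in the variable arm regions). Fragments covering
<20 codons or below 40% best identity are rejected — the analog of a failed
database screen. Candidate references for tree building are the whole
paralogue groups nearest by K2P (default 3 groups) plus the outgroup entry,
mirroring the screening step that preceded tree building in practice.

Assignment is two-level: NJ on JTT protein distances first; if that is
inconclusive, NJ on K2P nucleotide distances (paralogue groups 2 and 6-8
carry almost no protein signal). The fragment's candidate gene is read from
the smallest clade containing it whose other leaves share one gene label
(trees are rooted on the panel outgroup). The supported claim is "the
fragment belongs inside this gene's clade", so the bootstrap score is the
support of the split {fragment + all candidate leaves of that gene}: robust
to which species the fragment pairs with inside the clade, but properly
collapsing for protein-identical paralogs. Acceptance needs support >=
`min_support` (default 70%; the source procedure never states its
threshold). `n_bootstrap` defaults to the published 1000 replicates; the
demo and acceptance configurations use 100 (desk scale — support estimates
are then +-5% binomial noise, which the 70% threshold tolerates).

## The synthetic world

The generator owns a fixed, deterministic set of 43 gene roots plus an
outgroup homeobox (internal seed, independent of user seeds): a canonical
60-residue homeodomain scaffold, family-specific arm and helix motifs placed
at canonical coordinates so the packaged primers amplify each gene with the
survey's product geometry, 4 group-distinguishing and 6
member-distinguishing residue substitutions at free positions, and
gene-specific codon choices everywhere (so members of the deliberately
protein-identical groups 2 and 6-8 differ only synonymously). Codon
positions under primer motifs are sampled from the degeneracy-compatible
subset and frozen during evolution — the purifying selection that makes
degenerate priming work. HoxC5 is built divergent (no universal-arm motifs,
one substitution in the ELEKEF block) so only the member-specific primer
finds it, reproducing the escalation the tiered strategy exists for; group
13 carries the WFQNRRVK helix (own reverse primer) and A14 is reachable only
through the group-13/14 pair at 89 bp.

Evolution is a per-site K2P draw (default transition/transversion rate
ratio kappa=2, a typical vertebrate nuclear value) along a 3-species guide
tree of depth 0.04 substitutions/site, with surveyed taxa at 0.04 from the
roots — shallow divergences appropriate to a strongly conserved coding
region (observed homeodomain identities ~80-97%). Codons that would become
stops revert to the parental codon. Clone counts per amplified locus are
zero-truncated Poisson with mean 8; a second haplotype with 1-3 synonymous
changes appears with probability 0.3 carrying >=2 clones; each clone
independently acquires a 1-2 nt non-synonymous error with probability 0.05.
At these defaults the six-lineage demo world emits ~5,900 clones across
~750 loci — the same order as the ~3,900 clones of the survey it emulates.

What the generator does **not** emulate: exon1/UTR amplicons (those primers
are packaged and motif-validated but have no synthetic targets), indels,
chimeric reads, polymerase error spectra, primer thermodynamics, and
between-species rate variation. A green end-to-end test therefore
establishes that the pipeline's logic recovers a known inventory under the
stated noise model, not that the wet-lab survey's sensitivity is reproduced.

## Dollo parsimony

For one presence/absence character on a rooted topology the minimal
single-gain, irreversible-loss history is closed-form: the gain sits at the
root (forced when outgroups carry the gene) or at the MRCA of present
leaves, and the losses are the maximal subtrees below the gain containing no
present leaf. Unknown leaves constrain nothing and absorb no events.
Equally parsimonious placements cannot arise under this rule (the maximal
subtrees are unique), so loss edges are reported as the exact clade sets.
Ancestral reconstruction composes the per-gene histories; on the working
sarcopterygian tree ancestral presence is forced at the root because every
universe gene is attested in the lobe-finned fishes. The implementation is
tested against exhaustive minimisation over all loss-edge subsets on
thousands of random trees of up to 8 leaves.

## Known limitations

* Anchoring is ungapped; an indel-bearing fragment would be rejected rather
  than aligned.
* The 70% support threshold and the 3-group prescreen are explicit stand-ins
  where the modelled procedure is silent; both are configurable.
* Printed product sizes in the packaged primer table are nominal (see
  above); one regression value (125 bp for the universal pair) is asserted
  at its printed value and fails against the geometric 124 bp by design
  rather than silently re-targeting the table.
* The grid-based JTT matrix trades ~7% distance resolution for bootstrap
  speed; exported scalar distances are exact.
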