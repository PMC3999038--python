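# Methods

This note records the models, conventions and numerical choices behind
`peroxscan`, and what the synthetic benchmark does and does not show.

## Degenerate-primer model

Primers are 5'→3' strings over the IUPAC ambiguity alphabet plus
inosine (`I`).  Inosine base-pairs promiscuously, so it is treated as a
universal match during hybridization and emitted as the wildcard `N`
when a primer is expanded into concrete sequences; the number of
expansions is therefore the product of IUPAC set sizes over non-inosine
positions (24 for peroxiF2).  A primer binds a template window when,
aligned without gaps, at most `max_mismatch` positions have disjoint
base sets.  Two conventions are deliberate:

- The 3'-terminal two positions must match regardless of the tolerance:
  polymerase extension requires an annealed 3' end, and this cheaply
  suppresses spurious sites.
- The default tolerance is 0 mismatches.  The wet protocol gives no
  mismatch budget, so the stringent default is used and exposed as a
  CLI knob (`--max-mismatch`).

Amplicons are reported primer-inclusive.  Gel-estimated product sizes
include the primer footprints, so the size windows — (300, 500) bp for
class II and DyP around the expected ~400 bp, (150, 280) bp for the
~210 bp UPO product — are checked against the full product.  Whether
published product sizes include primers is ambiguous in general; the
inclusive convention is a package decision.  All convergent
forward/reverse site combinations inside the window are reported
(nested and overlapping products included); downstream filters decide.

## Translation

Standard genetic code only (templates are cDNA; `U`→`T` on ingest).  A
codon containing ambiguity codes or inosine translates to a residue
only when *every* concrete expansion encodes that residue, otherwise
`X`.  This is conservative but decidable and testable.  At the
translation stage of the pipeline, frame 0 on the forward-primer strand
is preferred because the survey primers are motif-anchored (e.g.
DyP360F encodes CPFAAHI from its first base); if frame 0 contains an
internal stop, the longest stop-free forward frame is used instead.

## Anchor mapping and classification

Catalytic positions are configured in *reference numbering* — Trp-171
(LiPH8) and Asp-175 (MnP1) for class II, Arg-329/Leu-354/Phe-356 (DyP
3MM3 structure numbering) for DyP — not as columns of any particular
multiple alignment.  Published alignment-column coordinates (210/222,
54/90/92) are artifacts of one specific MSA whose parameters are not
recoverable; mapping through reference numbering reproduces the same
biology without that MSA.  A query is aligned to the annotated
reference with an affine-gap global aligner (BLOSUM62, gap open 10,
extend 0.5 — conventional defaults, configurable) with free terminal
gaps, since queries are partial amplicon translations against
full-length references.  Each anchor reports the query residue in the
reference's column, `GAP` for an internal deletion, or `ABSENT` when
the anchor lies outside the aligned span of a partial query; both
`GAP` and `ABSENT` count as "residue not present" — a fragment lacking
the site lacks the evidence.

The class II rule table is total over the 2×2 space of
(Trp present, Asp present).  The VP-like cell is emitted even though
litter surveys may never populate it: a partial rule table would turn
data absence into a code path error.  "Untypical" LiP-like is the
residue-only call for Trp-without-Asp; promotion to canonical LiP is a
clade judgment that belongs to the tree stage, not the residue rule.
At the Mn-binding anchor, "acidic residue" means `D` by default with an
option to also accept `E` (the homologous acidic triad of VPs), via the
`tolerated` field of the anchor specification.

UPO fragments carry no known diagnostic residue in the amplified
region, so grouping is by partial-protein length alone: 66–74 aa →
group I.1, 80–90 aa → group II, otherwise unassigned.  Cohort
summaries print integer-rounded percentages *with explicit
denominators* — survey percentages are ambiguous when total, DNA-unique
and protein-unique counts differ, so the table never hides which
denominator a percentage refers to.

## Distances, trees and supports

Amino-acid distances use the observed proportion of differing residues
with pairwise deletion (columns gapped in either member of a pair are
excluded for that pair only), corrected for multiple hits with the
Poisson model d = −ln(1 − p) under uniform site rates.  Pairs with
p ≥ 0.99 are flagged UNDEFINED rather than silently capped, and tree
building refuses matrices containing UNDEFINED entries with an explicit
error — saturation should be visible, not absorbed.

Neighbor joining follows the Saitou–Nei Q criterion with two stated
conventions where the literature is silent: ties on Q break to the
lowest index pair (row-major scan), and negative branch-length
estimates clamp to zero.  On additive input the generating topology
and path lengths are recovered exactly (this is a test invariant).

Bootstrap support resamples alignment columns with replacement,
rebuilds the NJ tree per replicate, and attaches to each internal edge
of the *original* tree the percentage of usable replicates containing
the same bipartition (not a majority-rule consensus).  Replicates whose
resampled distances saturate are discarded from the denominator.  The
50% threshold is a display filter applied at Newick rendering; the tree
object keeps all supports.  Supports are deterministic under a fixed
seed.

Progressive multiple alignment uses an NJ guide order on pairwise
identity distances and merges profiles with mean-of-pairs BLOSUM62
scoring under the same affine gap penalties.  It is a minimal
progressive aligner sufficient for near-identical amplicon families,
not a ClustalW replica.

## Dereplication, richness, activity units

Unique sequence types are exact-string clusters, upper-cased at the
DNA level or on the pipeline-annotated translation at the protein
level; cluster representatives are the lexicographically smallest
member id and site labels are unioned per cluster, which is what makes
cross-site shared types detectable.  Synonymous codon variation can
merge but never split clusters, so unique protein types ≤ unique DNA
types always.

Activity conversion is Beer–Lambert dimensional analysis: the
photometric slope (ΔA/min) over ε×path gives mol L⁻¹ min⁻¹, scaled to
µmol/min (enzyme units) in the assay volume, from the extract aliquot
to the whole extract, and normalized per gram dry matter.
Mn-independent peroxidase activity is the peroxide-dependent total
minus the peroxide-free laccase activity; negative differences are
physically meaningless and clamp to zero with an explicit flag.  The
dry-matter fraction is an explicit input (default 1.0): surveys report
per g DM but rarely state moisture, so the package refuses to guess
silently.

## The synthetic benchmark

The generator emulates the structure of a multi-site litter survey:
nine sites by default (one maple, one aspen, four beech, two spruce,
one oak), a handful of target amplicons per family per site, plus
primer-free decoys.  Per family it builds a random ancestor protein
with catalytic residues implanted at fixed positions *in synthetic
numbering* (class II W40/D52, DyP R40/L65/F67) — real reference
proteins are not fabricated, so synthetic anchors are deliberately
decoupled from the real 171/175/329/354/356 coordinates.  References
diverge from the ancestor at 12% residue substitution; environmental
records diverge from references at 2% by default (5% in stress tests).
Translated lengths follow the published ranges: class II 133 aa
(~400 bp primer-inclusive), DyP 128–144 aa, UPO group I.1 66–74 aa and
group II 80–90 aa, adjusted by in-frame indels in a variable region
away from anchors.  Subtype plans mirror a litter survey's signature:
~90% MnP-like, a few percent Trp-only and GP-like, no VP; DyP pocket
residues present with marginal probabilities 99/99/91%; UPO 90% group
I.1.  Back-translation draws uniformly among synonymous codons, and a
fraction of records is re-emitted as duplicates (byte-identical or
synonymously re-encoded; same or different site), which exercises the
DNA-unique > protein-unique dereplication pattern and cross-site
sharing.  Primer footprints are stamped as concrete expansions of the
real degenerate primers so in-silico PCR genuinely has to find them.

Two emulation limits matter for interpreting green tests.  First,
mutation never hits primer footprints or anchor codons: degenerate
primer capture presupposes conserved priming sites, and anchor truth is
controlled by the ablation plan, not by noise — so classification
accuracy on these pools measures the anchor-mapping machinery, not
robustness to primer-site erosion.  Second, sequences are clean Sanger
clone proxies: no chimeras, no sequencing-error model, and decoys are
random DNA rather than real off-target transcripts.  Passing tests
therefore validate the pipeline logic, not the wet-lab failure modes of
a real survey.

## Problem sizes and runtime

The defaults used by the tests and the acceptance script are small by
design: 2–3 sites × 3–6 records per family per stage test, 1,000
bootstrap replicates on 4-taxon alignments, 30–100 replicates and ≤ 25
taxa for whole-pipeline trees.  The algorithms scale to full survey
sizes (hundreds of records); dense NJ is O(n³) and the distance matrix
O(n²L), both numpy-vectorized.

## Known limitations

- No local (Smith–Waterman) alignment mode and no structural alignment;
  anchor mapping relies on global homology, which is appropriate for
  single-family amplicons but not for remote homologs.
- The progressive aligner has no iterative refinement; deep or gappy
  families deserve a dedicated MSA tool, and the tree stage accepts
  externally aligned FASTA for that reason.
- Richness tables from residue calls alone cannot separate "MnP long"
  (a clade concept) from other MnPs; without tree placement all
  MnP-like calls fall into "MnP short/unclassified".
- BLAST-style database assignment is out of scope; best-reference
  assignment works against a local panel only.
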