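# Methods

This note documents the models, parameters, numerical choices, and
known limitations of the screen, and what the synthetic test data do —
and do not — demonstrate about behaviour on real data.

## Candidate discovery

Subjects are compared to baits with local pairwise alignment
(Smith–Waterman through Biopython's `PairwiseAligner`; BLOSUM62, gap
open 11, extend 1 — conventional protein-search settings). "Sequence
similarity" is interpreted as percent identity over the aligned columns
(gap columns included in the denominator), the stricter and more
reproducible of the common readings. The retention rule is strict on
both sides: identity **> 0.40** and score/self-score **> 0.30**, where
the self-score is the sum of substitution-matrix diagonal entries over
the bait — the maximum attainable score for that query, making the
ratio a length-normalised fraction of perfection. Both thresholds are
configurable; the defaults are deliberately lenient so that the later
refinement stages, not the search, decide the final candidate set.

An optional BLAST+ engine (`blastp` behind the same interface) is
provided for interchange; on the synthetic fixtures both engines retain
the same candidate sets, which the test suite asserts on identifiers
rather than scores (bitscores and raw scores are not unit-compatible).

### Emulating HSP behaviour

A textbook local aligner returns one globally optimal local alignment
and will happily bridge an intron that happens to be translated in
frame without a stop, or drag a net-positive excursion of near-random
columns along an alignment end. Seeded search tools do neither, because
X-drop extension terminates at sustained score drops. Genome-mode hits
are therefore post-processed: the alignment's per-column score profile
is segmented wherever the running score falls to zero or drops more
than 40 below its running maximum, and each segment's ends are trimmed
until the terminal six columns are gap-free with at least four
identities. The trimming matters: downstream splice-boundary search
anchors coordinate arithmetic on hit edges, and a single spurious
matching codon or gap column at an edge would corrupt that mapping.

## Translation and fragments

Standard genetic code (nuclear plant genes); any codon containing a
non-ACGT character translates to `X`, and `X` never satisfies a residue
rule — ambiguity is treated as absence of evidence. Six-frame
translation yields maximal stop-free runs ("fragments"); they are
stop-to-stop, not ATG-anchored, since assembled transcripts frequently
truncate the 5′ end. The default minimum fragment length is 50 aa for
transcripts (suppresses spurious short fragments while keeping real
coding runs) and 10 aa inside genome mode, where single exons can be
short and the locus chaining provides the context that individual
fragments lack.

## Gene models

Translated hits of one bait on one contig and strand are chained in
coding order by a weighted longest-increasing-subsequence dynamic
program maximising summed alignment score, subject to: genomic gap
between 20 nt and `max_intron_len` (default 20 000 nt, plant-typical),
strictly advancing bait coordinates, and at most 10 aa of query overlap
between consecutive hits. The overlap cap is what separates tandem
paralogs from introns — without it, the first half of one gene copy and
the second half of its neighbour chain into a single chimeric "locus".
Chains are extracted iteratively (best first) so spurious hits
interleaved between true exons cannot break a gene apart; chains of
different baits whose genomic spans overlap are taken to describe the
same locus, represented by the best-scoring chain.

One isoform per locus is stitched. Because removing an intron must
preserve the reading of the bait, the donor and acceptor of a junction
are not independent: candidate boundaries are enumerated as (peptide
split point `q*`, intron phase 0–2) pairs, each of which *determines*
both the donor and the acceptor coordinate through the flanking
fragments' codon lattices. A candidate is feasible when the intron
starts `GT` and ends `AG` on the coding strand, is at least 20 nt long,
and the spliced junction is stop-free. Among feasible candidates the
one whose spliced junction peptide (±10 codons) scores best against the
bait wins; ties break on smallest total boundary shift, then leftmost
donor. Junction choices are validated jointly against the full CDS
(no internal stops) with backtracking. If a junction admits no feasible
candidate, the locus is demoted to its single best fragment and flagged
`non-canonical-or-partial` — never silently dropped, and never stitched
across a non-canonical site.

Outer exon edges are finally extended so the model covers the bait's
full query span (local alignments trim terminal mismatches), shrinking
codon-wise if the extension would introduce a stop. This assumes the
subject gene is approximately bait-length; genuinely truncated genes at
contig edges are clamped. The screen does not attempt ATG/stop
refinement, multiple isoforms, UTRs, or non-canonical splice sites;
for production genome annotation a dedicated gene predictor remains the
better tool, and genome mode is intended for pathway-focused discovery.

Coordinates are 1-based inclusive internally and in GFF3 export (phase
computed per CDS segment); any future BED export would be 0-based
half-open.

## Alignment, cleaning, classification

Global multiple alignments use MAFFT when the binary is on `PATH`
(deterministic for fixed input order) with an internal center-star
progressive fallback anchored on the longest sequence; both guarantee
that degapping a row reproduces its input byte-exactly. Columns with
non-gap occupancy below 0.1 are removed before distance computation.

Trees are built per candidate group over all relevant baits plus the
candidates: neighbor joining on p-distances (pairwise mismatch fraction
over shared ungapped columns; zero-overlap pairs get distance 1) with
negative NJ branch lengths clamped to zero, or optionally FastTree.
"Closest bait" means minimum patristic distance — the sum of branch
lengths on the tip-to-tip path — which is invariant to rooting, the
reason it was chosen over root-dependent notions of tree proximity.
With fewer than four leaves, or on any tree-construction failure,
classification falls back to highest global-alignment identity with
deterministic tie-breaks (raw score, then lexicographic bait id). The
k = 3 nearest baits are inspected; if they span several reactions the
alternatives are recorded as co-candidates rather than discarded.

Candidates that pass the filter for several reactions are classified
once against the union of those reactions' bait sets, so the F3′H-vs-
F3′5′H style of ambiguity is resolved by overall proximity to whole
bait families, not by a single best hit. Per-reaction outputs
(candidate FASTA, alignment, tree, reports) are then written for the
assigned reaction only.

## Residue and domain screen

Reference positions are mapped onto candidates through alignment
columns; a gap in the candidate at a checked column is reported as
`absent` and blocks the functional call, but is kept distinct from a
`mismatch` — missing sequence is weaker evidence of non-functionality
than a contradicting residue, and the report preserves that
distinction. The prediction is conjunctive: functional iff every
residue rule matches (exact by default; an opt-in "similar" mode
accepts residues from the same coarse biochemical group —
aliphatic/aromatic/polar/acidic/basic — since imperfect conservation by
biochemically similar residues occurs at some positions) and every
domain is conserved. Domain conservation is identity over the columns
carrying the reference span, candidate gaps counting as mismatches,
with a default minimum of 0.6 — over a short motif this cleanly
separates homologous from random sequence and is configurable per rule.
"Non-functionality" is always relative to the expected function:
sub- or neofunctionalised enzymes will legitimately fail the screen.

Specificity rules are declared relative to a named anchor (e.g. the
start of DFR's 26-aa substrate-binding region) so that literature
positions like "position 3 of the domain" remain well-defined on any
reference; they append notes and never alter the prediction.

Contrasting-residue discovery aligns both sets jointly and reports
columns whose residues can be split into two disjoint sides covering at
least `purity` (default 0.9) of each family's ungapped rows; residues
are attributed to the side where they are relatively more frequent, and
positions are reported on a designated reference of the first set.

## Synthetic data and what the tests show

The generators plant known structure and record it as machine-readable
truth: families are derived from one ancestor by per-site substitution
(uniform over the 19 alternatives — no rate matrix, no indels; the
fixtures test bookkeeping and thresholds, not evolutionary realism)
with diagnostic positions and conserved motif spans held fixed;
transcripts are exactly CDS plus stop codon (no UTRs); genomes embed
reverse-translated genes (uniform codon usage) split at codon
boundaries into exons of ≥10 codons, separated by introns of 80–2000 nt
starting `GT` (or a requested non-canonical donor) and ending `AG`, on
random strands with random intergenic spacers.

Planted introns carry a *splice identifiability guarantee*: intron
interiors are resampled until no alternative phase-consistent GT..AG
pair exists within the stitcher's boundary-search window (±30 codons,
covering the search window plus alignment-edge slop). This makes the
planted boundaries the unique canonical interpretation of each
junction, so the genome-mode tests measure the stitcher itself rather
than the density of decoy splice dinucleotides in random DNA. Real
genomes offer no such guarantee: a decoy GT..AG pair near a true
junction, a phase-shifted intron of in-frame length, or a genuinely
non-canonical intron adjacent to a decoy can yield a plausible but
wrong stitch that only the junction-score ranking defends against.
Passing fixtures therefore demonstrate correct mechanics and exact
recovery under identifiable conditions, not exon-level accuracy on
arbitrary genomes. Similarly, UTR-free transcripts mean the
mode-equivalence results compare the three input paths on equal
footing; real assemblies with long UTRs will add fragment residues that
the residue screen then maps through the alignment (this is why
checking happens in alignment space, not at absolute positions).

Problem sizes in the default test and acceptance runs — three
reactions, six baits each, seven planted genes on a ~21 kb contig, 200
classification candidates, 30–100 resampled family pairs — keep a full
run in the low minutes on one CPU while exercising every stage;
all randomness flows from a single seed, and identical configuration
plus seed reproduces every output byte-for-byte.

## Known limitations

- Genome mode assumes subject genes are colinear with and approximately
  the length of some bait; large insertions, split loci across contigs,
  or very divergent exon structures degrade stitching.
- The internal aligner is exact but quadratic; very large bait sets or
  proteomes are better served by pointing the search at BLAST+.
- NJ on p-distances is a fallback, not a substitute for maximum
  likelihood on hard classification problems; FastTree is supported
  where fidelity matters.
- The functionality call is only as good as the supplied residue
  knowledge, and a "possibly non-functional" verdict flags a sequence
  for inspection — it is not a biochemical conclusion.
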