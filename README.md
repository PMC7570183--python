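# pathscreen

Knowledge-based screening of peptide, transcript, or genome sequences
for candidate enzymes of a metabolic pathway — shipped with knowledge
tables for the core flavonoid biosynthesis (CHS, STS, DFR), and
customisable to any pathway for which characterised *bait* sequences and
functionally relevant residues are known.

It is aimed at plant researchers who have a new proteome, transcriptome
assembly, or genome and want, for every reaction of a pathway, the best
candidate sequences together with an evidence-based prediction of
whether each candidate encodes a functional enzyme.

## The method

For each reaction the user supplies one FASTA file of bait peptides
(previously characterised enzymes of that reaction), designates one of
them as the *reference*, and lists functionally relevant residue
positions and domain spans 1-based on that reference in a small text
table. The screen then proceeds in four stages:

1. **Similarity search.** Subjects are searched locally against the
   baits (BLOSUM62, gap open 11 / extend 1). A hit is kept when its
   percent identity exceeds 40 % *and* its score exceeds 30 % of the
   bait's self-alignment score — a deliberately lenient filter that
   collects a comprehensive candidate set. Transcripts are first
   translated in all six frames into stop-free peptide fragments. For a
   genome, translated hits are treated as exons or exon fragments,
   grouped into loci by colinear chaining, and one isoform per locus is
   stitched such that every intron starts `GT` and ends `AG` on the
   coding strand; non-canonical junctions are never stitched — such
   loci are demoted to a flagged partial model.
2. **Refinement.** Candidates are aligned globally with the baits
   (MAFFT when available, an internal progressive aligner otherwise)
   and alignment columns with occupancy < 0.1 are removed.
3. **Classification.** Each candidate is assigned the reaction of its
   *closest* bait: minimum patristic distance on a phylogenetic tree
   (neighbor joining on p-distances, or FastTree) when a tree can be
   built, otherwise highest global-alignment identity. When the k
   nearest baits span several reactions, the alternatives are recorded
   — this is how members of closely related families (e.g. F3′H vs
   F3′5′H, or CHS vs STS) are told apart by overall similarity to the
   whole bait sets.
4. **Residue and domain screen.** Reference positions are mapped onto
   each candidate through the alignment. A candidate is predicted
   **functional** only if it matches the allowed residue at *every*
   checked position (e.g. the CHS diagnostics Q166 and Q167, which
   distinguish chalcone synthases from stilbene synthases showing
   Q166 H167 or H166 Q167) and conserves every checked domain (e.g. the
   malonyl-CoA-binding motif at 313–329 of the CHS reference); any
   violation yields **possibly_nonfunctional** with the violated rule
   named. Substrate-specificity sites only annotate: for DFR, N at
   position 3 of the 26-aa substrate-binding domain is reported as
   accepting all three dihydroflavonols, D as reduced dihydrokaempferol
   acceptance, and L/A as a dihydrokaempferol preference with reduced
   dihydromyricetin processing.

A companion tool discovers *contrasting residues* between two sequence
sets: alignment columns whose residues separate the families in at
least a configurable fraction (default 0.9) of rows per side.

## Worked example

Generate a synthetic three-reaction screen with known ground truth,
then annotate its peptides:

```bash
pathscreen fixtures --out demo --seed 7
pathscreen annotate --mode pep --subject demo/subjects_pep.fasta \
    --baits demo/config.tsv --out demo_run --seed 7
# 7 candidates, 6 predicted functional; outputs in demo_run
```

`demo_run/summary.tsv` (abridged):

```
reaction  candidate      closest_bait  metric         value     n_rules  n_matched  prediction              notes
CHS       subj_CHS_mut   CHS_4         tree_distance  0.161111  3        2          possibly_nonfunctional
CHS       subj_CHS_1     CHS_4         tree_distance  0.158333  3        3          functional
DFR       subj_DFR_1     DFR_5         tree_distance  0.226746  2        2          functional              substrate-binding position 3 is N: accepts dihydrokaempferol, dihydroquercetin, dihydromyricetin
```

Each row is one surviving candidate: its assigned reaction, the nearest
bait and the tree distance to it, how many residue/domain rules were
checked and matched, and the functionality prediction.
`subj_CHS_mut` is a planted Q166→H mutant (the stilbene-synthase
pattern); the per-reaction `residue_report.tsv` names the violation:

```
reaction  candidate     rule                 reference_pos  candidate_pos  observed  status
CHS       subj_CHS_mut  CHS-diagnostic-Q166  166            166            H         mismatch
CHS       subj_CHS_mut  CHS-diagnostic-Q167  167            167            Q         match
```

For real data, point `--baits` at your own pathway config (one line per
reaction: name, bait FASTA, reference id, rules table — see
`src/pathscreen/data/flavonoid/` for the shipped example) and choose
`--mode pep|rna|dna` to match your subject file. Genome mode
additionally writes `models.gff3` and `cds.fasta` with the stitched
gene models.

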