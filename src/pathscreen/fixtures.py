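"""Synthetic bait families, candidate peptides, transcripts and genomes.

Every generator is deterministic in its seed and returns a machine-
readable truth record alongside the sequences, so each pipeline stage
can be scored against known ground truth without external downloads.
The generators model the bookkeeping that the screen exercises — family
membership, planted diagnostic residues, exon/intron structure with
canonical splice dinucleotides — not evolutionary realism: substitutions
are uniform over the 19 alternative residues, codon choice is uniform,
and transcripts are bare coding sequences plus a stop codon.

Genomes come with a *splice identifiability guarantee*: after planting
an intron the generator resamples its interior until no alternative
phase-consistent donor/acceptor pair (``GT``..``AG``) exists within the
stitcher's boundary-search window.  The planted boundaries are thereby
the unique canonical interpretation of each junction, so genome-mode
tests measure the stitcher, not the density of decoy dinucleotides in
random DNA.  Real genomes offer no such guarantee; see the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np

from .seqkit import CODON_TABLE, Sequence

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NT4 = "ACGT"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
STOP_CODONS = _CODONS_BY_AA["*"]

# widest boundary window the stitcher will explore, in codons, plus slack
# for alignment-edge slop; the decoy scan covers this range
DECOY_SCAN_CODONS = 30


@dataclass
class FixtureTruth:
    """Ground truth serialized alongside every generated fixture."""

    seed: int
    families: dict = field(default_factory=dict)
    mutants: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        return cls(**json.loads(Path(path).read_text()))


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate(rng: np.random.Generator, residues: str, rate: float, frozen: set[int]) -> str:
    """Per-site substitution at ``rate``; 1-based positions in ``frozen`` kept."""
    out = list(residues)
    for i in range(len(out)):
        if (i + 1) in frozen:
            continue
        if rng.random() < rate:
            choices = [aa for aa in AA20 if aa != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def make_family(
    n: int,
    length: int,
    divergence: float,
    diagnostics: TSequence[tuple[int, str]],
    seed: int,
    family: str = "FAM",
    conserved_spans: TSequence[tuple[int, int]] = (),
    ancestor: str | None = None,
) -> tuple[list[Sequence], FixtureTruth]:
    """A bait family: n peptides diverged from one ancestor.

    Diagnostic positions (1-based) are held at the planted residue in
    every member; ``conserved_spans`` freezes whole motif spans at the
    ancestral state, emulating conserved functional domains.  Passing an
    explicit ``ancestor`` lets two families share descent (e.g. two
    enzyme classes separated only by their diagnostic residues).
    """
    if n < 2:
        raise ValueError("a family needs at least 2 members")
    rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = _random_peptide(rng, length)
    if len(ancestor) != length:
        raise ValueError("ancestor length mismatch")
    anc = list(ancestor)
    for pos, residue in diagnostics:
        if not 1 <= pos <= length:
            raise ValueError(f"diagnostic position {pos} outside 1..{length}")
        anc[pos - 1] = residue
    ancestor = "".join(anc)
    frozen = {pos for pos, _ in diagnostics}
    for start, end in conserved_spans:
        frozen.update(range(start, end + 1))
    members = [
        Sequence(f"{family}_{i + 1}", _mutate(rng, ancestor, divergence, frozen), "peptide")
        for i in range(n)
    ]
    truth = FixtureTruth(
        seed=seed,
        families={
            family: {
                "members": [m.id for m in members],
                "ancestor": ancestor,
                "diagnostics": [[pos, res] for pos, res in diagnostics],
                "conserved_spans": [list(s) for s in conserved_spans],
                "divergence": divergence,
                "length": length,
            }
        },
    )
    return members, truth


def make_mutant(seq: Sequence, edits: TSequence[tuple[int, str]], new_id: str | None = None) -> Sequence:
    """Exact point edits (1-based position, new residue); all else identical."""
    out = list(seq.residues)
    for pos, residue in edits:
        if not 1 <= pos <= len(out):
            raise ValueError(f"edit position {pos} outside 1..{len(out)}")
        out[pos - 1] = residue
    return Sequence(new_id or seq.id, "".join(out), seq.kind)


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniform random codon choice for each residue."""
    codons = []
    for aa in peptide:
        options = _CODONS_BY_AA.get(aa)
        if not options:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def make_transcript(peptide: Sequence, rng: np.random.Generator) -> Sequence:
    """Coding sequence of the peptide plus a stop codon."""
    cds = reverse_translate(peptide.residues, rng)
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    return Sequence(peptide.id, cds + stop, "dna")


# ---------------------------------------------------------------------------
# Genomes with planted multi-exon genes


@dataclass(frozen=True)
class GenePlan:
    peptide: Sequence
    n_exons: int
    donor: str = "GT"  # set to e.g. "GC" to plant a non-canonical intron
    strand: str | None = None  # None = random


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NT4), size=length))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _has_decoy_pair(local: str, d0: int, c0: int, donor: str) -> bool:
    """Any phase-consistent alternative GT..AG pair for this junction?

    ``d0``/``c0`` are the true last-exon-nt / first-exon-nt coordinates
    (1-based in ``local``); alternatives shift both by the same offset.
    """
    for k in range(-DECOY_SCAN_CODONS, DECOY_SCAN_CODONS + 1):
        for phase in range(3):
            if k == 0 and phase == 0 and donor == "GT":
                continue  # the planted boundary itself
            d = d0 + 3 * k + phase
            c = c0 + 3 * k + phase
            if d < 1 or c + 1 > len(local) or c - 3 < 0:
                continue
            if local[d : d + 2] == "GT" and local[c - 3 : c - 1] == "AG":
                return True
    return False


def _build_gene(
    plan: GenePlan, rng: np.random.Generator, intron_len_range: tuple[int, int]
) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
    """(coding-strand gene string, local exon spans, local intron spans)."""
    pep = plan.peptide.residues
    n_exons = plan.n_exons
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    if len(pep) < 10 * n_exons:
        raise ValueError("peptide must be at least 10 residues per exon")
    cds = reverse_translate(pep, rng)
    # exon cut points at codon boundaries, each exon >= 10 codons
    while True:
        cuts = sorted(rng.choice(np.arange(10, len(pep) - 9), size=n_exons - 1, replace=False))
        if all(b - a >= 10 for a, b in zip([0] + list(cuts), list(cuts) + [len(pep)])):
            break
    bounds = [0] + [3 * c for c in cuts] + [len(cds)]
    exon_seqs = [cds[bounds[i] : bounds[i + 1]] for i in range(n_exons)]
    lo, hi = intron_len_range
    intron_lens = [int(rng.integers(lo, hi + 1)) for _ in range(n_exons - 1)]

    def assemble(introns: list[str]) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]]]:
        parts, exon_spans, intron_spans = [], [], []
        pos = 0
        for i, exon in enumerate(exon_seqs):
            parts.append(exon)
            exon_spans.append((pos + 1, pos + len(exon)))
            pos += len(exon)
            if i < len(introns):
                parts.append(introns[i])
                intron_spans.append((pos + 1, pos + len(introns[i])))
                pos += len(introns[i])
        stop = STOP_CODONS[stop_choice]
        return "".join(parts) + stop, exon_spans, intron_spans

    stop_choice = int(rng.integers(len(STOP_CODONS)))
    introns = [
        plan.donor + _random_dna(rng, n - 4) + "AG" for n in intron_lens
    ]
    for attempt in range(500):
        local, exon_spans, intron_spans = assemble(introns)
        bad = None
        for j, (istart, iend) in enumerate(intron_spans):
            d0 = istart - 1  # last nt of the upstream exon
            c0 = iend + 1  # first nt of the downstream exon
            if _has_decoy_pair(local, d0, c0, plan.donor):
                bad = j
                break
        if bad is None:
            return local, exon_spans, intron_spans
        introns[bad] = plan.donor + _random_dna(rng, intron_lens[bad] - 4) + "AG"
    raise RuntimeError("could not build a decoy-free junction in 500 attempts")


def make_genome(
    genes: TSequence[GenePlan | tuple],
    intergenic_len: int = 2000,
    seed: int = 0,
    intron_len_range: tuple[int, int] = (80, 2000),
    contig_id: str = "contig1",
) -> tuple[Sequence, FixtureTruth]:
    """A single contig with the given genes planted on random strands.

    Each peptide is reverse-translated, split into exons at codon
    boundaries (every exon at least 10 codons), and separated by random
    introns starting with the plan's donor dinucleotide and ending AG; a
    stop codon follows the last exon.  Truth records forward-strand exon
    and intron spans, the strand, and the splice dinucleotides.
    """
    rng = np.random.default_rng(seed)
    plans = [g if isinstance(g, GenePlan) else GenePlan(*g) for g in genes]
    parts = [_random_dna(rng, intergenic_len)]
    offset = intergenic_len
    truth = FixtureTruth(
        seed=seed,
        params={"intergenic_len": intergenic_len, "intron_len_range": list(intron_len_range)},
    )
    for plan in plans:
        strand = plan.strand or ("+" if rng.random() < 0.5 else "-")
        local, exon_spans, intron_spans = _build_gene(plan, rng, intron_len_range)
        m = len(local)
        region = local if strand == "+" else _revcomp(local)

        def fwd(span: tuple[int, int]) -> list[int]:
            s, e = span
            if strand == "+":
                return [offset + s, offset + e]
            return [offset + m - e + 1, offset + m - s + 1]

        truth.genes.append(
            {
                "name": plan.peptide.id,
                "peptide": plan.peptide.residues,
                "contig": contig_id,
                "strand": strand,
                "n_exons": plan.n_exons,
                "donor": plan.donor,
                "exons": sorted(fwd(s) for s in exon_spans),
                "introns": sorted(fwd(s) for s in intron_spans),
            }
        )
        parts.append(region)
        offset += m
        spacer = _random_dna(rng, intergenic_len)
        parts.append(spacer)
        offset += intergenic_len
    genome = Sequence(contig_id, "".join(parts), "dna")
    return genome, truth


# ---------------------------------------------------------------------------
# A complete multi-reaction pathway fixture


@dataclass
class PathwayFixture:
    """In-memory handle on a generated pathway fixture directory."""

    root: Path
    config: Path
    subjects_pep: list[Sequence]
    subjects_rna: list[Sequence]
    genome: Sequence
    truth: FixtureTruth


# Per-reaction blueprints: ``diagnostics`` are pinned during family
# generation; ``rules`` are the residue-table rows (allowed sets may be
# wider than the pinned residue, e.g. the DFR substrate-specificity site
# where N/D/L/A are all naturally occurring).
REACTION_PLANS = {
    "CHS": {
        "length": 360,
        "diagnostics": [(166, "Q"), (167, "Q")],
        "rules": ["166 Q CHS-diagnostic-Q166", "167 Q CHS-diagnostic-Q167"],
        "domain": (313, 329, "malonyl-CoA-motif"),
        "extra": [],
    },
    "DFR": {
        "length": 340,
        "diagnostics": [(145, "K"), (133, "N")],
        "rules": ["145 K DFR-diagnostic-K145", "133 NDLA DFR-substrate-site"],
        "domain": None,
        "extra": [
            "@anchor substrate-binding 131 26",
            "@spec substrate-binding 3 N accepts dihydrokaempferol, dihydroquercetin, dihydromyricetin",
            "@spec substrate-binding 3 D reduced dihydrokaempferol acceptance",
            "@spec substrate-binding 3 L dihydrokaempferol preference, reduced dihydromyricetin processing",
            "@spec substrate-binding 3 A dihydrokaempferol preference, reduced dihydromyricetin processing",
        ],
    },
    "FLS": {
        "length": 330,
        "diagnostics": [(200, "G"), (230, "E")],
        "rules": ["200 G FLS-diagnostic-G200", "230 E FLS-diagnostic-E230"],
        "domain": None,
        "extra": [],
    },
}


def make_pathway_fixture(
    out_dir: str | Path,
    seed: int,
    n_baits: int = 6,
    bait_divergence: float = 0.12,
    candidate_divergence: float = 0.10,
    n_decoys: int = 2,
    exon_counts: TSequence[int] = (1, 2, 3, 2),
    intergenic_len: int = 1500,
    intron_len_range: tuple[int, int] = (80, 400),
) -> PathwayFixture:
    """Generate a three-reaction screen with known ground truth.

    Per reaction: a bait family (first member designated reference), a
    residue/domain table, planted *functional* candidate peptides (fresh
    family members), one planted loss-of-function mutant for the first
    reaction (diagnostic residue swapped, the pattern that separates
    chalcone synthases from stilbene synthases), and random decoy
    peptides.  Subjects are emitted in all three forms: peptides,
    transcripts (CDS + stop), and a genome with multi-exon genes.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    (out_dir / "knowledge").mkdir(parents=True, exist_ok=True)

    truth = FixtureTruth(seed=seed, params={"n_baits": n_baits})
    config_lines = []
    subjects: list[Sequence] = []
    gene_plans: list[GenePlan] = []
    functional: dict[str, list[str]] = {}
    mutants: list[dict] = []

    for r_i, (reaction, plan) in enumerate(sorted(REACTION_PLANS.items())):
        fam_seed = int(rng.integers(2**31 - 1))
        spans = [tuple(plan["domain"][:2])] if plan["domain"] else []
        baits, fam_truth = make_family(
            n=n_baits,
            length=plan["length"],
            divergence=bait_divergence,
            diagnostics=plan["diagnostics"],
            seed=fam_seed,
            family=reaction,
            conserved_spans=spans,
        )
        truth.families.update(fam_truth.families)
        bait_fasta = out_dir / "knowledge" / f"{reaction}.fasta"
        with open(bait_fasta, "w") as out:
            for b in baits:
                out.write(f">{b.id}\n{b.residues}\n")
        table = out_dir / "knowledge" / f"{reaction}.residues.txt"
        rows = list(plan["rules"])
        if plan["domain"]:
            s, e, name = plan["domain"]
            rows.append(f"{s}-{e} {name} 0.6")
        rows += plan["extra"]
        table.write_text("\n".join(rows) + "\n")
        config_lines.append(
            f"{reaction}\tknowledge/{bait_fasta.name}\t{baits[0].id}\tknowledge/{table.name}"
        )

        ancestor = truth.families[reaction]["ancestor"]
        frozen = {pos for pos, _ in plan["diagnostics"]}
        for s_e in truth.families[reaction]["conserved_spans"]:
            frozen.update(range(s_e[0], s_e[1] + 1))
        cands = []
        for c_i in range(2):
            cand = Sequence(
                f"subj_{reaction}_{c_i + 1}",
                _mutate(rng, ancestor, candidate_divergence, frozen),
                "peptide",
            )
            cands.append(cand)
        functional[reaction] = [c.id for c in cands]
        subjects.extend(cands)
        if r_i == 0:
            pos, res = plan["diagnostics"][0]
            swap = "H" if res != "H" else "Q"
            mut = make_mutant(cands[0], [(pos, swap)], new_id=f"subj_{reaction}_mut")
            subjects.append(mut)
            mutants.append(
                {"id": mut.id, "reaction": reaction, "edits": [[pos, swap]],
                 "violates": f"{reaction}-diagnostic-{res}{pos}"}
            )
    for d_i in range(n_decoys):
        subjects.append(
            Sequence(f"decoy_{d_i + 1}", _random_peptide(rng, 300), "peptide")
        )

    truth.mutants = mutants
    truth.params["functional"] = functional

    # peptide subjects
    pep_fasta = out_dir / "subjects_pep.fasta"
    with open(pep_fasta, "w") as out:
        for s in subjects:
            out.write(f">{s.id}\n{s.residues}\n")

    # transcripts: CDS + stop for every subject
    transcripts = [make_transcript(s, rng) for s in subjects]
    rna_fasta = out_dir / "subjects_rna.fasta"
    with open(rna_fasta, "w") as out:
        for s in transcripts:
            out.write(f">{s.id}\n{s.residues}\n")

    # genome: every non-decoy subject becomes a gene with 1-3 exons
    genic = [s for s in subjects if not s.id.startswith("decoy_")]
    for i, s in enumerate(genic):
        gene_plans.append(GenePlan(s, exon_counts[i % len(exon_counts)]))
    genome_seed = int(rng.integers(2**31 - 1))
    genome, genome_truth = make_genome(
        gene_plans,
        intergenic_len=intergenic_len,
        seed=genome_seed,
        intron_len_range=intron_len_range,
    )
    truth.genes = genome_truth.genes
    truth.params["genome"] = genome_truth.params
    dna_fasta = out_dir / "subjects_dna.fasta"
    with open(dna_fasta, "w") as out:
        out.write(f">{genome.id}\n")
        for i in range(0, len(genome.residues), 80):
            out.write(genome.residues[i : i + 80] + "\n")

    config = out_dir / "config.tsv"
    config.write_text("\n".join(config_lines) + "\n")
    truth.to_json(out_dir / "truth.json")
    return PathwayFixture(
        root=out_dir,
        config=config,
        subjects_pep=subjects,
        subjects_rna=transcripts,
        genome=genome,
        truth=truth,
    )
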