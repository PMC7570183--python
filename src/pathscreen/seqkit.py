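"""Nucleotide and peptide primitives.

FASTA I/O, reverse complement, six-frame translation, and extraction of
stop-free peptide fragments from nucleotide sequences.  Genome and
transcript screening both reduce DNA input to peptide space through
:func:`six_frame_fragments`; every fragment carries enough coordinate
information to map peptide hits back onto the parent nucleotide sequence.

Translation uses the standard genetic code.  Any codon containing a
character outside ``ACGT`` (typically ``N``) translates to ``X``; ``X``
never satisfies a residue rule downstream, so ambiguous positions are
conservatively treated as uninformative.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NT_ALPHABET = set("ACGT") | {"N"}

STOP = "*"
FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _build_codon_table() -> dict[str, str]:
    table = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
    for codon in CodonTable.unambiguous_dna_by_id[1].stop_codons:
        table[codon] = STOP
    return table


CODON_TABLE = _build_codon_table()


@dataclass(frozen=True)
class Sequence:
    """A named peptide or nucleotide sequence.

    The id is the FASTA header token up to the first whitespace; residues
    are stored upper-case and validated against the alphabet of ``kind``.
    """

    id: str
    residues: str
    kind: str  # "peptide" or "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if self.kind not in ("peptide", "dna"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        alphabet = AA_ALPHABET if self.kind == "peptide" else NT_ALPHABET
        bad = set(self.residues) - alphabet - {STOP}
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"not in the {self.kind} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TranslationFragment:
    """A maximal stop-free peptide run from one reading frame.

    ``start_nt`` is the 1-based forward-strand coordinate of the base of the
    fragment's first codon that is closest to the parent's 5' end: for plus
    frames this is the first base of the first codon, for minus frames it is
    the (forward-strand) position pairing with the last base of the last
    codon, so that ``start_nt..start_nt + 3*len - 1`` always spans the
    fragment on the forward strand.
    """

    parent_id: str
    frame: int
    start_nt: int
    residues: str

    @property
    def id(self) -> str:
        sign = "+" if self.frame > 0 else "-"
        return f"{self.parent_id}_fr{sign}{abs(self.frame)}_{self.start_nt}"

    def forward_span(self) -> tuple[int, int]:
        """1-based inclusive forward-strand span covered by the fragment."""
        return self.start_nt, self.start_nt + 3 * len(self.residues) - 1

    def genomic_interval(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Forward-strand nt span of peptide interval ``p_start..p_end``.

        Peptide coordinates are 1-based within the fragment.
        """
        if not (1 <= p_start <= p_end <= len(self.residues)):
            raise ValueError("peptide interval outside fragment")
        lo, hi = self.forward_span()
        if self.frame > 0:
            return lo + 3 * (p_start - 1), lo + 3 * p_end - 1
        return hi - 3 * p_end + 1, hi - 3 * (p_start - 1)


def reverse_complement(seq: Sequence) -> Sequence:
    """Reverse complement of a DNA sequence (``N`` maps to ``N``)."""
    if seq.kind != "dna":
        raise TypeError("reverse_complement requires a dna sequence")
    return Sequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1], "dna")


def translate(seq: Sequence, frame: int) -> str:
    """Translate one reading frame; stops appear as ``*``.

    Frames +1/+2/+3 read the forward strand starting at offsets 0/1/2,
    frames -1/-2/-3 read the reverse complement likewise.  The trailing
    partial codon is dropped; codons containing non-ACGT characters
    translate to ``X``.
    """
    if seq.kind != "dna":
        raise TypeError("translate requires a dna sequence")
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    s = seq.residues if frame > 0 else reverse_complement(seq).residues
    s = s[abs(frame) - 1 :]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def six_frame_fragments(seq: Sequence, min_fragment_len: int = 50) -> list[TranslationFragment]:
    """Maximal stop-free peptide runs in all six frames.

    Returns every run of length >= ``min_fragment_len``; the coordinate
    bookkeeping guarantees each fragment re-translates exactly from the
    parent at its recorded frame and offset.
    """
    if min_fragment_len < 1:
        raise ValueError("min_fragment_len must be >= 1")
    n = len(seq)
    fragments: list[TranslationFragment] = []
    for frame in FRAMES:
        pep = translate(seq, frame)
        off = abs(frame) - 1  # nt offset on the coding strand
        start = 0
        for run in pep.split(STOP):
            if len(run) >= min_fragment_len:
                # coding-strand nt offset (0-based) of the run's first codon
                nt0 = off + 3 * start
                if frame > 0:
                    start_nt = nt0 + 1
                else:
                    # coding strand is the reverse complement; map its
                    # codon span back to forward-strand coordinates
                    start_nt = n - (nt0 + 3 * len(run)) + 1
                fragments.append(TranslationFragment(seq.id, frame, start_nt, run))
            start += len(run) + 1
    return fragments


# ---------------------------------------------------------------------------
# FASTA I/O


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, kind: str) -> list[Sequence]:
    """Read a (optionally gzip-compressed) FASTA file.

    IDs are truncated at the first whitespace; duplicate ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: list[Sequence] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
            seen.add(record.id)
            seqs.append(Sequence(record.id, str(record.seq), kind))
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        for seq in seqs:
            handle.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i : i + width] + "\n")
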