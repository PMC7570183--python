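"""Local similarity search of subject sequences against bait peptides.

Candidate discovery follows the lenient two-threshold rule: a local hit
is kept when its percent identity over the aligned columns exceeds
``min_identity`` (default 0.40) *and* its score exceeds ``min_score_ratio``
(default 0.30) of the bait's self-alignment score.  Both comparisons are
strict, matching the "above 40% / above 30%" reading of the thresholds.

Two engines sit behind the same interface: the default internal engine
built on :class:`Bio.Align.PairwiseAligner` (BLOSUM62, gap open 11 /
extend 1), and an optional wrapper around the BLAST+ ``blastp`` binary
for interchange with external tooling.  Nucleotide subjects are reduced
to peptide space with six-frame stop-free fragments before searching, so
transcript and genome screening reuse the peptide path.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence as TSequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .knowledge_base import BaitSet
from .seqkit import Sequence, TranslationFragment, six_frame_fragments, write_fasta


@dataclass(frozen=True)
class Scoring:
    """Protein scoring scheme (substitution matrix + affine gaps)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class SearchHit:
    """One local alignment of a bait (query) against a subject."""

    query_id: str
    subject_id: str
    identity: float  # fraction of identical aligned columns
    score: float
    query_self_score: float
    q_start: int  # 1-based inclusive, bait coordinates
    q_end: int
    s_start: int  # 1-based inclusive, subject (peptide) coordinates
    s_end: int
    frame: int | None = None  # translated search only
    contig: str | None = None  # genome mode: parent nucleotide sequence
    strand: str | None = None
    g_start: int | None = None  # genome mode: forward-strand nt span
    g_end: int | None = None
    fragment: TranslationFragment | None = None

    @property
    def score_ratio(self) -> float:
        return self.score / self.query_self_score


def _make_aligner(scoring: Scoring, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def self_score(seq: Sequence, scoring: Scoring = Scoring()) -> float:
    """Score of a gap-free alignment of the sequence against itself.

    Equals the sum of substitution-matrix diagonal entries over the
    residues, which is the maximum attainable score for this query.
    """
    if seq.kind != "peptide":
        raise TypeError("self_score requires a peptide sequence")
    if not seq.residues:
        raise ValueError("empty sequence")
    matrix = substitution_matrices.load(scoring.matrix)
    return float(sum(matrix[aa, aa] for aa in seq.residues))


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int]:
    """(matches, columns, q_start, q_end, s_start, s_end) of one alignment."""
    q_blocks, s_blocks = alignment.aligned
    query = alignment.query if isinstance(alignment.query, str) else str(alignment.query)
    target = alignment.target if isinstance(alignment.target, str) else str(alignment.target)
    matches = 0
    columns = 0
    prev_q_end = prev_s_end = None
    for (t0, t1), (q0, q1) in zip(q_blocks, s_blocks):
        if prev_q_end is not None:
            columns += max(t0 - prev_q_end, q0 - prev_s_end)
        for a, b in zip(target[t0:t1], query[q0:q1]):
            matches += a == b
        columns += t1 - t0
        prev_q_end, prev_s_end = t1, q1
    t_start, t_end = q_blocks[0][0], q_blocks[-1][1]
    s_start, s_end = s_blocks[0][0], s_blocks[-1][1]
    return matches, columns, t_start + 1, t_end, s_start + 1, s_end


def _alignment_columns(
    alignment, scoring: Scoring
) -> list[tuple[int, int, float, bool, bool]]:
    """Per-column (query_pos, subject_pos, score, is_match, is_gap).

    Positions are 1-based; gap columns carry the position of the
    ungapped side and the gap penalty (open for the first column of a
    run, extend afterwards).
    """
    matrix = substitution_matrices.load(scoring.matrix)
    q_blocks, s_blocks = alignment.aligned
    target = str(alignment.target)
    query = str(alignment.query)
    cols: list[tuple[int, int, float, bool]] = []
    prev_t = prev_s = None
    for (t0, t1), (s0, s1) in zip(q_blocks, s_blocks):
        if prev_t is not None:
            for k in range(t0 - prev_t):
                penalty = -scoring.gap_open if k == 0 else -scoring.gap_extend
                cols.append((prev_t + k + 1, prev_s, penalty, False, True))
            for k in range(s0 - prev_s):
                penalty = -scoring.gap_open if k == 0 else -scoring.gap_extend
                cols.append((prev_t, prev_s + k + 1, penalty, False, True))
        for k in range(t1 - t0):
            a, b = target[t0 + k], query[s0 + k]
            try:
                sc = float(matrix[a, b])
            except (KeyError, IndexError):
                sc = -1.0
            cols.append((t0 + k + 1, s0 + k + 1, sc, a == b, False))
        prev_t, prev_s = t1, s1
    return cols


def _xdrop_segments(
    scores: list[float], xdrop: float = 40.0
) -> list[tuple[int, int]]:
    """Split a column score profile into HSP-like segments.

    Emulates the X-drop behaviour of seeded local search: a segment ends
    where the running score either falls back to zero or drops more than
    ``xdrop`` below its running maximum (e.g. while crossing an intron
    that happened to be translated in frame).  Returns inclusive column
    index ranges ending at each segment's score maximum.
    """
    segments: list[tuple[int, int]] = []
    start = None
    cum = best = 0.0
    best_i = -1
    i = 0
    while i < len(scores):
        if start is None:
            if scores[i] > 0:
                start, cum, best, best_i = i, scores[i], scores[i], i
            i += 1
            continue
        cum += scores[i]
        if cum > best:
            best, best_i = cum, i
        if cum <= 0 or best - cum > xdrop:
            segments.append((start, best_i))
            start, cum, best, best_i = None, 0.0, 0.0, -1
        i += 1
    if start is not None and best > 0:
        segments.append((start, best_i))
    return segments


def _trim_hsp_ends(
    cols: list[tuple[int, int, float, bool, bool]],
    window: int = 6,
    min_matches: int = 4,
) -> list[tuple[int, int, float, bool, bool]]:
    """Trim low-identity or gappy tails off an HSP's column list.

    A locally optimal alignment may carry a net-positive excursion of
    near-random columns at either end (with gaps inside it), which would
    corrupt coordinate anchoring downstream; ends are cut back until the
    terminal ``window`` columns are gap-free, hold at least
    ``min_matches`` identities, and the outermost column is a match.
    """
    cols = list(cols)
    for _ in range(2):
        while cols and (
            not cols[-1][3]
            or any(c[4] for c in cols[-window:])
            or sum(1 for c in cols[-window:] if c[3]) < min(min_matches, len(cols))
        ):
            cols.pop()
        cols.reverse()
    return cols


def align_local(query: Sequence, subject_residues: str, scoring: Scoring = Scoring()):
    """Best local alignment; returns ``None`` if no positive-scoring one."""
    aligner = _make_aligner(scoring, "local")
    score = aligner.score(query.residues, subject_residues)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(query.residues, subject_residues)))
    return score, alignment


def global_identity(a: str, b: str, scoring: Scoring = Scoring()) -> tuple[float, float]:
    """(identity, score) of the best global alignment of two peptides."""
    aligner = _make_aligner(scoring, "global")
    alignment = next(iter(aligner.align(a, b)))
    matches, columns, *_ = _alignment_stats(alignment)
    return matches / columns if columns else 0.0, float(alignment.score)


def search_candidates(
    baits: BaitSet,
    subjects: TSequence[Sequence],
    mode: str,
    scoring: Scoring = Scoring(),
    min_fragment_len: int = 50,
    min_raw_score: float = 40.0,
) -> list[SearchHit]:
    """Search every bait against every subject.

    ``mode`` is ``pep`` (peptide subjects), ``rna`` (transcripts; subjects
    are expanded into six-frame stop-free fragments first) or ``dna``
    (genome; like ``rna`` but hits additionally carry forward-strand
    genomic coordinates so they can be chained into gene models).
    ``min_raw_score`` is a cheap prefilter on the raw local score that
    skips hopeless bait/fragment pairs before the full alignment is built.
    """
    if mode not in ("pep", "rna", "dna"):
        raise ValueError(f"unknown mode {mode!r}")
    expected_kind = "peptide" if mode == "pep" else "dna"
    for subject in subjects:
        if subject.kind != expected_kind:
            raise ValueError(
                f"mode {mode!r} requires {expected_kind} subjects, "
                f"got {subject.kind!r} for {subject.id!r}"
            )

    if mode == "pep":
        targets: list[tuple[str, str, TranslationFragment | None]] = [
            (s.id, s.residues, None) for s in subjects
        ]
    else:
        targets = []
        for subject in subjects:
            for frag in six_frame_fragments(subject, min_fragment_len):
                targets.append((frag.id, frag.residues, frag))

    hits: list[SearchHit] = []
    for bait in baits:
        qss = self_score(bait, scoring)
        for subject_id, residues, frag in targets:
            result = align_local(bait, residues, scoring)
            if result is None or result[0] < min_raw_score:
                continue
            score, alignment = result
            if mode == "dna":
                # split HSP-style so hits do not bridge in-frame introns
                cols = _alignment_columns(alignment, scoring)
                pieces = []
                for c0, c1 in _xdrop_segments([c[2] for c in cols]):
                    seg = _trim_hsp_ends(cols[c0 : c1 + 1])
                    if not seg:
                        continue
                    seg_score = sum(c[2] for c in seg)
                    if seg_score < min_raw_score:
                        continue
                    matches = sum(1 for c in seg if c[3])
                    pieces.append(
                        (matches, len(seg), seg[0][0], seg[-1][0], seg[0][1],
                         seg[-1][1], seg_score)
                    )
            else:
                matches, columns, q0, q1, s0, s1 = _alignment_stats(alignment)
                pieces = [(matches, columns, q0, q1, s0, s1, float(score))]
            for matches, columns, q0, q1, s0, s1, piece_score in pieces:
                hit = SearchHit(
                    query_id=bait.id,
                    subject_id=subject_id,
                    identity=matches / columns,
                    score=float(piece_score),
                    query_self_score=qss,
                    q_start=q0,
                    q_end=q1,
                    s_start=s0,
                    s_end=s1,
                )
                if frag is not None:
                    g_start, g_end = frag.genomic_interval(s0, s1)
                    hit = replace(
                        hit,
                        frame=frag.frame,
                        contig=frag.parent_id,
                        strand="+" if frag.frame > 0 else "-",
                        g_start=g_start,
                        g_end=g_end,
                        fragment=frag,
                    )
                hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[SearchHit],
    min_identity: float = 0.40,
    min_score_ratio: float = 0.30,
) -> list[SearchHit]:
    """Retain hits with identity > ``min_identity`` and
    score/self-score > ``min_score_ratio`` (both strictly above)."""
    if not 0.0 <= min_identity <= 1.0 or not 0.0 <= min_score_ratio <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    return [
        h
        for h in hits
        if h.identity > min_identity and h.score / h.query_self_score > min_score_ratio
    ]


# ---------------------------------------------------------------------------
# Optional external blastp engine and outfmt-6-style interchange


def blastp_available() -> bool:
    return shutil.which("blastp") is not None and shutil.which("makeblastdb") is not None


def search_candidates_blastp(
    baits: BaitSet, subjects: TSequence[Sequence], evalue: float = 1e-3
) -> list[SearchHit]:
    """Peptide search through the external BLAST+ ``blastp`` binary.

    Scores are bitscores; the self-score denominator is the bait's
    bitscore against itself from the same database, keeping the ratio
    filter unit-consistent within the engine.
    """
    if not blastp_available():
        raise EnvironmentError("blastp/makeblastdb not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_fasta(list(baits), tmp / "baits.fasta")
        write_fasta(subjects, tmp / "subjects.fasta")
        subprocess.run(
            ["makeblastdb", "-in", "subjects.fasta", "-dbtype", "prot"],
            cwd=tmp, check=True, capture_output=True,
        )
        subprocess.run(
            ["makeblastdb", "-in", "baits.fasta", "-dbtype", "prot"],
            cwd=tmp, check=True, capture_output=True,
        )
        fmt = "6 qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
        run = lambda db, out: subprocess.run(  # noqa: E731
            ["blastp", "-query", "baits.fasta", "-db", db, "-outfmt", fmt,
             "-evalue", str(evalue), "-out", out],
            cwd=tmp, check=True, capture_output=True,
        )
        run("baits.fasta", "self.tsv")
        run("subjects.fasta", "hits.tsv")
        self_scores: dict[str, float] = {}
        for line in (tmp / "self.tsv").read_text().splitlines():
            cols = line.split("\t")
            if cols[0] == cols[1]:
                self_scores[cols[0]] = max(self_scores.get(cols[0], 0.0), float(cols[11]))
        hits: list[SearchHit] = []
        best: dict[tuple[str, str], SearchHit] = {}
        for line in (tmp / "hits.tsv").read_text().splitlines():
            cols = line.split("\t")
            hit = SearchHit(
                query_id=cols[0],
                subject_id=cols[1],
                identity=float(cols[2]) / 100.0,
                score=float(cols[11]),
                query_self_score=self_scores.get(cols[0], 1.0),
                q_start=int(cols[6]),
                q_end=int(cols[7]),
                s_start=int(cols[8]),
                s_end=int(cols[9]),
            )
            key = (hit.query_id, hit.subject_id)
            if key not in best or hit.score > best[key].score:
                best[key] = hit
        hits = list(best.values())
    return hits


TSV_HEADER = "qseqid\tsseqid\tpident\tlength\tqstart\tqend\tsstart\tsend\tbitscore\tself_score"


def write_hits_tsv(hits: Iterable[SearchHit], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        handle.write(TSV_HEADER + "\n")
        for h in hits:
            length = h.q_end - h.q_start + 1
            handle.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity * 100:.2f}\t{length}\t"
                f"{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.score:.1f}\t{h.query_self_score:.1f}\n"
            )


def read_hits_tsv(path: str | Path) -> list[SearchHit]:
    hits = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        c = line.split("\t")
        hits.append(
            SearchHit(
                query_id=c[0], subject_id=c[1], identity=float(c[2]) / 100.0,
                score=float(c[8]), query_self_score=float(c[9]),
                q_start=int(c[4]), q_end=int(c[5]), s_start=int(c[6]), s_end=int(c[7]),
            )
        )
    return hits
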