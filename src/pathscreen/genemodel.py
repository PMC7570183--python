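"""Genome mode: from translated-search hits to one gene model per locus.

Hits of a bait against a genome are treated as exons or exon fragments.
Colinear hits on one contig and strand are grouped into loci, and for
each locus a single isoform is stitched such that every intron starts
``GT`` and ends ``AG`` on the coding strand (canonical splice sites
only).  Loci for which no canonical, stop-free stitching exists are
demoted to their single best fragment and flagged
``non-canonical-or-partial`` rather than silently dropped.

Boundary search: because an intron's removal must preserve the reading
of the bait, the donor and acceptor positions are not independent.  For
a junction between two exon fragments the stitcher enumerates candidate
peptide split points ``q*`` (the last bait residue encoded by the left
exon) and intron phases 0-2; each pair determines both the donor and the
acceptor coordinate through the fragments' own codon mappings.  Among
the GT..AG-consistent, in-frame, stop-free choices the one whose spliced
junction peptide scores best against the bait wins (ties: smallest total
boundary shift, then leftmost donor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Align import substitution_matrices

from .search import Scoring, SearchHit
from .seqkit import CODON_TABLE, STOP, Sequence, reverse_complement

MIN_INTRON_LEN = 20
MAX_QUERY_OVERLAP = 10  # aa; adjacent exon hits may share only edge slop
PARTIAL_FLAG = "non-canonical-or-partial"
CANONICAL_FLAG = "canonical"


@dataclass(frozen=True)
class ExonFragment:
    """One translated-search hit reinterpreted as a (partial) exon."""

    contig: str
    strand: str
    g_start: int  # forward-strand 1-based inclusive
    g_end: int
    q_start: int  # bait peptide coordinates
    q_end: int
    score: float

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise ValueError("g_start must be <= g_end")


@dataclass
class Locus:
    """Colinear exon fragments of one bait on one contig and strand."""

    contig: str
    strand: str
    query_id: str
    fragments: list[ExonFragment]
    bait: Sequence | None = None

    @property
    def total_score(self) -> float:
        return sum(f.score for f in self.fragments)

    @property
    def g_span(self) -> tuple[int, int]:
        return min(f.g_start for f in self.fragments), max(f.g_end for f in self.fragments)


@dataclass
class GeneModel:
    """One stitched isoform: exons, introns, CDS and encoded peptide."""

    name: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # forward-strand 1-based, sorted ascending
    introns: list[tuple[int, int]]
    cds: str
    peptide: str
    flag: str = CANONICAL_FLAG
    source_bait: str = ""
    score: float = 0.0  # summed alignment score of the source locus

    @property
    def is_partial(self) -> bool:
        return self.flag == PARTIAL_FLAG


def _fragment_from_hit(hit: SearchHit) -> ExonFragment:
    if hit.g_start is None or hit.strand is None:
        raise ValueError("group_hits requires dna-mode hits with genomic coordinates")
    return ExonFragment(
        contig=hit.contig,
        strand=hit.strand,
        g_start=int(hit.g_start),
        g_end=int(hit.g_end),
        q_start=int(hit.q_start),
        q_end=int(hit.q_end),
        score=float(hit.score),
    )


def _coding_order_key(frag: ExonFragment) -> int:
    return frag.g_start if frag.strand == "+" else -frag.g_end


def _coding_gap(prev: ExonFragment, cur: ExonFragment) -> int:
    """nt between two fragments in coding order (negative = overlap)."""
    if prev.strand == "+":
        return cur.g_start - prev.g_end - 1
    return prev.g_start - cur.g_end - 1


def group_hits(
    hits: Iterable[SearchHit],
    max_intron_len: int = 20000,
    baits: Mapping[str, Sequence] | None = None,
) -> list[Locus]:
    """Partition dna-mode hits into candidate loci.

    Hits of one bait on one contig/strand are chained in coding order:
    consecutive chain members must advance colinearly in bait
    coordinates with a genomic gap between ``MIN_INTRON_LEN`` and
    ``max_intron_len``.  Chains are extracted iteratively by a dynamic
    program maximizing summed fragment score, so spurious hits
    interleaved between true exons cannot break a gene apart, and a
    regression of the query coordinate separates tandem paralogs.
    Chains of different baits whose genomic spans overlap describe the
    same locus; the best-scoring chain represents it.
    """
    by_group: dict[tuple[str, str, str], list[ExonFragment]] = {}
    for hit in hits:
        frag = _fragment_from_hit(hit)
        by_group.setdefault((hit.query_id, frag.contig, frag.strand), []).append(frag)

    chains: list[Locus] = []
    for (query_id, contig, strand), frags in sorted(by_group.items()):
        frags.sort(key=lambda f: (_coding_order_key(f), f.q_start))
        remaining = list(frags)
        while remaining:
            chain = _best_chain(remaining, max_intron_len)
            chains.append(Locus(contig, strand, query_id, chain))
            chosen = set(id(f) for f in chain)
            remaining = [f for f in remaining if id(f) not in chosen]

    # merge chains from different baits that describe the same genomic locus
    loci: list[Locus] = []
    for locus in sorted(
        chains, key=lambda l: (l.contig, l.strand, -l.total_score, l.query_id)
    ):
        lo, hi = locus.g_span
        for kept in loci:
            if kept.contig == locus.contig and kept.strand == locus.strand:
                klo, khi = kept.g_span
                if lo <= khi and klo <= hi:
                    break
        else:
            loci.append(locus)
    loci.sort(key=lambda l: (l.contig, l.strand, l.g_span))
    if baits is not None:
        for locus in loci:
            locus.bait = baits.get(locus.query_id)
    return loci


def _best_chain(frags: list[ExonFragment], max_intron_len: int) -> list[ExonFragment]:
    """Score-maximal colinear chain (weighted LIS over coding order)."""
    n = len(frags)
    best = [f.score for f in frags]
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            gap = _coding_gap(frags[j], frags[i])
            colinear = (
                frags[i].q_start > frags[j].q_start
                and frags[i].q_end > frags[j].q_end
                and frags[j].q_end - frags[i].q_start + 1 <= MAX_QUERY_OVERLAP
            )
            if MIN_INTRON_LEN <= gap <= max_intron_len and colinear:
                cand = best[j] + frags[i].score
                if cand > best[i]:
                    best[i] = cand
                    back[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    chain = []
    while end != -1:
        chain.append(frags[end])
        end = back[end]
    return list(reversed(chain))


# ---------------------------------------------------------------------------
# Stitching


@dataclass(frozen=True)
class _CFrag:
    """Fragment in coding-strand coordinates (1-based, ascending)."""

    c_start: int
    c_end: int
    q_start: int
    q_end: int
    score: float


def _to_coding(frag: ExonFragment, contig_len: int) -> _CFrag:
    if frag.strand == "+":
        return _CFrag(frag.g_start, frag.g_end, frag.q_start, frag.q_end, frag.score)
    return _CFrag(
        contig_len - frag.g_end + 1,
        contig_len - frag.g_start + 1,
        frag.q_start,
        frag.q_end,
        frag.score,
    )


def _translate_frame0(cds: str) -> str:
    return "".join(
        CODON_TABLE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - len(cds) % 3, 3)
    )


@dataclass(frozen=True)
class _JunctionOption:
    donor_end: int  # last exon nt of the left exon (coding coords)
    acceptor_start: int  # first exon nt of the right exon
    junction_score: float
    shift: int


def _junction_options(
    left: _CFrag,
    right: _CFrag,
    coding: str,
    bait: Sequence | None,
    search_window: int,
    matrix,
) -> list[_JunctionOption]:
    """All GT..AG-consistent boundary choices for one junction, best first."""
    w3 = max(1, search_window // 3)
    ref = min(left.q_end, right.q_start - 1)
    q_lo = max(left.q_start, min(left.q_end, right.q_start - 1) - w3)
    q_hi = min(right.q_end - 1, max(left.q_end, right.q_start - 1) + w3)
    n = len(coding)
    options: list[_JunctionOption] = []
    for q_star in range(q_lo, q_hi + 1):
        for phase in range(3):
            d = left.c_end + 3 * (q_star - left.q_end) + phase
            c = right.c_start + 3 * (q_star + 1 - right.q_start) + phase
            if d < left.c_start or c - 1 > right.c_end:
                continue
            if c - d - 1 < MIN_INTRON_LEN:
                continue
            if d + 2 > n or c - 3 < 0:
                continue
            if coding[d : d + 2] != "GT" or coding[c - 3 : c - 1] != "AG":
                continue
            score = _score_junction(left, right, coding, bait, q_star, phase, matrix)
            if score is None:
                continue
            shift = abs(d - left.c_end) + abs(c - right.c_start)
            options.append(_JunctionOption(d, c, score, shift))
    options.sort(key=lambda o: (-o.junction_score, o.shift, o.donor_end))
    return options


def _score_junction(
    left: _CFrag,
    right: _CFrag,
    coding: str,
    bait: Sequence | None,
    q_star: int,
    phase: int,
    matrix,
    window: int = 10,
) -> float | None:
    """Gap-free score of the spliced junction peptide against the bait.

    Returns ``None`` when the spliced junction contains a stop codon.
    Without a bait to score against, every stop-free option scores 0 and
    ranking falls back to the shift/position tie-breaks.
    """
    k_l = min(window, q_star - left.q_start + 1)
    k_r = min(window, right.q_end - q_star - 1)
    # coding-strand start of bait codon j in the left/right exon mapping
    left_first = left.c_end + 3 * (q_star - k_l + 1 - left.q_end) - 2
    d = left.c_end + 3 * (q_star - left.q_end) + phase
    c = right.c_start + 3 * (q_star + 1 - right.q_start) + phase
    right_last = right.c_start + 3 * (q_star + k_r + 1 - right.q_start) - 1
    if left_first < 1 or right_last > len(coding):
        return None
    spliced = coding[left_first - 1 : d] + coding[c - 1 : right_last]
    pep = _translate_frame0(spliced)
    if STOP in pep:
        return None
    if bait is None:
        return 0.0
    ref = bait.residues[q_star - k_l : q_star + k_r + 1]
    total = 0.0
    for a, b in zip(pep, ref):
        try:
            total += matrix[a, b]
        except (KeyError, IndexError):
            total -= 1.0
    return total


def stitch_isoform(
    locus: Locus,
    genome: Sequence,
    search_window: int = 30,
    scoring: Scoring = Scoring(),
    name: str | None = None,
) -> GeneModel:
    """Construct the single isoform of a locus.

    Boundary choices are searched junction by junction (best first, with
    backtracking on downstream stop codons); outer exon edges are then
    extended so the model covers the bait's full query span, trimmed back
    codon-wise if the extension would run into a stop.
    """
    if genome.kind != "dna":
        raise TypeError("stitch_isoform requires a dna genome sequence")
    contig_len = len(genome)
    strand = locus.strand
    coding = genome.residues if strand == "+" else reverse_complement(genome).residues
    frags = sorted(
        (_to_coding(f, contig_len) for f in locus.fragments), key=lambda f: f.c_start
    )
    matrix = substitution_matrices.load(scoring.matrix)
    bait = locus.bait
    if name is None:
        lo, hi = locus.g_span
        name = f"{locus.contig}_{strand}_{lo}_{hi}"

    option_lists = [
        _junction_options(frags[i], frags[i + 1], coding, bait, search_window, matrix)
        for i in range(len(frags) - 1)
    ]

    choice = _search_stitching(frags, option_lists, coding)
    if choice is None:
        best = max(frags, key=lambda f: f.score)
        exons_c = [(best.c_start, best.c_end)]
        q_first, q_last = best.q_start, best.q_end
        flag = PARTIAL_FLAG
    else:
        exons_c = choice
        q_first, q_last = frags[0].q_start, frags[-1].q_end
        flag = CANONICAL_FLAG

    exons_c = _extend_outer(exons_c, coding, bait, q_first, q_last)
    cds = "".join(coding[s - 1 : e] for s, e in exons_c)
    peptide = _translate_frame0(cds).rstrip(STOP)
    introns_c = [
        (exons_c[i][1] + 1, exons_c[i + 1][0] - 1) for i in range(len(exons_c) - 1)
    ]

    def back(span: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return span
        return contig_len - span[1] + 1, contig_len - span[0] + 1

    exons = sorted(back(s) for s in exons_c)
    introns = sorted(back(s) for s in introns_c)
    return GeneModel(
        name=name,
        contig=locus.contig,
        strand=strand,
        exons=exons,
        introns=introns,
        cds=cds,
        peptide=peptide,
        flag=flag,
        source_bait=locus.query_id,
        score=locus.total_score,
    )


def _search_stitching(
    frags: list[_CFrag],
    option_lists: list[list[_JunctionOption]],
    coding: str,
    max_expansions: int = 2000,
) -> list[tuple[int, int]] | None:
    """Best-first search over junction options; validates the full CDS.

    Returns the exon coding spans, or ``None`` when no canonical,
    stop-free stitching exists.
    """
    if len(frags) == 1:
        return [(frags[0].c_start, frags[0].c_end)]
    if any(not opts for opts in option_lists):
        return None

    expansions = 0
    indices = [0] * len(option_lists)

    def build(indices: list[int]) -> list[tuple[int, int]]:
        exons = []
        start = frags[0].c_start
        for i, opt_i in enumerate(indices):
            opt = option_lists[i][opt_i]
            exons.append((start, opt.donor_end))
            start = opt.acceptor_start
        exons.append((start, frags[-1].c_end))
        return exons

    # iterate assignments in best-first (lexicographic over sorted options)
    for combo in itertools.product(*(range(len(o)) for o in option_lists)):
        expansions += 1
        if expansions > max_expansions:
            break
        exons = build(list(combo))
        if any(s > e for s, e in exons):
            continue
        cds = "".join(coding[s - 1 : e] for s, e in exons)
        pep = _translate_frame0(cds)
        if STOP not in pep[:-1] and pep[-1:] != STOP:
            return exons
    return None


def _extend_outer(
    exons_c: list[tuple[int, int]],
    coding: str,
    bait: Sequence | None,
    q_first: int,
    q_last: int,
) -> list[tuple[int, int]]:
    """Extend the outer exon edges to cover the bait's full query span."""
    if bait is None:
        return exons_c
    exons = list(exons_c)
    ext5 = 3 * (q_first - 1)
    ext3 = 3 * (len(bait) - q_last)
    s0, e0 = exons[0]
    new_start = max(s0 - ext5, s0 - 3 * ((s0 - 1) // 3))
    sl, el = exons[-1]
    new_end = min(el + ext3, el + 3 * ((len(coding) - el) // 3))
    # trim extensions back codon-wise if they introduce stop codons
    while new_start < s0:
        head = _translate_frame0(coding[new_start - 1 : e0])
        if STOP not in head[: (s0 - new_start) // 3]:
            break
        new_start += 3
    exons[0] = (new_start, e0)
    while new_end > el:
        n_tail = (new_end - el) // 3
        tail = _translate_frame0(coding[sl - 1 : new_end])
        if STOP not in tail[-n_tail:]:
            break
        new_end -= 3
    exons[-1] = (exons[-1][0], new_end) if len(exons) > 1 else (new_start, new_end)
    return exons


# ---------------------------------------------------------------------------
# GFF3 export / import


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/CDS features (1-based inclusive, phase computed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            attrs = f"ID={m.name};flag={m.flag};bait={m.source_bait}"
            out.write(
                f"{m.contig}\tpathscreen\tgene\t{lo}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            out.write(
                f"{m.contig}\tpathscreen\tmRNA\t{lo}\t{hi}\t.\t{m.strand}\t.\t"
                f"ID={m.name}.t1;Parent={m.name}\n"
            )
            exons = m.exons if m.strand == "+" else list(reversed(m.exons))
            phase = 0
            for s, e in exons:
                out.write(
                    f"{m.contig}\tpathscreen\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds.{m.name};Parent={m.name}.t1\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def read_gff3(path: str | Path) -> dict[str, dict]:
    """Read back models written by :func:`write_gff3` (coordinates only)."""
    models: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        contig, _, feature, start, end, _, strand, phase, attrs = cols
        info = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if feature == "gene":
            models[info["ID"]] = {
                "contig": contig,
                "strand": strand,
                "flag": info.get("flag", ""),
                "exons": [],
            }
        elif feature == "CDS":
            name = info["Parent"].rsplit(".t1", 1)[0]
            models[name]["exons"].append((int(start), int(end)))
    for m in models.values():
        m["exons"].sort()
    return models
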