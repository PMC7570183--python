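"""Candidate refinement and function assignment.

Filtered candidates are aligned globally together with the baits, the
alignment is cleaned of sparsely occupied columns, and each candidate is
assigned the reaction of its *closest* bait: by patristic distance on a
phylogenetic tree when one can be built (neighbor joining on p-distances
by default, or an external FastTree binary), otherwise by the highest
global-alignment identity.  When the k nearest baits span several
reactions, the alternatives are recorded as co-candidates — this is how
sequences that resemble two related enzyme families (e.g. flavonoid
3'-hydroxylases vs 3'5'-hydroxylases) are disambiguated by their overall
similarity to the whole bait sets rather than by a single best hit.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .knowledge_base import BaitSet
from .search import Scoring, _make_aligner, global_identity
from .seqkit import Sequence


@dataclass(frozen=True)
class Msa:
    """A multiple alignment: equal-length rows of (id, aligned string)."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        lengths = {len(aligned) for _, aligned in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, aligned in self.rows:
            if r == rid:
                return aligned
        raise KeyError(rid)

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


@dataclass(frozen=True)
class Assignment:
    candidate_id: str
    reaction: str
    closest_bait_id: str
    metric: str  # "tree_distance" or "alignment_similarity"
    value: float
    co_candidates: tuple[str, ...] = ()


def mafft_available(tool_path: str | None = None) -> bool:
    return shutil.which(tool_path or "mafft") is not None


def fasttree_available(tool_path: str | None = None) -> bool:
    return any(shutil.which(t) for t in ([tool_path] if tool_path else ["fasttree", "FastTree"]))


def build_msa(
    seqs: TSequence[Sequence],
    method: str = "auto",
    tool_path: str | None = None,
    scoring: Scoring = Scoring(),
) -> Msa:
    """Global multiple alignment of peptides.

    ``method='mafft'`` shells out to MAFFT (deterministic for a fixed
    input order); ``method='internal'`` uses a center-star progressive
    alignment anchored on the longest sequence; ``'auto'`` prefers MAFFT
    when the binary is available.  Row order always equals input order
    and degapping any row reproduces its input sequence exactly.
    """
    if len(seqs) < 2:
        raise ValueError("an alignment needs at least 2 sequences")
    if method == "auto":
        method = "mafft" if mafft_available(tool_path) else "internal"
    if method == "mafft":
        return _mafft_msa(seqs, tool_path or "mafft")
    if method == "internal":
        return _center_star_msa(seqs, scoring)
    raise ValueError(f"unknown msa method {method!r}")


def _mafft_msa(seqs: TSequence[Sequence], binary: str) -> Msa:
    if not mafft_available(binary):
        raise EnvironmentError(f"MSA binary {binary!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as out:
            for s in seqs:
                out.write(f">{s.id}\n{s.residues}\n")
        proc = subprocess.run(
            [binary, "--quiet", "--auto", "--amino", "--anysymbol", str(fasta)],
            check=True,
            capture_output=True,
            text=True,
        )
    rows: dict[str, str] = {}
    rid = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            rid = line[1:].split()[0]
            rows[rid] = ""
        elif rid is not None:
            rows[rid] += line.strip().upper()
    ordered = tuple((s.id, rows[s.id]) for s in seqs)
    return Msa(rows=ordered)


def _center_star_msa(seqs: TSequence[Sequence], scoring: Scoring) -> Msa:
    """Progressive center-star alignment (all sequences vs one anchor)."""
    center_idx = max(range(len(seqs)), key=lambda i: (len(seqs[i]), -i))
    center = seqs[center_idx]
    aligner = _make_aligner(scoring, "global")
    n_anchor = len(center)
    # insertions[i] = max inserted run before center residue i (i == n_anchor: after last)
    insertions = [0] * (n_anchor + 1)
    pairwise: list[tuple[list[str], str]] = []  # per-seq: per-slot inserted strings + matched chars
    for seq in seqs:
        if seq.id == center.id and seq.residues == center.residues:
            slots = [""] * (n_anchor + 1)
            matched = center.residues
        else:
            alignment = next(iter(aligner.align(center.residues, seq.residues)))
            a_center, a_seq = str(alignment[0]), str(alignment[1])
            slots = [""] * (n_anchor + 1)
            matched_chars = []
            ci = 0
            for col_c, col_s in zip(a_center, a_seq):
                if col_c == "-":
                    slots[ci] += col_s
                else:
                    matched_chars.append(col_s)
                    ci += 1
            matched = "".join(matched_chars)
        pairwise.append((slots, matched))
        for i, ins in enumerate(slots):
            insertions[i] = max(insertions[i], len(ins))
    rows = []
    for seq, (slots, matched) in zip(seqs, pairwise):
        parts = []
        for i in range(n_anchor):
            parts.append(slots[i].ljust(insertions[i], "-"))
            parts.append(matched[i])
        parts.append(slots[n_anchor].ljust(insertions[n_anchor], "-"))
        rows.append((seq.id, "".join(parts)))
    return Msa(rows=tuple(rows))


def occupancy_filter(msa: Msa, min_occupancy: float = 0.1) -> Msa:
    """Drop alignment columns whose non-gap fraction is below the cutoff.

    Columns with occupancy >= ``min_occupancy`` are retained in order;
    the default removes only very sparse columns (<0.1 occupied).
    """
    if not msa.rows:
        return msa
    arr = np.frombuffer(
        "".join(aligned for _, aligned in msa.rows).encode(), dtype="S1"
    ).reshape(len(msa.rows), msa.n_columns)
    occupancy = (arr != b"-").mean(axis=0)
    keep = occupancy >= min_occupancy
    rows = tuple(
        (rid, arr[i, keep].tobytes().decode()) for i, (rid, _) in enumerate(msa.rows)
    )
    return Msa(rows=rows)


# ---------------------------------------------------------------------------
# Trees


def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Pairwise p-distances over columns where both rows are ungapped."""
    ids = msa.ids
    arr = np.frombuffer(
        "".join(aligned for _, aligned in msa.rows).encode(), dtype="S1"
    ).reshape(len(ids), msa.n_columns)
    gap = arr == b"-"
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            total = int(shared.sum())
            if total == 0:
                d = 1.0
            else:
                d = float((arr[i, shared] != arr[j, shared]).sum()) / total
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(dist, ids)


def build_tree(
    msa: Msa, method: str = "nj", tool_path: str | None = None
) -> TreeNode:
    """Tree over the alignment rows; NJ on p-distances or FastTree."""
    if len(msa.rows) < 4:
        raise ValueError("tree construction needs at least 4 leaves")
    if method == "fasttree":
        return _fasttree(msa, tool_path)
    if method != "nj":
        raise ValueError(f"unknown tree method {method!r}")
    tree = nj(p_distance_matrix(msa))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0  # NJ can emit tiny negative branches
    return tree


def _fasttree(msa: Msa, tool_path: str | None) -> TreeNode:
    binary = tool_path or next(
        (t for t in ("fasttree", "FastTree") if shutil.which(t)), None
    )
    if binary is None or not shutil.which(binary):
        raise EnvironmentError("FastTree binary not found on PATH")
    fasta = "".join(f">{rid}\n{aligned}\n" for rid, aligned in msa.rows)
    proc = subprocess.run(
        [binary, "-quiet", "-nopr", "-wag"],
        input=fasta,
        capture_output=True,
        text=True,
        check=True,
    )
    return TreeNode.read([proc.stdout.strip()])


def patristic_distances(tree: TreeNode, from_id: str, to_ids: Iterable[str]) -> dict[str, float]:
    """Sum of branch lengths from one tip to each of the given tips."""
    tip = tree.find(from_id)
    return {other: float(tip.distance(tree.find(other))) for other in to_ids}


# ---------------------------------------------------------------------------
# Classification


def _bait_reactions(bait_sets: TSequence[BaitSet]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for bs in bait_sets:
        for bait in bs:
            if bait.id in mapping and mapping[bait.id] != bs.reaction:
                raise ValueError(f"bait id {bait.id!r} appears in several reactions")
            mapping[bait.id] = bs.reaction
    return mapping


def _rank_to_assignments(
    candidate_id: str,
    ranked: list[tuple[float, str]],
    reactions: dict[str, str],
    metric: str,
    k_nearest: int,
) -> Assignment:
    best_value, best_bait = ranked[0]
    best_reaction = reactions[best_bait]
    top_reactions = []
    for _, bait_id in ranked[:k_nearest]:
        r = reactions[bait_id]
        if r not in top_reactions:
            top_reactions.append(r)
    co = tuple(r for r in top_reactions if r != best_reaction)
    return Assignment(
        candidate_id=candidate_id,
        reaction=best_reaction,
        closest_bait_id=best_bait,
        metric=metric,
        value=best_value,
        co_candidates=co,
    )


def classify_by_similarity(
    candidates: TSequence[Sequence],
    bait_sets: TSequence[BaitSet],
    k_nearest: int = 3,
    scoring: Scoring = Scoring(),
) -> list[Assignment]:
    """Assign each candidate the reaction of its most similar bait.

    Similarity is percent identity in a pairwise global alignment; ties
    break on the raw alignment score, then lexicographic bait id.
    """
    reactions = _bait_reactions(bait_sets)
    baits = [bait for bs in bait_sets for bait in bs]
    assignments = []
    for cand in candidates:
        scored = []
        for bait in baits:
            identity, raw = global_identity(cand.residues, bait.residues, scoring)
            scored.append((-identity, -raw, bait.id))
        scored.sort()
        ranked = [(-neg_ident, bait_id) for neg_ident, _, bait_id in scored]
        assignments.append(
            _rank_to_assignments(cand.id, ranked, reactions, "alignment_similarity", k_nearest)
        )
    return assignments


def classify_by_tree(
    candidates: TSequence[Sequence],
    bait_sets: TSequence[BaitSet],
    k_nearest: int = 3,
    msa_method: str = "auto",
    tree_method: str = "nj",
    min_occupancy: float = 0.1,
    msa_tool_path: str | None = None,
    tree_tool_path: str | None = None,
    scoring: Scoring = Scoring(),
) -> tuple[list[Assignment], TreeNode | None]:
    """Assign each candidate the reaction of its nearest bait in a tree.

    Candidates and all baits are aligned together, sparse columns are
    removed, and nearest means minimum patristic distance (sum of branch
    lengths, invariant to rooting).  Falls back to
    :func:`classify_by_similarity` when fewer than four leaves are
    available or tree construction fails.
    """
    reactions = _bait_reactions(bait_sets)
    baits = [bait for bs in bait_sets for bait in bs]
    leaves = list(baits) + [c for c in candidates]
    if not candidates:
        return [], None
    if len(leaves) < 4:
        return classify_by_similarity(candidates, bait_sets, k_nearest, scoring), None
    try:
        msa = build_msa(leaves, method=msa_method, tool_path=msa_tool_path, scoring=scoring)
        msa = occupancy_filter(msa, min_occupancy)
        tree = build_tree(msa, method=tree_method, tool_path=tree_tool_path)
    except Exception:
        return classify_by_similarity(candidates, bait_sets, k_nearest, scoring), None
    bait_ids = [b.id for b in baits]
    assignments = []
    for cand in candidates:
        distances = patristic_distances(tree, cand.id, bait_ids)
        ranked = sorted(
            ((dist, bait_id) for bait_id, dist in distances.items()),
            key=lambda t: (t[0], t[1]),
        )
        assignments.append(
            _rank_to_assignments(cand.id, ranked, reactions, "tree_distance", k_nearest)
        )
    return assignments, tree


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as out:
        for rid, aligned in msa.rows:
            out.write(f">{rid}\n{aligned}\n")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(str(path))
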