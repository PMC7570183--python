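"""Residue and domain screening of candidates against the reference.

Functionally relevant positions are defined 1-based on the reference
peptide; the alignment maps them onto each candidate.  A candidate is
predicted *functional* only when every checked position matches an
allowed residue (optionally accepting biochemically similar residues)
and every checked domain is conserved; any violation downgrades the call
to *possibly non-functional* with the violated rule named.  A gapped
("absent") diagnostic position also blocks the functional call but is
reported distinctly from a mismatch.

Substrate-specificity rules only annotate — they never change the
functional/non-functional prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence as TSequence

from .classify import Msa, build_msa
from .knowledge_base import DomainRule, ReferenceSpec, ResidueRule
from .seqkit import Sequence

ABSENT = "absent"

# Coarse biochemical grouping used by the opt-in "similar residue" mode.
BIOCHEMICAL_GROUPS: dict[str, str] = {}
for _group, _members in {
    "aliphatic": "AGILPV",
    "aromatic": "FWY",
    "polar": "CNQST",
    "acidic": "DE",
    "basic": "HKR",
    "sulfur": "M",
}.items():
    for _aa in _members:
        BIOCHEMICAL_GROUPS[_aa] = _group


@dataclass(frozen=True)
class ResidueCheck:
    rule: ResidueRule
    candidate_position: int | str  # 1-based on the candidate, or "absent"
    observed: str  # residue character or '-'
    status: str  # match | similar | mismatch | absent


@dataclass(frozen=True)
class DomainCheck:
    rule: DomainRule
    identity: float
    conserved: bool


@dataclass
class FunctionalityCall:
    candidate_id: str
    reaction: str
    residue_checks: list[ResidueCheck]
    domain_checks: list[DomainCheck]
    prediction: str  # "functional" | "possibly_nonfunctional"
    notes: list[str] = field(default_factory=list)

    @property
    def violated(self) -> list[str]:
        out = [c.rule.label for c in self.residue_checks if c.status in ("mismatch", ABSENT)]
        out += [c.rule.name for c in self.domain_checks if not c.conserved]
        return out


def _column_of_position(msa: Msa, reference_id: str, position: int) -> int:
    """Alignment column index (0-based) of a 1-based reference position."""
    aligned = msa.row(reference_id)
    count = 0
    for col, char in enumerate(aligned):
        if char != "-":
            count += 1
            if count == position:
                return col
    raise ValueError(
        f"position {position} beyond the {count}-aa reference {reference_id!r}"
    )


def map_positions(
    msa: Msa, reference_id: str, candidate_id: str, positions: Iterable[int]
) -> list[tuple[int, int | str]]:
    """Map reference positions onto the candidate through the alignment.

    For each 1-based reference position, returns the candidate's 1-based
    residue index in the same alignment column, or ``"absent"`` when the
    candidate holds a gap there.
    """
    cand = msa.row(candidate_id)
    out: list[tuple[int, int | str]] = []
    # precompute candidate residue index per column
    cand_index = []
    count = 0
    for char in cand:
        if char != "-":
            count += 1
            cand_index.append(count)
        else:
            cand_index.append(0)
    for position in positions:
        col = _column_of_position(msa, reference_id, position)
        if cand[col] == "-":
            out.append((position, ABSENT))
        else:
            out.append((position, cand_index[col]))
    return out


def check_residues(
    msa: Msa,
    spec: ReferenceSpec,
    reference_id: str,
    candidate_id: str,
    similar_mode: bool = False,
) -> list[ResidueCheck]:
    """One check per residue rule: match / similar / mismatch / absent."""
    cand = msa.row(candidate_id)
    checks = []
    for rule in spec.residue_rules:
        col = _column_of_position(msa, reference_id, rule.position)
        observed = cand[col]
        if observed == "-":
            status: str = ABSENT
            cand_pos: int | str = ABSENT
        else:
            cand_pos = len(cand[: col + 1].replace("-", ""))
            if observed in rule.allowed:
                status = "match"
            elif similar_mode and any(
                BIOCHEMICAL_GROUPS.get(observed) == BIOCHEMICAL_GROUPS.get(a)
                and BIOCHEMICAL_GROUPS.get(observed) is not None
                for a in rule.allowed
            ):
                status = "similar"
            else:
                status = "mismatch"
        checks.append(ResidueCheck(rule, cand_pos, observed, status))
    return checks


def check_domains(
    msa: Msa, spec: ReferenceSpec, reference_id: str, candidate_id: str
) -> list[DomainCheck]:
    """Identity of the candidate over each domain's alignment columns.

    Identity is counted over the columns carrying the reference span
    (candidate gaps count as mismatches), so a candidate gapped across
    the whole span scores 0.
    """
    ref = msa.row(reference_id)
    cand = msa.row(candidate_id)
    checks = []
    for rule in spec.domain_rules:
        col_start = _column_of_position(msa, reference_id, rule.start)
        col_end = _column_of_position(msa, reference_id, rule.end)
        span = rule.end - rule.start + 1
        matches = sum(
            1
            for col in range(col_start, col_end + 1)
            if ref[col] != "-" and cand[col] == ref[col]
        )
        identity = matches / span
        checks.append(DomainCheck(rule, identity, identity >= rule.min_identity))
    return checks


def predict_functionality(
    candidate_id: str,
    reaction: str,
    residue_checks: list[ResidueCheck],
    domain_checks: list[DomainCheck],
    similar_mode: bool = False,
) -> FunctionalityCall:
    """Functional iff every residue rule and every domain check passes.

    With no rules configured the call is vacuously functional, flagged
    with a caveat note.
    """
    ok_status = {"match", "similar"} if similar_mode else {"match"}
    residues_ok = all(c.status in ok_status for c in residue_checks)
    domains_ok = all(c.conserved for c in domain_checks)
    prediction = "functional" if residues_ok and domains_ok else "possibly_nonfunctional"
    call = FunctionalityCall(
        candidate_id=candidate_id,
        reaction=reaction,
        residue_checks=residue_checks,
        domain_checks=domain_checks,
        prediction=prediction,
    )
    if not residue_checks and not domain_checks:
        call.notes.append("no residue or domain rules configured; functional by default")
    return call


def annotate_specificity(
    call: FunctionalityCall, spec: ReferenceSpec, msa: Msa, reference_id: str
) -> FunctionalityCall:
    """Append substrate-specificity notes; the prediction is untouched."""
    if not spec.specificity_rules:
        return call
    cand = msa.row(call.candidate_id)
    for rule in spec.specificity_rules:
        position = spec.specificity_position(rule)
        col = _column_of_position(msa, reference_id, position)
        observed = cand[col]
        if observed == rule.residue:
            call.notes.append(
                f"{rule.anchor} position {rule.position} is {observed}: {rule.annotation}"
            )
    return call


# ---------------------------------------------------------------------------
# Contrasting residues between two families


def contrasting_residues(
    set_a: TSequence[Sequence],
    set_b: TSequence[Sequence],
    purity: float = 0.9,
    reference_id: str | None = None,
    msa_method: str = "auto",
) -> list[tuple[int, str, str]]:
    """Alignment columns that discriminate two sequence families.

    Both sets are aligned jointly; a column is *contrasting* when its
    residues can be split into two disjoint sets such that at least
    ``purity`` of each family's ungapped rows carry a residue from its
    own side.  Residues are attributed to the family in which they are
    relatively more frequent.  Positions are reported 1-based on a
    designated reference from ``set_a`` (default: its first sequence);
    columns gapped in the reference cannot be expressed and are skipped.
    Returns ``(reference_position, residues_a, residues_b)`` sorted by
    position, residue strings sorted alphabetically.
    """
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    if reference_id is None:
        reference_id = set_a[0].id
    ref_index = next(i for i, s in enumerate(set_a) if s.id == reference_id)
    # the two sets may share ids (or be the same set); alias rows internally
    aliased = [
        Sequence(f"A{i}", s.residues, s.kind) for i, s in enumerate(set_a)
    ] + [Sequence(f"B{i}", s.residues, s.kind) for i, s in enumerate(set_b)]
    msa = build_msa(aliased, method=msa_method)
    rows_a = [aligned for rid, aligned in msa.rows if rid.startswith("A")]
    rows_b = [aligned for rid, aligned in msa.rows if rid.startswith("B")]
    ref = msa.row(f"A{ref_index}")
    out = []
    ref_pos = 0
    for col in range(msa.n_columns):
        if ref[col] != "-":
            ref_pos += 1
        else:
            continue
        col_a = [row[col] for row in rows_a if row[col] != "-"]
        col_b = [row[col] for row in rows_b if row[col] != "-"]
        if not col_a or not col_b:
            continue
        freq_a = {r: col_a.count(r) / len(col_a) for r in set(col_a)}
        freq_b = {r: col_b.count(r) / len(col_b) for r in set(col_b)}
        side_a, side_b = set(), set()
        for r in set(col_a) | set(col_b):
            if freq_a.get(r, 0.0) >= freq_b.get(r, 0.0):
                side_a.add(r)
            else:
                side_b.add(r)
        cover_a = sum(freq_a.get(r, 0.0) for r in side_a)
        cover_b = sum(freq_b.get(r, 0.0) for r in side_b)
        if cover_a >= purity and cover_b >= purity:
            res_a = "".join(sorted(r for r in side_a if r in freq_a))
            res_b = "".join(sorted(r for r in side_b if r in freq_b))
            out.append((ref_pos, res_a, res_b))
    return out
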