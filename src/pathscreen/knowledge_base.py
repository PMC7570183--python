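"""Loading and validation of the user-supplied pathway knowledge.

A screen is driven by per-reaction knowledge: a FASTA file of bait
peptides (previously characterised enzymes of one reaction) of which one
is the designated *reference*, plus a plain-text table of functionally
relevant residue positions and domain spans given 1-based on that
reference.  A top-level config file lists the reactions of the pathway.

Residue/domain table dialect (whitespace-separated, ``#`` comments)::

    166     Q       CHS-diagnostic-Q166
    313-329 malonyl-CoA-motif 0.6
    @anchor substrate-binding 131 26
    @spec   substrate-binding 3 N accepts dihydrokaempferol, ...

Plain rows with a single integer are residue rules (position, allowed
one-letter codes, label); ``start-end`` rows are domain rules with an
optional minimum identity (default 0.6).  ``@anchor`` names a sub-domain
by its start and length on the reference; ``@spec`` rows attach a
substrate-specificity annotation to a residue at a position *within* a
named anchor (or ``full`` for the whole reference), so knowledge stated
relative to a short functional domain stays well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .seqkit import AA_ALPHABET, Sequence, read_fasta, write_fasta


class ConfigurationError(ValueError):
    """Invalid or inconsistent knowledge files."""


@dataclass(frozen=True)
class BaitSet:
    """All baits of one reaction plus the designated reference."""

    reaction: str
    baits: tuple[Sequence, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.baits:
            raise ConfigurationError(f"reaction {self.reaction!r}: empty bait set")
        matches = [b for b in self.baits if b.id == self.reference_id]
        if len(matches) != 1:
            raise ConfigurationError(
                f"reaction {self.reaction!r}: reference id {self.reference_id!r} "
                f"matches {len(matches)} baits (need exactly 1)"
            )

    @property
    def reference(self) -> Sequence:
        return next(b for b in self.baits if b.id == self.reference_id)

    def __iter__(self):
        return iter(self.baits)


@dataclass(frozen=True)
class ResidueRule:
    position: int  # 1-based on the reference peptide
    allowed: frozenset[str]
    label: str

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ConfigurationError(f"rule {self.label!r}: empty allowed set")
        bad = set(self.allowed) - AA_ALPHABET
        if bad:
            raise ConfigurationError(
                f"rule {self.label!r}: unknown amino-acid codes {sorted(bad)}"
            )


@dataclass(frozen=True)
class DomainRule:
    start: int  # 1-based inclusive on the reference
    end: int
    name: str
    min_identity: float = 0.6

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ConfigurationError(f"domain {self.name!r}: bad span {self.start}-{self.end}")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ConfigurationError(f"domain {self.name!r}: min_identity outside [0,1]")


@dataclass(frozen=True)
class Anchor:
    """A named sub-domain of the reference (start, length; 1-based)."""

    name: str
    start: int
    length: int


@dataclass(frozen=True)
class SpecificityRule:
    """Maps a residue at an anchored position to a substrate annotation."""

    anchor: str
    position: int  # 1-based within the anchor (or on the reference for "full")
    residue: str
    annotation: str


@dataclass
class ReferenceSpec:
    reaction: str
    residue_rules: list[ResidueRule] = field(default_factory=list)
    domain_rules: list[DomainRule] = field(default_factory=list)
    anchors: dict[str, Anchor] = field(default_factory=dict)
    specificity_rules: list[SpecificityRule] = field(default_factory=list)

    def specificity_position(self, rule: SpecificityRule) -> int:
        """Reference position (1-based) a specificity rule refers to."""
        if rule.anchor == "full":
            return rule.position
        anchor = self.anchors[rule.anchor]
        return anchor.start + rule.position - 1


def load_bait_set(fasta_path: str | Path, reference_id: str, reaction: str | None = None) -> BaitSet:
    """Load one reaction's baits; the reference must be among them."""
    fasta_path = Path(fasta_path)
    baits = read_fasta(fasta_path, kind="peptide")
    if reaction is None:
        reaction = fasta_path.stem.split(".")[0]
    if not any(b.id == reference_id for b in baits):
        raise ConfigurationError(
            f"reference id {reference_id!r} not found among the "
            f"{len(baits)} records of {fasta_path}"
        )
    return BaitSet(reaction=reaction, baits=tuple(baits), reference_id=reference_id)


def save_bait_set(bait_set: BaitSet, path: str | Path) -> None:
    write_fasta(bait_set.baits, path)


def load_reference_spec(table_path: str | Path, bait_set: BaitSet) -> ReferenceSpec:
    """Parse a residue/domain table and validate it against the reference."""
    table_path = Path(table_path)
    if not table_path.exists():
        raise FileNotFoundError(table_path)
    ref_len = len(bait_set.reference)
    spec = ReferenceSpec(reaction=bait_set.reaction)
    with open(table_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            where = f"{table_path}:{lineno}"
            tokens = line.split()
            if tokens[0] == "@anchor":
                name, start, length = tokens[1], int(tokens[2]), int(tokens[3])
                if not 1 <= start <= start + length - 1 <= ref_len:
                    raise ConfigurationError(f"{where}: anchor {name!r} outside reference")
                spec.anchors[name] = Anchor(name, start, length)
            elif tokens[0] == "@spec":
                anchor, pos, residue = tokens[1], int(tokens[2]), tokens[3].upper()
                annotation = " ".join(tokens[4:])
                if residue not in AA_ALPHABET:
                    raise ConfigurationError(f"{where}: unknown residue {residue!r}")
                rule = SpecificityRule(anchor, pos, residue, annotation)
                spec.specificity_rules.append(rule)
            elif "-" in tokens[0]:
                start_s, end_s = tokens[0].split("-", 1)
                name = tokens[1] if len(tokens) > 1 else f"domain-{tokens[0]}"
                min_identity = float(tokens[2]) if len(tokens) > 2 else 0.6
                rule = DomainRule(int(start_s), int(end_s), name, min_identity)
                if rule.end > ref_len:
                    raise ConfigurationError(
                        f"{where}: domain span {tokens[0]} exceeds the "
                        f"{ref_len}-aa reference {bait_set.reference_id!r}"
                    )
                spec.domain_rules.append(rule)
            else:
                position = int(tokens[0])
                if len(tokens) < 2:
                    raise ConfigurationError(f"{where}: residue row needs an allowed set")
                allowed = frozenset(tokens[1].upper())
                label = " ".join(tokens[2:]) if len(tokens) > 2 else f"pos-{position}"
                if not 1 <= position <= ref_len:
                    raise ConfigurationError(
                        f"{where}: position {position} outside the "
                        f"{ref_len}-aa reference {bait_set.reference_id!r}"
                    )
                spec.residue_rules.append(ResidueRule(position, allowed, label))
    # validate anchored specificity positions now that anchors are known
    for rule in spec.specificity_rules:
        if rule.anchor != "full" and rule.anchor not in spec.anchors:
            raise ConfigurationError(
                f"{table_path}: @spec refers to unknown anchor {rule.anchor!r}"
            )
        pos = spec.specificity_position(rule)
        if not 1 <= pos <= ref_len:
            raise ConfigurationError(
                f"{table_path}: specificity position {pos} outside the reference"
            )
    spec.residue_rules.sort(key=lambda r: r.position)
    spec.domain_rules.sort(key=lambda r: (r.start, r.end))
    return spec


@dataclass(frozen=True)
class Reaction:
    """One pathway step: bait set plus its residue/domain knowledge."""

    bait_set: BaitSet
    spec: ReferenceSpec

    @property
    def name(self) -> str:
        return self.bait_set.reaction


def load_pathway(config_path: str | Path) -> list[Reaction]:
    """Load a whole pathway from a tab-separated config file.

    Each non-comment line: ``reaction<TAB>bait_fasta<TAB>reference_id[<TAB>table]``,
    paths relative to the config file.  The table column may be empty for
    reactions without residue knowledge.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(config_path)
    base = config_path.parent
    reactions: list[Reaction] = []
    seen: set[str] = set()
    with open(config_path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ConfigurationError(
                    f"{config_path}:{lineno}: need reaction, bait file, reference id"
                )
            name, fasta, reference_id = cols[0], cols[1], cols[2]
            if name in seen:
                raise ConfigurationError(f"{config_path}:{lineno}: duplicate reaction {name!r}")
            seen.add(name)
            bait_set = load_bait_set(base / fasta, reference_id, reaction=name)
            if len(cols) > 3 and cols[3].strip():
                spec = load_reference_spec(base / cols[3].strip(), bait_set)
            else:
                spec = ReferenceSpec(reaction=name)
            reactions.append(Reaction(bait_set=bait_set, spec=spec))
    if not reactions:
        raise ConfigurationError(f"{config_path}: no reactions configured")
    return reactions
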