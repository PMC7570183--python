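"""End-to-end orchestration of the three screening modes.

``pep`` screens supplied peptides directly; ``rna`` first translates
transcripts in all six frames into stop-free peptide fragments; ``dna``
chains translated genome hits into loci, stitches one isoform per locus
across canonical GT-AG introns, and feeds the stitched peptides back
into the peptide path.  All three modes therefore converge on the same
peptide-level analysis: two-threshold similarity filtering, global
alignment with the baits, closest-bait classification, and the residue/
domain screen with a functionality prediction per candidate.

Every intermediate result is persisted into the output directory (per
reaction: candidate FASTA, alignment, tree, residue and domain reports;
globally: a summary table and a stage log with in/out counts), so each
step of a run can be inspected after the fact.  Given identical inputs,
configuration and seed, a run is byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import genemodel as _genemodel
from . import residues as _residues
from .knowledge_base import Reaction, load_pathway
from .search import Scoring, filter_hits, search_candidates
from .seqkit import Sequence, read_fasta, write_fasta


@dataclass
class RunConfig:
    mode: str  # pep | rna | dna
    subject: str
    baits: str  # pathway config file (reaction -> bait fasta, reference, table)
    out: str
    min_identity: float = 0.40
    min_score_ratio: float = 0.30
    min_occupancy: float = 0.1
    min_fragment_len: int = 50
    dna_fragment_len: int = 10  # stop-free run length floor in genome mode
    max_intron_len: int = 20000
    search_window: int = 30
    purity: float = 0.9
    k_nearest: int = 3
    similar_mode: bool = False
    use_tree: bool = True
    msa_method: str = "auto"
    tree_method: str = "nj"
    search_tool_path: str | None = None
    msa_tool_path: str | None = None
    tree_tool_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("pep", "rna", "dna"):
            raise ValueError(f"mode must be pep, rna or dna, not {self.mode!r}")
        for name in ("min_identity", "min_score_ratio", "min_occupancy", "purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for path in (self.subject, self.baits):
            if not Path(path).exists():
                raise FileNotFoundError(path)


@dataclass
class Candidate:
    """A subject sequence that survived filtering for >=1 reaction."""

    seq: Sequence
    reactions: list[str]  # reactions whose filter it passed, config order
    best_hits: dict[str, float]  # reaction -> best score ratio
    model: _genemodel.GeneModel | None = None  # dna mode only


@dataclass
class RunResult:
    out_dir: Path
    candidates: list[Candidate]
    assignments: list
    calls: list
    summary: pd.DataFrame
    models: list = field(default_factory=list)
    log: list = field(default_factory=list)


def _log(log: list, stage: str, reaction: str, n_in: int, n_out: int, note: str = "") -> None:
    log.append({"stage": stage, "reaction": reaction, "in": n_in, "out": n_out, "note": note})


def _collect_pep_candidates(
    reactions: list[Reaction],
    subjects: list[Sequence],
    subject_lookup: dict[str, Sequence],
    cfg: RunConfig,
    scoring: Scoring,
    log: list,
    mode: str,
) -> dict[str, Candidate]:
    """Run the peptide (or translated-fragment) search and filter."""
    candidates: dict[str, Candidate] = {}
    for reaction in reactions:
        try:
            hits = search_candidates(
                reaction.bait_set,
                subjects,
                mode=mode,
                scoring=scoring,
                min_fragment_len=cfg.min_fragment_len,
            )
        except Exception as exc:  # a broken reaction must not sink the run
            _log(log, "search+filter", reaction.name, 0, 0, f"error: {exc}")
            continue
        kept = filter_hits(hits, cfg.min_identity, cfg.min_score_ratio)
        _log(log, "search+filter", reaction.name, len(hits), len(kept))
        for hit in kept:
            if mode == "rna":
                frag = hit.fragment
                seq = Sequence(frag.id, frag.residues, "peptide")
            else:
                seq = subject_lookup[hit.subject_id]
            cand = candidates.setdefault(
                seq.id, Candidate(seq=seq, reactions=[], best_hits={})
            )
            ratio = hit.score / hit.query_self_score
            if reaction.name not in cand.reactions:
                cand.reactions.append(reaction.name)
            cand.best_hits[reaction.name] = max(
                cand.best_hits.get(reaction.name, 0.0), ratio
            )
    return candidates


def _dna_candidates(
    reactions: list[Reaction],
    genome_seqs: list[Sequence],
    cfg: RunConfig,
    scoring: Scoring,
    log: list,
) -> tuple[dict[str, Candidate], list[_genemodel.GeneModel]]:
    """Genome mode: raw translated hits -> loci -> stitched isoforms.

    The score-ratio filter is applied to the assembled isoform peptide
    (re-searched against the baits), not to raw exon fragments, which
    would almost always fail it individually.
    """
    genome_lookup = {g.id: g for g in genome_seqs}
    all_models: list[_genemodel.GeneModel] = []
    stitched: dict[str, Sequence] = {}
    model_by_pepid: dict[str, _genemodel.GeneModel] = {}
    for reaction in reactions:
        raw = search_candidates(
            reaction.bait_set,
            genome_seqs,
            mode="dna",
            scoring=scoring,
            min_fragment_len=cfg.dna_fragment_len,
            min_raw_score=30.0,
        )
        # lenient identity-only prefilter on raw exon fragments
        exonic = [h for h in raw if h.identity > cfg.min_identity]
        baits = {b.id: b for b in reaction.bait_set}
        loci = _genemodel.group_hits(exonic, cfg.max_intron_len, baits=baits)
        _log(log, "group-hits", reaction.name, len(exonic), len(loci))
        for locus in loci:
            genome = genome_lookup[locus.contig]
            model = _genemodel.stitch_isoform(
                locus, genome, cfg.search_window, scoring,
                name=f"{reaction.name}_{locus.contig}_{locus.strand}"
                f"_{locus.g_span[0]}_{locus.g_span[1]}",
            )
            if not model.peptide:
                continue
            all_models.append(model)
            pep_id = model.name
            stitched[pep_id] = Sequence(pep_id, model.peptide, "peptide")
            model_by_pepid[pep_id] = model
        _log(log, "stitch", reaction.name, len(loci), len(all_models))

    # de-duplicate models covering the same genomic region: different
    # reactions' baits (or spurious short hits inside a real gene) can
    # describe one locus; the best-supported model represents it
    kept: list[_genemodel.GeneModel] = []
    for pep_id, seq in sorted(
        stitched.items(), key=lambda kv: (-model_by_pepid[kv[0]].score, kv[0])
    ):
        m = model_by_pepid[pep_id]
        lo = min(s for s, _ in m.exons)
        hi = max(e for _, e in m.exons)
        overlaps = False
        for other in kept:
            if other.contig == m.contig and other.strand == m.strand:
                olo = min(s for s, _ in other.exons)
                ohi = max(e for _, e in other.exons)
                if lo <= ohi and olo <= hi:
                    overlaps = True
                    break
        if not overlaps:
            kept.append(m)
    all_models = [m for m in all_models if m in kept]
    peptides = sorted((stitched[m.name] for m in kept), key=lambda s: s.id)
    lookup = {p.id: p for p in peptides}
    candidates = _collect_pep_candidates(
        [r for r in reactions], peptides, lookup, cfg, scoring, log, mode="pep"
    )
    for cand in candidates.values():
        cand.model = model_by_pepid.get(cand.seq.id)
    return candidates, all_models


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute one screen; returns the result and writes all outputs."""
    config.validate()
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    scoring = Scoring()
    log: list = []

    # echo the configuration verbatim
    with open(out_dir / "config.txt", "w") as handle:
        for key, value in sorted(asdict(config).items()):
            handle.write(f"{key}={value}\n")

    reactions = load_pathway(config.baits)
    subject_kind = "peptide" if config.mode == "pep" else "dna"
    subjects = read_fasta(config.subject, kind=subject_kind)
    subject_lookup = {s.id: s for s in subjects}
    _log(log, "load", "*", len(reactions), len(subjects), "reactions in / subjects out")

    models: list[_genemodel.GeneModel] = []
    if config.mode == "dna":
        candidates, models = _dna_candidates(reactions, subjects, config, scoring, log)
    else:
        candidates = _collect_pep_candidates(
            reactions, subjects, subject_lookup, config, scoring, log, config.mode
        )
    ordered = [candidates[k] for k in sorted(candidates)]
    _log(log, "candidates", "*", len(subjects), len(ordered))

    # classification: group candidates by the set of reactions they hit,
    # classify each group against the union of those reactions' baits
    reaction_by_name = {r.name: r for r in reactions}
    assignments: dict[str, _classify.Assignment] = {}
    groups: dict[tuple, list[Candidate]] = {}
    for cand in ordered:
        groups.setdefault(tuple(sorted(cand.reactions)), []).append(cand)
    for group_reactions, members in sorted(groups.items()):
        bait_sets = [reaction_by_name[r].bait_set for r in group_reactions]
        seqs = [c.seq for c in members]
        if config.use_tree:
            group_assign, _tree = _classify.classify_by_tree(
                seqs,
                bait_sets,
                k_nearest=config.k_nearest,
                msa_method=config.msa_method,
                tree_method=config.tree_method,
                min_occupancy=config.min_occupancy,
                msa_tool_path=config.msa_tool_path,
                tree_tool_path=config.tree_tool_path,
                scoring=scoring,
            )
        else:
            group_assign = _classify.classify_by_similarity(
                seqs, bait_sets, config.k_nearest, scoring
            )
        for a in group_assign:
            assignments[a.candidate_id] = a
    _log(log, "classify", "*", len(ordered), len(assignments))

    # per-reaction refinement, residue/domain screen, reports
    calls: list[_residues.FunctionalityCall] = []
    call_order: dict[str, int] = {}
    for reaction in reactions:
        try:
            _screen_reaction(
                reaction, ordered, assignments, calls, call_order, out_dir, config, scoring, log
            )
        except Exception as exc:
            _log(log, "screen", reaction.name, 0, 0, f"error: {exc}")

    if config.mode == "dna":
        _genemodel.write_gff3(models, out_dir / "models.gff3")
        write_fasta(
            [Sequence(m.name, m.cds, "dna") for m in models if m.cds],
            out_dir / "cds.fasta",
        )

    summary = summarize(calls, [assignments[c.candidate_id] for c in calls])
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(log, columns=["stage", "reaction", "in", "out", "note"]).to_csv(
        out_dir / "log.tsv", sep="\t", index=False
    )
    return RunResult(
        out_dir=out_dir,
        candidates=ordered,
        assignments=[assignments[c.seq.id] for c in ordered],
        calls=calls,
        summary=summary,
        models=models,
        log=log,
    )


def _screen_reaction(
    reaction: Reaction,
    ordered: list[Candidate],
    assignments: dict,
    calls: list,
    call_order: dict[str, int],
    out_dir: Path,
    config: RunConfig,
    scoring: Scoring,
    log: list,
) -> None:
    """Residue/domain screen and per-reaction outputs for one reaction."""
    r_dir = out_dir / reaction.name
    assigned = [c for c in ordered if assignments[c.seq.id].reaction == reaction.name]
    if not assigned:
        _log(log, "screen", reaction.name, 0, 0)
        return
    r_dir.mkdir(exist_ok=True)
    cand_seqs = [c.seq for c in assigned]
    write_fasta(cand_seqs, r_dir / "candidates.fasta")
    msa = _classify.build_msa(
        list(reaction.bait_set) + cand_seqs,
        method=config.msa_method,
        tool_path=config.msa_tool_path,
        scoring=scoring,
    )
    _classify.write_msa_fasta(msa, r_dir / "alignment.fasta")
    if config.use_tree and len(msa.rows) >= 4:
        try:
            tree = _classify.build_tree(
                _classify.occupancy_filter(msa, config.min_occupancy),
                method=config.tree_method,
                tool_path=config.tree_tool_path,
            )
            _classify.write_newick(tree, r_dir / "tree.nwk")
        except Exception:
            pass
    ref_id = reaction.bait_set.reference_id
    residue_rows, domain_rows = [], []
    for cand in assigned:
        residue_checks = _residues.check_residues(
            msa, reaction.spec, ref_id, cand.seq.id, config.similar_mode
        )
        domain_checks = _residues.check_domains(msa, reaction.spec, ref_id, cand.seq.id)
        call = _residues.predict_functionality(
            cand.seq.id, reaction.name, residue_checks, domain_checks,
            config.similar_mode,
        )
        call = _residues.annotate_specificity(call, reaction.spec, msa, ref_id)
        calls.append(call)
        call_order[cand.seq.id] = len(calls)
        for rc in residue_checks:
            residue_rows.append(
                {
                    "reaction": reaction.name,
                    "candidate": cand.seq.id,
                    "rule": rc.rule.label,
                    "reference_pos": rc.rule.position,
                    "candidate_pos": rc.candidate_position,
                    "observed": rc.observed,
                    "status": rc.status,
                }
            )
        for dc in domain_checks:
            domain_rows.append(
                {
                    "reaction": reaction.name,
                    "candidate": cand.seq.id,
                    "domain": dc.rule.name,
                    "span": f"{dc.rule.start}-{dc.rule.end}",
                    "identity": round(dc.identity, 4),
                    "conserved": dc.conserved,
                }
            )
    pd.DataFrame(
        residue_rows,
        columns=["reaction", "candidate", "rule", "reference_pos",
                 "candidate_pos", "observed", "status"],
    ).to_csv(r_dir / "residue_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        domain_rows,
        columns=["reaction", "candidate", "domain", "span", "identity", "conserved"],
    ).to_csv(r_dir / "domain_report.tsv", sep="\t", index=False)
    n_func = sum(
        1 for c in calls
        if c.reaction == reaction.name and c.prediction == "functional"
    )
    _log(log, "screen", reaction.name, len(assigned), n_func, "functional candidates out")


def summarize(calls: list, assignments: list) -> pd.DataFrame:
    """One row per candidate, sorted by reaction then descending value."""
    rows = []
    for call, assignment in zip(calls, assignments):
        n_rules = len(call.residue_checks) + len(call.domain_checks)
        n_matched = sum(
            1 for c in call.residue_checks if c.status in ("match", "similar")
        ) + sum(1 for c in call.domain_checks if c.conserved)
        rows.append(
            {
                "reaction": call.reaction,
                "candidate": call.candidate_id,
                "closest_bait": assignment.closest_bait_id,
                "metric": assignment.metric,
                "value": round(assignment.value, 6),
                "co_candidates": ",".join(assignment.co_candidates),
                "n_rules": n_rules,
                "n_matched": n_matched,
                "prediction": call.prediction,
                "notes": "; ".join(call.notes),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["reaction", "candidate", "closest_bait", "metric", "value",
                 "co_candidates", "n_rules", "n_matched", "prediction", "notes"],
    )
    if len(frame):
        ascending = [True, False, True]
        frame = frame.sort_values(
            ["reaction", "value", "candidate"], ascending=ascending, kind="mergesort"
        ).reset_index(drop=True)
    return frame
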