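"""Residue mapping, residue/domain checks, functionality prediction,
contrasting-residue discovery and substrate-specificity annotation."""

import numpy as np
import pytest

from pathscreen.classify import Msa
from pathscreen.data import load_flavonoid_pathway
from pathscreen.fixtures import make_family, _mutate
from pathscreen.knowledge_base import (
    Anchor,
    DomainRule,
    ReferenceSpec,
    ResidueRule,
    SpecificityRule,
)
from pathscreen.residues import (
    ABSENT,
    annotate_specificity,
    check_domains,
    check_residues,
    contrasting_residues,
    map_positions,
    predict_functionality,
)
from pathscreen.seqkit import Sequence


def _msa(*rows):
    return Msa(rows=tuple(rows))


class TestMapPositions:
    def test_gap_free_alignment_is_identity_mapping(self):
        msa = _msa(("ref", "MKVLE"), ("cand", "MKWLE"))
        assert map_positions(msa, "ref", "cand", [1, 3, 5]) == [(1, 1), (3, 3), (5, 5)]

    def test_insertion_shifts_candidate_position(self):
        # candidate has a 2-residue insertion before the reference's 3rd
        msa = _msa(("ref", "MK--VLE"), ("cand", "MKAAVLE"))
        assert map_positions(msa, "ref", "cand", [3]) == [(3, 5)]

    def test_gapped_column_reports_absent(self):
        msa = _msa(("ref", "MKVLE"), ("cand", "MK-LE"))
        assert map_positions(msa, "ref", "cand", [3]) == [(3, ABSENT)]

    def test_position_beyond_reference_raises(self):
        msa = _msa(("ref", "MKV"), ("cand", "MKV"))
        with pytest.raises(ValueError):
            map_positions(msa, "ref", "cand", [9])

    def test_matches_column_walk_oracle_on_random_gapped_alignments(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(5, 40))
            ref = "".join(rng.choice(list("ACDEF-"), n))
            cand = "".join(rng.choice(list("ACDEF-"), n))
            if ref.replace("-", "") == "" or cand.replace("-", "") == "":
                continue
            msa = _msa(("ref", ref), ("cand", cand))
            ref_len = len(ref.replace("-", ""))
            pos = int(rng.integers(1, ref_len + 1))
            # oracle: walk columns counting ungapped residues on each row
            seen_ref = seen_cand = 0
            expected = None
            for r_char, c_char in zip(ref, cand):
                if c_char != "-":
                    seen_cand += 1
                if r_char != "-":
                    seen_ref += 1
                    if seen_ref == pos:
                        expected = seen_cand if c_char != "-" else ABSENT
                        break
            assert map_positions(msa, "ref", "cand", [pos]) == [(pos, expected)]


class TestCheckResidues:
    spec = ReferenceSpec(
        reaction="CHS",
        residue_rules=[
            ResidueRule(2, frozenset("Q"), "diag-Q2"),
            ResidueRule(3, frozenset("R"), "diag-R3"),
        ],
    )

    def test_matching_candidate(self):
        msa = _msa(("ref", "MQRLE"), ("cand", "MQRIE"))
        checks = check_residues(msa, self.spec, "ref", "cand")
        assert [c.status for c in checks] == ["match", "match"]

    def test_mismatch_is_reported_with_observed_residue(self):
        msa = _msa(("ref", "MQRLE"), ("cand", "MHRIE"))
        checks = check_residues(msa, self.spec, "ref", "cand")
        assert checks[0].status == "mismatch" and checks[0].observed == "H"

    def test_similar_mode_accepts_same_biochemical_group(self):
        spec = ReferenceSpec("X", residue_rules=[ResidueRule(2, frozenset("R"), "basic")])
        msa = _msa(("ref", "MRV"), ("cand", "MKV"))
        strict = check_residues(msa, spec, "ref", "cand", similar_mode=False)
        relaxed = check_residues(msa, spec, "ref", "cand", similar_mode=True)
        assert strict[0].status == "mismatch"
        assert relaxed[0].status == "similar"

    def test_gapped_diagnostic_position_is_absent(self):
        msa = _msa(("ref", "MQRLE"), ("cand", "M-RIE"))
        checks = check_residues(msa, self.spec, "ref", "cand")
        assert checks[0].status == ABSENT


class TestCheckDomains:
    def test_identical_span_is_conserved(self):
        spec = ReferenceSpec("X", domain_rules=[DomainRule(2, 4, "motif", 0.6)])
        msa = _msa(("ref", "MQRLE"), ("cand", "AQRLA"))
        (check,) = check_domains(msa, spec, "ref", "cand")
        assert check.identity == 1.0 and check.conserved

    def test_fully_gapped_span_scores_zero(self):
        spec = ReferenceSpec("X", domain_rules=[DomainRule(2, 4, "motif", 0.6)])
        msa = _msa(("ref", "MQRLE"), ("cand", "M---E"))
        (check,) = check_domains(msa, spec, "ref", "cand")
        assert check.identity == 0.0 and not check.conserved

    def test_matches_hand_computed_column_identity(self):
        rng = np.random.default_rng(9)
        ref_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
        cand_seq = _mutate(rng, ref_seq, 0.3, set())
        spec = ReferenceSpec("X", domain_rules=[DomainRule(11, 30, "motif", 0.6)])
        msa = _msa(("ref", ref_seq), ("cand", cand_seq))
        (check,) = check_domains(msa, spec, "ref", "cand")
        expected = sum(a == b for a, b in zip(ref_seq[10:30], cand_seq[10:30])) / 20
        assert check.identity == pytest.approx(expected, abs=1e-9)


class TestPredictFunctionality:
    def _checks(self, statuses):
        return [
            type("C", (), {"status": s, "rule": ResidueRule(i + 1, frozenset("Q"), f"r{i}")})()
            for i, s in enumerate(statuses)
        ]

    def test_all_match_is_functional(self):
        call = predict_functionality("c", "CHS", self._checks(["match", "match"]), [])
        assert call.prediction == "functional"

    def test_single_mismatch_names_the_rule(self):
        call = predict_functionality("c", "CHS", self._checks(["match", "mismatch"]), [])
        assert call.prediction == "possibly_nonfunctional"
        assert "r1" in call.violated

    def test_no_rules_is_vacuously_functional_with_caveat(self):
        call = predict_functionality("c", "CHS", [], [])
        assert call.prediction == "functional"
        assert call.notes

    def test_monotone_adding_rules_never_creates_functional(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            n = int(rng.integers(0, 6))
            statuses = list(rng.choice(["match", "mismatch"], n))
            base = predict_functionality("c", "X", self._checks(statuses), [])
            extended = predict_functionality(
                "c", "X", self._checks(statuses + [str(rng.choice(["match", "mismatch"]))]), []
            )
            if base.prediction == "possibly_nonfunctional":
                assert extended.prediction == "possibly_nonfunctional"


class TestContrastingResidues:
    def _families(self, seed, n=8, length=120, divergence=0.05):
        _, anc_truth = make_family(2, length, 0.0, [], seed=seed, family="ANC")
        anc = anc_truth.families["ANC"]["ancestor"]
        fam_a, _ = make_family(
            n, length, divergence, [(40, "Q"), (41, "Q")], seed=seed + 1, family="A", ancestor=anc
        )
        fam_b, _ = make_family(
            n, length, divergence, [(40, "H"), (41, "Q")], seed=seed + 2, family="B", ancestor=anc
        )
        return fam_a, fam_b

    def test_planted_contrasting_column_recovered(self):
        fam_a, fam_b = self._families(seed=31)
        out = contrasting_residues(fam_a, fam_b, purity=0.9, msa_method="internal")
        assert (40, "Q", "H") in out
        assert all(pos != 41 for pos, *_ in out)  # shared Q is not contrasting

    def test_identical_sets_give_empty_result(self):
        fam_a, _ = self._families(seed=37)
        assert contrasting_residues(fam_a, fam_a, purity=0.9, msa_method="internal") == []

    def test_purity_threshold_controls_noise_tolerance(self):
        fam_a, fam_b = self._families(seed=41)
        # one noisy member of A carries the B-state at the planted column
        noisy = list(fam_a)
        noisy[0] = Sequence(noisy[0].id, noisy[0].residues[:39] + "H" + noisy[0].residues[40:], "peptide")
        strict = contrasting_residues(noisy, fam_b, purity=1.0, msa_method="internal")
        relaxed = contrasting_residues(noisy, fam_b, purity=0.85, msa_method="internal")
        assert all(pos != 40 for pos, *_ in strict)
        assert any(pos == 40 for pos, *_ in relaxed)

    def test_shipped_chalcone_vs_stilbene_baits_contrast_at_diagnostic(self):
        """The shipped bait families disagree exactly at the residue the
        knowledge table marks as diagnostic (position asserted through
        the designated reference, not hard-coded)."""
        reactions = {r.name: r for r in load_flavonoid_pathway()}
        chs, sts = reactions["CHS"].bait_set, reactions["STS"].bait_set
        out = contrasting_residues(
            list(chs), list(sts), purity=0.9, reference_id=chs.reference_id
        )
        diagnostic_positions = {r.position for r in reactions["CHS"].spec.residue_rules}
        assert diagnostic_positions & {pos for pos, *_ in out}


class TestSpecificityAnnotation:
    def _spec(self):
        return ReferenceSpec(
            reaction="DFR",
            anchors={"sub": Anchor("sub", 3, 5)},
            specificity_rules=[
                SpecificityRule("sub", 3, "N", "accepts all three dihydroflavonols"),
                SpecificityRule("sub", 3, "D", "reduced dihydrokaempferol acceptance"),
            ],
        )

    @pytest.mark.parametrize(
        "residue,expected",
        [("N", "accepts all three"), ("D", "reduced dihydrokaempferol")],
    )
    def test_notes_follow_observed_residue(self, residue, expected):
        spec = self._spec()
        ref = "MAKQNLE"
        cand = ref[:4] + residue + ref[5:]  # anchored position 3 -> reference 5
        msa = _msa(("ref", ref), ("cand", cand))
        call = predict_functionality("cand", "DFR", [], [])
        call = annotate_specificity(call, spec, msa, "ref")
        assert any(expected in note for note in call.notes)

    def test_annotation_never_changes_the_prediction(self):
        spec = self._spec()
        msa = _msa(("ref", "MAKQNLE"), ("cand", "MAKQDLE"))
        call = predict_functionality("cand", "DFR", [], [])
        before = call.prediction
        assert annotate_specificity(call, spec, msa, "ref").prediction == before
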