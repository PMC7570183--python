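"""Shared fixtures: one synthetic pathway screen reused across tests.

The pathway fixture and the three pipeline runs are expensive, so they
are generated once per session; individual tests only read them.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathscreen.fixtures import make_family, make_pathway_fixture, _mutate
from pathscreen.knowledge_base import BaitSet
from pathscreen.pipeline import RunConfig, run_pipeline
from pathscreen.seqkit import Sequence

SEED = 1


@pytest.fixture(scope="session")
def pathway_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("pathway")
    return make_pathway_fixture(root, seed=SEED)


def _run(fixture, mode: str, subject: str, out) -> object:
    config = RunConfig(
        mode=mode,
        subject=str(fixture.root / subject),
        baits=str(fixture.config),
        out=str(out),
        seed=SEED,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def pep_run(pathway_fixture, tmp_path_factory):
    return _run(pathway_fixture, "pep", "subjects_pep.fasta", tmp_path_factory.mktemp("pep"))


@pytest.fixture(scope="session")
def rna_run(pathway_fixture, tmp_path_factory):
    return _run(pathway_fixture, "rna", "subjects_rna.fasta", tmp_path_factory.mktemp("rna"))


@pytest.fixture(scope="session")
def dna_run(pathway_fixture, tmp_path_factory):
    return _run(pathway_fixture, "dna", "subjects_dna.fasta", tmp_path_factory.mktemp("dna"))


@pytest.fixture(scope="session")
def two_families():
    """Two related enzyme families separated by diagnostic residues.

    Both descend from one ancestor; the first carries Q166/Q167 (the
    chalcone-synthase pattern), the second H166/Q167 (a stilbene-
    synthase pattern), with extra divergence between the families.
    """
    _, anc_truth = make_family(2, 300, 0.0, [], seed=SEED + 100, family="ANC")
    ancestor = anc_truth.families["ANC"]["ancestor"]
    fam_a, truth_a = make_family(
        6, 300, 0.10, [(166, "Q"), (167, "Q")], seed=SEED + 101, family="CHS",
        ancestor=ancestor,
    )
    rng = np.random.default_rng(SEED + 102)
    ancestor_b = _mutate(rng, ancestor, 0.25, {166, 167})
    fam_b, truth_b = make_family(
        6, 300, 0.10, [(166, "H"), (167, "Q")], seed=SEED + 103, family="STS",
        ancestor=ancestor_b,
    )
    bait_a = BaitSet("CHS", tuple(fam_a), fam_a[0].id)
    bait_b = BaitSet("STS", tuple(fam_b), fam_b[0].id)
    # the returned ancestors carry each family's diagnostic residues
    return (
        bait_a,
        bait_b,
        truth_a.families["CHS"]["ancestor"],
        truth_b.families["STS"]["ancestor"],
    )


def draw_candidates(ancestors: dict[str, str], n_each: int, seed: int, divergence: float = 0.10):
    """Fresh family members with known truth, for classification tests."""
    rng = np.random.default_rng(seed)
    out, truth = [], {}
    for i in range(n_each):
        for family, ancestor in ancestors.items():
            seq = Sequence(
                f"cand_{family}_{i}", _mutate(rng, ancestor, divergence, {166, 167}), "peptide"
            )
            out.append(seq)
            truth[seq.id] = family
    return out, truth
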