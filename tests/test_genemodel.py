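"""Grouping translated hits into loci and stitching gene models."""

import numpy as np
import pytest

from pathscreen.fixtures import GenePlan, make_family, make_genome
from pathscreen.genemodel import (
    CANONICAL_FLAG,
    PARTIAL_FLAG,
    ExonFragment,
    group_hits,
    read_gff3,
    stitch_isoform,
    write_gff3,
)
from pathscreen.knowledge_base import BaitSet
from pathscreen.search import SearchHit, filter_hits, search_candidates
from pathscreen.seqkit import Sequence, reverse_complement


@pytest.fixture(scope="module")
def family():
    baits, _ = make_family(6, 300, 0.12, [(166, "Q"), (167, "Q")], seed=5, family="CHS")
    return BaitSet("CHS", tuple(baits), baits[0].id)


def _dna_hits(family, genome, min_identity=0.4):
    hits = search_candidates(
        family, [genome], mode="dna", min_fragment_len=10, min_raw_score=30
    )
    return [h for h in hits if h.identity > min_identity]


def _loci(family, genome):
    return group_hits(_dna_hits(family, genome), 20000, baits={b.id: b for b in family})


def _make_hit(g_start, g_end, q_start, q_end, strand="+", contig="c", query="q"):
    return SearchHit(
        query_id=query, subject_id="f", identity=0.9, score=100.0,
        query_self_score=1000.0, q_start=q_start, q_end=q_end, s_start=1, s_end=10,
        strand=strand, contig=contig, g_start=g_start, g_end=g_end,
    )


class TestGroupHits:
    def test_two_colinear_hits_share_a_locus(self):
        hits = [_make_hit(1000, 1300, 1, 100), _make_hit(1800, 2100, 101, 200)]
        loci = group_hits(hits)
        assert len(loci) == 1 and len(loci[0].fragments) == 2

    def test_distant_hits_split(self):
        hits = [_make_hit(1000, 1300, 1, 100), _make_hit(10**6 + 1300, 10**6 + 1600, 101, 200)]
        assert len(group_hits(hits, max_intron_len=20000)) == 2

    def test_query_regression_separates_tandem_paralogs(self):
        hits = [
            _make_hit(1000, 1300, 1, 100),
            _make_hit(1800, 2100, 101, 200),
            _make_hit(3000, 3300, 1, 100),  # second copy restarts the query
            _make_hit(3800, 4100, 101, 200),
        ]
        loci = group_hits(hits)
        assert [len(l.fragments) for l in loci] == [2, 2]

    def test_rejects_non_genomic_hits(self):
        pep_hit = SearchHit("q", "s", 0.9, 50.0, 100.0, 1, 10, 1, 10)
        with pytest.raises(ValueError, match="dna-mode"):
            group_hits([pep_hit])

    def test_planted_paralogs_on_one_contig(self, family):
        genome, truth = make_genome(
            [
                GenePlan(Sequence("p1", family.baits[1].residues, "peptide"), 2, strand="+"),
                GenePlan(Sequence("p2", family.baits[2].residues, "peptide"), 3, strand="+"),
            ],
            intergenic_len=1500,
            seed=31,
            intron_len_range=(80, 300),
        )
        multi = [l for l in _loci(family, genome) if len(l.fragments) >= 2]
        loci = sorted(multi, key=lambda l: -l.total_score)[:2]
        spans = sorted(l.g_span for l in loci)
        planted = sorted(
            (g["exons"][0][0], g["exons"][-1][1]) for g in truth.genes
        )
        assert len(loci) == 2
        for (lo, hi), (plo, phi) in zip(spans, planted):
            assert abs(lo - plo) < 200 and abs(hi - phi) < 200
        assert [len(l.fragments) for l in sorted(loci, key=lambda l: l.g_span)] == [
            g["n_exons"] for g in truth.genes
        ]


class TestStitchIsoform:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_two_exon_gene_recovered_exactly(self, family, strand):
        peptide = family.baits[1].residues
        genome, truth = make_genome(
            [GenePlan(Sequence("g", peptide, "peptide"), 2, strand=strand)],
            intergenic_len=1000, seed=41, intron_len_range=(80, 300),
        )
        locus = max(_loci(family, genome), key=lambda l: l.total_score)
        model = stitch_isoform(locus, genome, 30)
        assert model.flag == CANONICAL_FLAG
        assert [list(e) for e in model.exons] == truth.genes[0]["exons"]
        assert model.peptide == peptide
        for a, b in model.introns:
            intron = genome.residues[a - 1 : b]
            if model.strand == "-":
                intron = reverse_complement(Sequence("i", intron, "dna")).residues
            assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_single_fragment_locus_verbatim(self, family):
        frag = ExonFragment("c", "+", 100, 399, 1, 100, 500.0)
        from pathscreen.genemodel import Locus

        rng = np.random.default_rng(3)
        backbone = "".join(rng.choice(list("ACGT"), 600))
        genome = Sequence("c", backbone, "dna")
        locus = Locus("c", "+", "q", [frag], bait=None)
        model = stitch_isoform(locus, genome, 30)
        assert model.flag == CANONICAL_FLAG
        assert model.exons == [(100, 399)] and model.introns == []

    def test_gc_ag_intron_yields_flagged_partial(self, family):
        peptide = family.baits[1].residues
        genome, _ = make_genome(
            [GenePlan(Sequence("g", peptide, "peptide"), 2, donor="GC")],
            intergenic_len=1000, seed=43, intron_len_range=(80, 300),
        )
        locus = max(_loci(family, genome), key=lambda l: l.total_score)
        model = stitch_isoform(locus, genome, 30)
        assert model.flag == PARTIAL_FLAG
        assert len(model.exons) == 1  # demoted to its single best fragment

    def test_strand_symmetry(self, family):
        """The reverse-complemented genome yields the same peptide."""
        peptide = family.baits[1].residues
        genome, _ = make_genome(
            [GenePlan(Sequence("g", peptide, "peptide"), 3, strand="+")],
            intergenic_len=1000, seed=47, intron_len_range=(80, 300),
        )
        flipped = reverse_complement(genome)
        peptides = set()
        for g in (genome, flipped):
            locus = max(_loci(family, g), key=lambda l: l.total_score)
            peptides.add(stitch_isoform(locus, g, 30).peptide)
        assert peptides == {peptide}

    def test_stitched_peptide_passes_hit_filter(self, family, ):
        peptide = family.baits[2].residues
        genome, _ = make_genome(
            [GenePlan(Sequence("g", peptide, "peptide"), 2)],
            intergenic_len=1000, seed=53, intron_len_range=(80, 300),
        )
        locus = max(_loci(family, genome), key=lambda l: l.total_score)
        model = stitch_isoform(locus, genome, 30)
        kept = filter_hits(
            search_candidates(
                family, [Sequence("m", model.peptide, "peptide")], mode="pep"
            )
        )
        assert any(h.subject_id == "m" for h in kept)


class TestGff3:
    def test_coordinates_round_trip(self, family, tmp_path):
        peptide = family.baits[1].residues
        genome, _ = make_genome(
            [GenePlan(Sequence("g", peptide, "peptide"), 3)],
            intergenic_len=800, seed=59, intron_len_range=(80, 200),
        )
        locus = max(_loci(family, genome), key=lambda l: l.total_score)
        model = stitch_isoform(locus, genome, 30, name="model1")
        path = tmp_path / "out.gff3"
        write_gff3([model], path)
        back = read_gff3(path)
        assert back["model1"]["exons"] == [tuple(map(int, e)) for e in model.exons]
        assert back["model1"]["strand"] == model.strand
        assert back["model1"]["flag"] == model.flag
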