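"""Junction classification on a hand-built 12-transcript annotation."""

import random

import numpy as np
import pytest

from txcomplexity.genome import AnnotationSet, GenomicInterval, JunctionTag
from txcomplexity.splicing import (
    call_alternative_5prime,
    call_alternative_junctions,
    canonical_junctions,
    classify_junction,
    detect_retained_introns,
)
from txcomplexity.simulate import SimulationConfig, simulate_annotation, simulate_junctions
from txcomplexity.utr import UtrScanParams

from conftest import make_coverage, make_transcript


@pytest.fixture(scope="module")
def toy() -> AnnotationSet:
    """Twelve transcripts exercising every event geometry on both strands."""
    ts = [
        # gene A: 6 exons, plus strand
        make_transcript(
            "tA.1",
            [(1000, 1100), (1200, 1300), (1400, 1500), (1600, 1700), (1800, 1900), (2000, 2100)],
        ),
        # gene B: 4 exons, minus strand
        make_transcript("tB.1", [(5000, 5100), (5200, 5300), (5400, 5500), (5600, 5700)], strand="-"),
        make_transcript("tC.1", [(8000, 8500)]),
        # gene D: two isoforms sharing their junction
        make_transcript("tD.1", [(10000, 10100), (10200, 10300)], gene="tD"),
        make_transcript("tD.2", [(10000, 10100), (10200, 10350)], gene="tD"),
        make_transcript("tE.1", [(12000, 12100), (12200, 12300)]),
        make_transcript("tF.1", [(14000, 14100), (14200, 14300)], strand="-"),
        make_transcript("tG.1", [(16000, 16200)]),
        make_transcript("tH.1", [(18000, 18100), (18200, 18300)]),
        make_transcript("tI.1", [(20000, 20100), (20200, 20300)]),
        make_transcript("tJ.1", [(22000, 22100), (22200, 22300)], strand="-"),
        make_transcript("tK.1", [(24000, 24100), (24200, 24300)]),
    ]
    return AnnotationSet(ts)


class TestCanonicalJunctions:
    def test_counts_per_transcript(self, toy):
        js = canonical_junctions(toy)
        in_a = [j for j in js if 1000 <= j.donor_end < 2100]
        assert len(in_a) == 5  # 6 exons -> 5 junctions

    def test_single_exon_contributes_none(self, toy):
        js = canonical_junctions(toy)
        assert not any(8000 <= j.donor_end < 8500 for j in js)

    def test_shared_junction_deduplicated(self, toy):
        js = [j for j in canonical_junctions(toy) if j.donor_end == 10100]
        assert len(js) == 1


def J(L, R, t=20, strand="+"):
    return JunctionTag("chr1", strand, L, R, t)


class TestClassification:
    def test_adjacent_pair_is_canonical(self, toy):
        call = classify_junction(J(1100, 1200), toy)
        assert call.kind == "canonical" and call.gene_id == "tA"

    def test_single_exon_skip(self, toy):
        call = classify_junction(J(1100, 1400), toy)
        assert call.kind == "exon_skip" and call.skipped_exons == (2,)

    def test_two_exon_skip_wt1_style(self, toy):
        """Junction joining exon 3's end to exon 6's start skips exons 4 and 5."""
        call = classify_junction(J(1500, 2000), toy)
        assert call.kind == "exon_skip" and call.skipped_exons == (4, 5)

    def test_alt_donor_novel_donor_in_intron(self, toy):
        call = classify_junction(J(1110, 1200), toy)
        assert call.kind == "alt_donor"

    def test_alt_acceptor_novel_acceptor(self, toy):
        call = classify_junction(J(1100, 1190), toy)
        assert call.kind == "alt_acceptor"

    def test_cassette_exon_both_boundaries_intronic(self, toy):
        call = classify_junction(J(1520, 1580), toy)
        assert call.kind == "cassette_exon" and call.gene_id == "tA"

    def test_minus_strand_canonical(self, toy):
        call = classify_junction(J(5500, 5600, strand="-"), toy)
        assert call.kind == "canonical" and call.gene_id == "tB"

    def test_minus_strand_exon_skip_numbering(self, toy):
        # joins transcript exon 1 (genomic right) to exon 3, skipping exon 2
        call = classify_junction(J(5300, 5600, strand="-"), toy)
        assert call.kind == "exon_skip" and call.skipped_exons == (2,)

    def test_minus_strand_alt_donor(self, toy):
        # donor of a minus transcript sits at the genomic-right boundary
        call = classify_junction(J(5300, 5588, strand="-"), toy)
        assert call.kind == "alt_donor"

    def test_alt_5prime_upstream_of_plus_gene(self, toy):
        call = classify_junction(J(500, 1000), toy)
        assert call.kind == "alt_5prime" and call.gene_id == "tA"

    def test_alt_5prime_upstream_of_minus_gene(self, toy):
        call = classify_junction(J(5700, 6500, strand="-"), toy)
        assert call.kind == "alt_5prime" and call.gene_id == "tB"

    def test_unassignable_junction_novel(self, toy):
        call = classify_junction(J(40000, 41000), toy)
        assert call.kind == "novel_unclassified" and call.gene_id is None

    def test_deterministic_and_order_independent(self, toy):
        js = [J(1100, 1400), J(1110, 1200), J(500, 1000), J(1520, 1580)]
        expected = [classify_junction(j, toy).kind for j in js]
        shuffled = js[::-1]
        got = {id(j): classify_junction(j, toy).kind for j in shuffled}
        assert [got[id(j)] for j in js] == expected

    def test_every_canonical_junction_classifies_canonical(self, toy):
        for j in canonical_junctions(toy):
            assert classify_junction(j, toy).kind == "canonical"

    def test_no_false_alternatives_on_simulated_annotation(self):
        cfg = SimulationConfig(genome=[("chr1", 700_000)], n_genes=10, seed=4)
        ann, truth = simulate_annotation(cfg)
        for j in simulate_junctions(ann, truth):
            assert classify_junction(j, ann).kind == "canonical"


class TestThresholds:
    def test_candidate_and_report_thresholds_record_for_record(self, toy):
        # six distinct alt_acceptor junctions with tag counts 1,2,4,5,9,10
        counts = [1, 2, 4, 5, 9, 10]
        js = [J(1100, 1180 + i, t=c) for i, c in enumerate(counts)]
        calls = call_alternative_junctions(js, toy, min_candidate=2, min_report=5)
        got = sorted(c.junction.tag_count for c in calls)
        assert got == [2, 4, 5, 9, 10]  # t=1 excluded below the candidate cutoff
        reportable = sorted(c.junction.tag_count for c in calls if c.reportable)
        assert reportable == [5, 9, 10]

    def test_canonical_junctions_never_reported(self, toy):
        calls = call_alternative_junctions([J(1100, 1200, t=500)], toy)
        assert calls == []

    def test_alt5_ten_tag_cutoff(self, toy):
        ten = J(500, 1000, t=10)
        nine = J(400, 1000, t=9)
        inside = J(1100, 1200, t=50)
        calls = call_alternative_5prime([ten, nine, inside], toy, min_tags=10)
        assert len(calls) == 1
        assert calls[0].junction.tag_count == 10 and calls[0].kind == "alt_5prime"


class TestRetainedIntron:
    def test_covered_intron_detected_uncovered_not(self, toy):
        cov = make_coverage(N=10**7)
        t = toy.get("tA.1")
        # gene body at ~rate lam so gene RPKM is well-defined
        lam = 3
        for e in t.exons:
            cov.add("chr1", "+", e.start, np.full(len(e), lam))
        intron1 = t.introns()[0]
        cov.add("chr1", "+", intron1.start, np.full(len(intron1), lam))
        gene_rpkm = {
            "tA": (t.exon_length + len(intron1)) and lam * 1e9 / 10**7  # per-base rate as RPKM
        }
        events = detect_retained_introns(cov, toy, gene_rpkm, UtrScanParams())
        assert [(e.gene_id, e.intron_number) for e in events] == [("tA", 1)]
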