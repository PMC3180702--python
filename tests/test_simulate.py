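"""Generator contracts: determinism, planted geometry, count calibration."""

import numpy as np
import pytest

from txcomplexity.genome import GenomicInterval
from txcomplexity.quantify import gene_expression_table
from txcomplexity.simulate import (
    COMPARTMENTS,
    ConfigurationError,
    PlantedAntisense,
    PlantedFeatureSpec,
    PlantedJunction,
    PlantedMarker,
    SimulationConfig,
    simulate_annotation,
    simulate_coverage,
    simulate_junctions,
    simulate_probeset_matrix,
)


def small_config(**kw) -> SimulationConfig:
    defaults = dict(genome=[("chr1", 700_000)], n_genes=10, seed=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAnnotation:
    def test_determinism_given_seed(self):
        a1, t1 = simulate_annotation(small_config())
        a2, t2 = simulate_annotation(small_config())
        assert [(t.transcript_id, t.span, tuple(t.exons)) for t in a1] == [
            (t.transcript_id, t.span, tuple(t.exons)) for t in a2
        ]
        assert t1.gene_targets == t2.gene_targets

    def test_no_same_strand_span_overlap(self):
        ann, _ = simulate_annotation(small_config(n_genes=8, seed=5))
        genes = [t for t in ann]
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if a.strand == b.strand and a.chrom == b.chrom:
                    assert not a.span.overlaps(b.span)

    def test_embedded_partner_strictly_inside_opposite_strand(self):
        cfg = small_config(
            planted=PlantedFeatureSpec(
                antisense=[PlantedAntisense("g002", "embedded", 20.0)]
            )
        )
        ann, truth = simulate_annotation(cfg)
        host = ann.get("g002.t1")
        partner = ann.get("g002_as.t1")
        assert partner.strand != host.strand
        assert host.span.start < partner.span.start
        assert partner.span.end < host.span.end

    def test_zero_genes_empty_annotation(self):
        ann, _ = simulate_annotation(small_config(n_genes=0))
        assert len(ann) == 0

    def test_impossible_placement_raises(self):
        with pytest.raises(ConfigurationError, match="too small"):
            simulate_annotation(small_config(genome=[("chr1", 40_000)], n_genes=10))

    def test_unknown_planted_gene_raises(self):
        cfg = small_config(
            planted=PlantedFeatureSpec(antisense=[PlantedAntisense("g999", "embedded", 5.0)])
        )
        with pytest.raises(ConfigurationError, match="unknown genes"):
            simulate_annotation(cfg)


class TestCoverage:
    def test_expected_total_tag_starts(self):
        """target 50 RPKM, N=1e7, 1000 exonic bp -> 500 expected tag starts."""
        cfg = small_config(
            genome=[("chr1", 60_000)],
            n_genes=1,
            gene_length_range=(1000, 1000),
            exon_count_range=(1, 1),
            target_rpkm_range=(50.0, 50.0),
            library_total_tags=10**7,
            noise="none",
        )
        ann, truth = simulate_annotation(cfg)
        cov = simulate_coverage(ann, truth, cfg)
        assert cov.total_tags_stored() == 500

    def test_zero_background_outside_features(self):
        cfg = small_config(noise="poisson", seed=9)
        ann, truth = simulate_annotation(cfg)
        cov = simulate_coverage(ann, truth, cfg)
        t = next(iter(ann))
        # first intron must be empty at background 0
        intron = t.introns()[0]
        assert cov.count_in(intron) == 0

    def test_rpkm_converges_to_target(self):
        """Empirical RPKM within 3 Poisson SE of target for >=95% of genes."""
        cfg = small_config(n_genes=10, seed=21)
        ann, truth = simulate_annotation(cfg)
        cov = simulate_coverage(ann, truth, cfg)
        records = {r.gene_id: r for r in gene_expression_table(cov, ann)}
        ok = 0
        for gene, target in truth.gene_targets.items():
            r = records[gene]
            lamL = target * cov.library_total_tags / 1e9 * r.L
            assert lamL >= 100
            se = 3 * np.sqrt(lamL) / lamL * target  # 3 SE on the RPKM scale
            ok += abs(r.rpkm - target) <= se
        assert ok / len(truth.gene_targets) >= 0.95

    def test_deterministic_mode_reproducible(self):
        cfg = small_config(noise="none")
        ann, truth = simulate_annotation(cfg)
        c1 = simulate_coverage(ann, truth, cfg)
        c2 = simulate_coverage(ann, truth, cfg)
        for chrom, strand in c1._arrays:
            assert np.array_equal(c1.counts(chrom, strand), c2.counts(chrom, strand))


class TestJunctions:
    def test_single_exon_transcript_has_no_canonical_junctions(self):
        cfg = small_config(
            genome=[("chr1", 60_000)], n_genes=1, exon_count_range=(1, 1)
        )
        ann, truth = simulate_annotation(cfg)
        assert simulate_junctions(ann, truth) == []

    def test_planted_counts_and_geometry(self):
        cfg = small_config(
            planted=PlantedFeatureSpec(
                alt_junctions=[PlantedJunction("g001", "exon_skip", 350, n_skip=1)]
            )
        )
        ann, truth = simulate_annotation(cfg)
        js = simulate_junctions(ann, truth)
        (rec,) = truth.of_kind("alt_junction")
        planted = [
            j for j in js
            if (j.donor_end, j.acceptor_start) == (rec.footprint.start, rec.footprint.end)
        ]
        assert len(planted) == 1 and planted[0].tag_count == 350

    def test_incompatible_skip_raises(self):
        cfg = small_config(
            exon_count_range=(2, 3),
            planted=PlantedFeatureSpec(
                alt_junctions=[PlantedJunction("g000", "exon_skip", 10, n_skip=4)]
            ),
        )
        with pytest.raises(ConfigurationError, match="exon"):
            simulate_annotation(cfg)


class TestProbesets:
    def test_eleven_compartments_in_stated_order(self):
        cfg = small_config()
        ann, truth = simulate_annotation(cfg)
        _ps, matrix = simulate_probeset_matrix(ann, truth, config=cfg)
        assert matrix.compartments == COMPARTMENTS
        assert len(matrix.compartments) == 11

    def test_marker_row_maximal_in_its_compartment(self):
        cfg = small_config(
            planted=PlantedFeatureSpec(
                compartment_markers=[PlantedMarker("g003", "cap mesenchyme", 25.0)]
            )
        )
        ann, truth = simulate_annotation(cfg)
        _ps, matrix = simulate_probeset_matrix(ann, truth, config=cfg)
        row = matrix.intensities.loc["ps_g003"]
        assert row.idxmax() == "cap mesenchyme"

    def test_seed_fixed_identical_matrix(self):
        cfg = small_config()
        ann, truth = simulate_annotation(cfg)
        _p1, m1 = simulate_probeset_matrix(ann, truth, config=cfg)
        _p2, m2 = simulate_probeset_matrix(ann, truth, config=cfg)
        assert m1.intensities.equals(m2.intensities)

    def test_unknown_marker_compartment_raises(self):
        cfg = small_config(
            planted=PlantedFeatureSpec(
                compartment_markers=[PlantedMarker("g000", "cap mesenchyme", 5.0)]
            )
        )
        ann, truth = simulate_annotation(cfg)
        with pytest.raises(ConfigurationError):
            simulate_probeset_matrix(ann, truth, compartments=["only one"], config=cfg)
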