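"""Extended-3'UTR scan: window conventions, the three call criteria, masking."""

import numpy as np
import pytest

from txcomplexity.genome import AnnotationSet, GenomicInterval
from txcomplexity.quantify import gene_expression_table
from txcomplexity.simulate import (
    PlantedFeatureSpec,
    PlantedUtrExtension,
    SimulationConfig,
    simulate_annotation,
    simulate_coverage,
)
from txcomplexity.utr import (
    UtrScanParams,
    Window,
    annotate_known_extension,
    call_extension,
    detect_extensions,
    scan_downstream_windows,
)

from conftest import make_coverage, make_transcript

N = 10**7
# a window count whose window RPKM equals the gene RPKM of `GENE_RPKM`
GENE_RPKM = 100.0
FULL = int(GENE_RPKM * N * 30 / 1e9)  # 30 counts per window


def windows_from_counts(counts, masked=(), start=1000, strand="+"):
    out = []
    for i, c in enumerate(counts):
        if strand == "+":
            iv = GenomicInterval("chr1", start + 30 * i, start + 30 * (i + 1), strand)
        else:
            iv = GenomicInterval("chr1", start - 30 * (i + 1), start - 30 * i, strand)
        out.append(Window(iv, c, masked=i in masked))
    return out


class TestWindowTiling:
    def test_plus_strand_first_window(self):
        t = make_transcript("t.1", [(400, 1000)])
        cov = make_coverage()
        ws = scan_downstream_windows(cov, t, AnnotationSet([t]))
        assert (ws[0].interval.start, ws[0].interval.end) == (1000, 1030)
        assert len(ws) == 20_000 // 30

    def test_minus_strand_first_window(self):
        t = make_transcript("t.1", [(5000, 6000)], strand="-")
        cov = make_coverage()
        ws = scan_downstream_windows(cov, t, AnnotationSet([t]))
        assert (ws[0].interval.start, ws[0].interval.end) == (4970, 5000)

    def test_windows_over_other_transcript_masked(self):
        t = make_transcript("t.1", [(400, 1000)])
        other = make_transcript("o.1", [(1200, 2000)], strand="-")
        cov = make_coverage()
        ws = scan_downstream_windows(cov, t, AnnotationSet([t, other]))
        # windows [1000,1030)...: window index 6 is [1180,1210) -> overlaps
        assert not ws[5].masked
        assert all(w.masked for w in ws[6:33])

    def test_truncated_at_chromosome_edge(self):
        t = make_transcript("t.1", [(100, 500)], strand="-")
        cov = make_coverage()
        ws = scan_downstream_windows(cov, t, AnnotationSet([t]))
        # minus-strand 3' end at 100: only 100 bp of downstream room
        assert len(ws) == 100 // 30


class TestCallCriteria:
    def test_twenty_full_windows_called_600bp(self):
        ws = windows_from_counts([FULL] * 20 + [0] * 40)
        call = call_extension(ws, GENE_RPKM, N, strand="+")
        assert call is not None
        assert call.extension_length == 600
        assert call.run_length == 20
        assert (call.extension.start, call.extension.end) == (1000, 1600)

    def test_twelve_windows_fails_length_criterion(self):
        ws = windows_from_counts([FULL] * 12 + [0] * 40)
        assert call_extension(ws, GENE_RPKM, N) is None  # 360 bp <= 500

    def test_forty_percent_signal_fails_fraction_criterion(self):
        ws = windows_from_counts([int(FULL * 0.4)] * 30)
        assert call_extension(ws, GENE_RPKM, N) is None

    def test_seventeen_vs_sixteen_window_boundary(self):
        """With defaults a call needs run >= 17 (510 bp > 500)."""
        ws17 = windows_from_counts([FULL] * 17 + [0] * 40)
        ws16 = windows_from_counts([FULL] * 16 + [0] * 40)
        assert call_extension(ws17, GENE_RPKM, N) is not None
        assert call_extension(ws16, GENE_RPKM, N) is None

    def test_window_at_exactly_half_gene_rpkm_is_expressed(self):
        ws = windows_from_counts([FULL // 2] * 20 + [0] * 10)
        call = call_extension(ws, GENE_RPKM, N)
        assert call is not None and call.run_length == 20

    def test_masked_window_truncates_anchored_run(self):
        ws = windows_from_counts([FULL] * 40, masked={20})
        call = call_extension(ws, GENE_RPKM, N)
        assert call is not None
        assert call.run_length == 20  # clipped at the first masked window

    def test_mask_skip_policy_continues_run(self):
        params = UtrScanParams(mask_policy="skip")
        ws = windows_from_counts([FULL] * 40, masked={20})
        call = call_extension(ws, GENE_RPKM, N, params)
        assert call is not None and call.run_length == 39

    def test_minus_strand_extension_interval(self):
        ws = windows_from_counts([FULL] * 20 + [0] * 10, start=9000, strand="-")
        call = call_extension(ws, GENE_RPKM, N, strand="-")
        assert (call.extension.start, call.extension.end) == (8400, 9000)

    def test_gap_in_run_stops_at_gap(self):
        ws = windows_from_counts([FULL] * 10 + [0] + [FULL] * 30)
        assert call_extension(ws, GENE_RPKM, N) is None  # anchored run only 10 -> 300bp


class TestKnownAnnotation:
    def test_extension_inside_longer_model_flagged(self):
        ws = windows_from_counts([FULL] * 20 + [0] * 10)
        call = call_extension(ws, GENE_RPKM, N, gene_id="g", strand="+")
        longer = make_transcript("h.1", [(500, 3000)])
        flagged = annotate_known_extension(call, AnnotationSet([longer]))
        assert flagged.previously_annotated is True

    def test_no_known_set_unannotated(self):
        ws = windows_from_counts([FULL] * 20 + [0] * 10)
        call = annotate_known_extension(call_extension(ws, GENE_RPKM, N), None)
        assert call.previously_annotated is False

    def test_opposite_strand_known_model_ignored(self):
        ws = windows_from_counts([FULL] * 20 + [0] * 10)
        call = call_extension(ws, GENE_RPKM, N, strand="+")
        minus_model = make_transcript("h.1", [(500, 3000)], strand="-")
        flagged = annotate_known_extension(call, AnnotationSet([minus_model]))
        assert flagged.previously_annotated is False


def planted_dataset(noise="none", seed=2):
    planted = PlantedFeatureSpec(
        utr_extensions=[
            PlantedUtrExtension("g000", 1500, 1.0),
            PlantedUtrExtension("g001", 600, 1.0),
            PlantedUtrExtension("g002", 3000, 1.0),
        ]
    )
    cfg = SimulationConfig(
        genome=[("chr1", 700_000)], n_genes=10, seed=seed, noise=noise, planted=planted
    )
    ann, truth = simulate_annotation(cfg)
    cov = simulate_coverage(ann, truth, cfg)
    rpkms = {r.gene_id: r.rpkm for r in gene_expression_table(cov, ann)}
    return cfg, ann, cov, rpkms


class TestDetection:
    def test_noise_free_recovery_of_planted_extensions(self):
        _cfg, ann, cov, rpkms = planted_dataset()
        calls = {c.gene_id: c for c in detect_extensions(cov, ann, rpkms)}
        assert set(calls) == {"g000", "g001", "g002"}
        # called length within one window of the planted length
        assert abs(calls["g000"].extension_length - 1500) <= 30
        assert abs(calls["g002"].extension_length - 3000) <= 30

    def test_monotonicity_in_f_k_m(self):
        """Raising f, k or m never increases the number of calls."""
        _cfg, ann, cov, rpkms = planted_dataset(noise="poisson")
        base = len(detect_extensions(cov, ann, rpkms, UtrScanParams()))
        for params in (
            UtrScanParams(f=0.8),
            UtrScanParams(k=40),
            UtrScanParams(m=2000),
        ):
            assert len(detect_extensions(cov, ann, rpkms, params)) <= base

    def test_strand_symmetry_under_reflection(self):
        """Reflecting the genome and swapping strands mirrors the calls."""
        from conftest import reflect_annotation, reflect_coverage, reflect_interval

        _cfg, ann, cov, rpkms = planted_dataset()
        length = cov.chrom_lengths["chr1"]
        calls = detect_extensions(cov, ann, rpkms)
        m_calls = detect_extensions(reflect_coverage(cov), reflect_annotation(ann, length), rpkms)
        fwd = {(c.gene_id, c.extension.start, c.extension.end) for c in calls}
        mirrored = {
            (c.gene_id, length - c.extension.end, length - c.extension.start)
            for c in m_calls
        }
        assert fwd == mirrored
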