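"""Shared fixtures: hand-built annotations and coverage vectors."""

from __future__ import annotations

import numpy as np
import pytest

from txcomplexity.genome import (
    AnnotationSet,
    GenomicInterval,
    StrandedCoverage,
    TranscriptModel,
)


def make_transcript(
    tid: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    gene: str | None = None,
    biotype: str = "coding",
) -> TranscriptModel:
    ivs = [GenomicInterval(chrom, a, b, strand) for a, b in exons]
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid.split(".")[0],
        span=GenomicInterval(chrom, ivs[0].start, ivs[-1].end, strand),
        exons=ivs,
        biotype=biotype,
    )


def make_coverage(
    chrom_len: int = 100_000, N: int = 10_000_000, chrom: str = "chr1"
) -> StrandedCoverage:
    return StrandedCoverage({chrom: chrom_len}, N)


@pytest.fixture
def simple_transcript() -> TranscriptModel:
    """Two-exon plus-strand transcript: exons [100,300) and [500,800)."""
    return make_transcript("tA.1", [(100, 300), (500, 800)])


@pytest.fixture
def simple_annotation(simple_transcript) -> AnnotationSet:
    return AnnotationSet([simple_transcript])


def reflect_interval(iv: GenomicInterval, length: int) -> GenomicInterval:
    """Mirror an interval about the chromosome midpoint and flip its strand."""
    flip = {"+": "-", "-": "+", ".": "."}
    return GenomicInterval(iv.chrom, length - iv.end, length - iv.start, flip[iv.strand])


def reflect_annotation(ann: AnnotationSet, length: int) -> AnnotationSet:
    out = AnnotationSet()
    for t in ann:
        exons = sorted(
            (reflect_interval(e, length) for e in t.exons), key=lambda e: e.start
        )
        span = reflect_interval(t.span, length)
        out.add(
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                span=span,
                exons=exons,
                biotype=t.biotype,
            )
        )
    return out


def reflect_coverage(cov: StrandedCoverage) -> StrandedCoverage:
    """Reverse every coverage vector and swap the two strands."""
    out = StrandedCoverage(cov.chrom_lengths, cov.library_total_tags)
    for chrom in cov.chrom_lengths:
        for strand, flipped in (("+", "-"), ("-", "+")):
            arr = cov._arrays.get((chrom, strand))
            if arr is not None:
                out.add(chrom, flipped, 0, arr[::-1].copy())
    return out
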