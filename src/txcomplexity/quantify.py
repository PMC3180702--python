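"""Tag-start counting, RPKM computation and expressed-locus tables.

RPKM (reads per kilobase of exon model per million mapped tags) is
``C x 10^9 / (N x L)`` where C is the strand-matched tag-start count within
the exon union, L the exon-union length in bp, and N the library's total
mapped tag count. Counting is strand-matched only: antisense signal is never
included in a gene's C (the library is stranded and antisense transcription
is analysed separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import (
    AnnotationSet,
    GenomicInterval,
    StrandedCoverage,
    TranscriptModel,
)


@dataclass(frozen=True)
class ExpressionRecord:
    """Expression of one locus or transcript: counts, length, RPKM."""

    gene_id: str
    C: int
    L: int
    rpkm: float
    transcript_ids: tuple[str, ...] = ()
    biotype: str = "coding"


def rpkm(C: int, L: int, N: int) -> float:
    """Reads per kilobase per million mapped tags: C x 10^9 / (N x L)."""
    if L <= 0:
        raise ValueError(f"exon length L must be positive, got {L}")
    if N <= 0:
        raise ValueError(f"library size N must be positive, got {N}")
    if C < 0:
        raise ValueError(f"count C must be non-negative, got {C}")
    return C * 1e9 / (N * L)


def count_tag_starts(cov: StrandedCoverage, model: TranscriptModel) -> int:
    """Strand-matched tag-start count within the transcript's exon union."""
    if model.chrom not in cov.chrom_lengths:
        raise KeyError(f"chromosome {model.chrom!r} absent from coverage")
    return cov.count_exons(model)


def _exon_union(models: Sequence[TranscriptModel]) -> list[GenomicInterval]:
    """Merge exons of same-gene transcripts into a disjoint union."""
    exons = sorted(
        (e for m in models for e in m.exons), key=lambda e: (e.start, e.end)
    )
    merged: list[GenomicInterval] = []
    for e in exons:
        if merged and e.start <= merged[-1].end:
            if e.end > merged[-1].end:
                merged[-1] = GenomicInterval(e.chrom, merged[-1].start, e.end, e.strand)
        else:
            merged.append(e)
    return merged


def gene_expression_table(
    cov: StrandedCoverage, ann: AnnotationSet
) -> list[ExpressionRecord]:
    """One record per gene over the union of its transcripts' exons."""
    out = []
    for gene_id, models in sorted(ann.by_gene().items()):
        union = _exon_union(models)
        strand = models[0].strand
        C = sum(cov.count_in(e, strand=strand) for e in union)
        L = sum(len(e) for e in union)
        biotype = "coding" if any(m.biotype == "coding" for m in models) else "noncoding"
        out.append(
            ExpressionRecord(
                gene_id=gene_id,
                C=C,
                L=L,
                rpkm=rpkm(C, L, cov.library_total_tags),
                transcript_ids=tuple(m.transcript_id for m in models),
                biotype=biotype,
            )
        )
    return out


def transcript_expression_table(
    cov: StrandedCoverage, ann: AnnotationSet
) -> list[ExpressionRecord]:
    """One record per transcript over its own exons."""
    out = []
    for t in ann:
        C = count_tag_starts(cov, t)
        out.append(
            ExpressionRecord(
                gene_id=t.gene_id,
                C=C,
                L=t.exon_length,
                rpkm=rpkm(C, t.exon_length, cov.library_total_tags),
                transcript_ids=(t.transcript_id,),
                biotype=t.biotype,
            )
        )
    return out


def expressed_loci(
    records: Iterable[ExpressionRecord],
    threshold: float = 1.0,
    biotype: Optional[str] = None,
) -> list[ExpressionRecord]:
    """Records at or above the RPKM threshold (inclusive), optionally by biotype.

    The threshold is inclusive: a locus at exactly 1 RPKM counts as active.
    """
    out = [r for r in records if r.rpkm >= threshold]
    if biotype is not None:
        out = [r for r in out if r.biotype == biotype]
    return out


def tukey_hinges(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Five-number summary with Tukey (median-of-halves) hinges.

    Returns (min, lower hinge, median, upper hinge, max). With an odd number
    of observations the median is included in both halves.
    """
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        raise ValueError("empty sample")

    def med(a: Sequence[float]) -> float:
        m = len(a)
        return a[m // 2] if m % 2 else (a[m // 2 - 1] + a[m // 2]) / 2.0

    half = (n + 1) // 2  # include median in both halves when n odd
    return (v[0], med(v[:half]), med(v), med(v[n - half:]), v[-1])


@dataclass(frozen=True)
class CompartmentSummary:
    compartment: str
    marker_count: int
    detected_count: int
    detection_fraction: Optional[float]
    rpkm_summary: Optional[tuple[float, float, float, float, float]]


@dataclass(frozen=True)
class CompartmentSensitivityReport:
    compartments: tuple[CompartmentSummary, ...]
    overall_detection_fraction: Optional[float]


def compartment_sensitivity(
    markers: dict[str, Sequence[str]],
    records: Iterable[ExpressionRecord],
    detect_threshold: float = 1.0,
) -> CompartmentSensitivityReport:
    """Per-compartment marker detection fractions and RPKM five-number summaries.

    A marker gene without an expression record counts as undetected; a
    compartment with an empty marker list is reported with missing fraction.
    """
    by_gene = {r.gene_id: r for r in records}
    summaries = []
    total_markers = 0
    total_detected = 0
    for comp, genes in markers.items():
        genes = list(genes)
        if not genes:
            summaries.append(CompartmentSummary(comp, 0, 0, None, None))
            continue
        values = [by_gene[g].rpkm if g in by_gene else 0.0 for g in genes]
        detected = sum(1 for v in values if v >= detect_threshold)
        total_markers += len(genes)
        total_detected += detected
        summaries.append(
            CompartmentSummary(
                compartment=comp,
                marker_count=len(genes),
                detected_count=detected,
                detection_fraction=detected / len(genes),
                rpkm_summary=tukey_hinges(values),
            )
        )
    overall = total_detected / total_markers if total_markers else None
    return CompartmentSensitivityReport(tuple(summaries), overall)
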