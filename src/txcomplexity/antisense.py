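"""Strand-specific detection of sense-antisense transcript pairs.

For every annotated (sense) transcript, opposite-strand tag starts within its
exon union quantify antisense expression; transcripts whose antisense RPKM
reaches the calling threshold (default 10 RPKM) are emitted as pairs. The
overlap geometry is classified from the contiguous extent of the
opposite-strand signal, in sense-transcript orientation: head_to_head
(extent overlaps and extends beyond the 5' terminus), tail_to_tail (beyond
the 3' terminus), embedded (inside the span) or full_span (covers the span).
Orientation is decided from signal extent rather than from any annotated
partner, so uncharacterized antisense transcripts are classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genome import (
    AnnotationSet,
    GenomicInterval,
    StrandedCoverage,
    TranscriptModel,
    opposite_strand,
)
from .quantify import rpkm

ORIENTATIONS = ("head_to_head", "tail_to_tail", "embedded", "full_span")


@dataclass(frozen=True)
class AntisensePair:
    sense_transcript: TranscriptModel
    antisense_rpkm: float
    antisense_extent: GenomicInterval
    orientation: str
    partner_model: Optional[TranscriptModel] = None
    known_nat: bool = False


def opposite_strand_expression(cov: StrandedCoverage, model: TranscriptModel) -> float:
    """RPKM over the sense transcript's exon union using opposite-strand tag starts."""
    opp = opposite_strand(model.strand)
    C = cov.count_exons(model, strand=opp)
    return rpkm(C, model.exon_length, cov.library_total_tags)


def classify_orientation(sense: GenomicInterval, extent: GenomicInterval) -> str:
    """Overlap orientation class in sense-transcript orientation."""
    if not sense.overlaps(extent):
        raise ValueError("sense span and antisense extent do not intersect")
    if extent.start <= sense.start and extent.end >= sense.end:
        return "full_span"
    if sense.strand == "+":
        beyond_5 = extent.start < sense.start
        beyond_3 = extent.end > sense.end
    else:
        beyond_5 = extent.end > sense.end
        beyond_3 = extent.start < sense.start
    if beyond_5:
        return "head_to_head"
    if beyond_3:
        return "tail_to_tail"
    return "embedded"


def _antisense_extent(
    cov: StrandedCoverage, model: TranscriptModel, max_gap: int
) -> Optional[GenomicInterval]:
    """Bounding interval of opposite-strand covered runs intersecting the span.

    Runs are first merged with a gap tolerance (tag-start sparsity fragments
    contiguous transcription into runs); the search region extends one scan
    radius beyond the span on both sides so an extent can reach past the
    sense termini.
    """
    opp = opposite_strand(model.strand)
    margin = 25_000
    runs = cov.covered_runs(
        model.chrom,
        opp,
        model.span.start - margin,
        model.span.end + margin,
        max_gap=max_gap,
    )
    hits = [r for r in runs if r[0] < model.span.end and r[1] > model.span.start]
    if not hits:
        return None
    return GenomicInterval(model.chrom, hits[0][0], hits[-1][1], opp)


def detect_antisense(
    cov: StrandedCoverage,
    ann: AnnotationSet,
    min_rpkm: float = 10.0,
    min_sense_rpkm: float = 0.0,
    gap_tolerance: int = 30,
) -> list[AntisensePair]:
    """One pair per sense transcript with antisense expression >= min_rpkm.

    The 10 RPKM threshold applies to the antisense signal; an optional
    independent minimum on the sense transcript's own RPKM can be set with
    ``min_sense_rpkm``. ``gap_tolerance`` (default 30 bp, the window grain
    used elsewhere) merges fragmented covered runs into a contiguous extent.
    """
    pairs: list[AntisensePair] = []
    for t in ann:
        as_rpkm = opposite_strand_expression(cov, t)
        if as_rpkm < min_rpkm:
            continue
        if min_sense_rpkm > 0:
            sense_rpkm = rpkm(
                cov.count_exons(t), t.exon_length, cov.library_total_tags
            )
            if sense_rpkm < min_sense_rpkm:
                continue
        extent = _antisense_extent(cov, t, gap_tolerance)
        if extent is None:
            continue
        orientation = classify_orientation(t.span, extent)
        partner = None
        opp = opposite_strand(t.strand)
        partners = [
            p for p in ann.overlapping(extent, strand=opp) if p.gene_id != t.gene_id
        ]
        if partners:
            partner = max(partners, key=lambda p: p.span.intersection_length(extent))
        pairs.append(
            AntisensePair(
                sense_transcript=t,
                antisense_rpkm=as_rpkm,
                antisense_extent=extent,
                orientation=orientation,
                partner_model=partner,
            )
        )
    return pairs


def flag_known_nat(
    pairs: Iterable[AntisensePair],
    known: Optional[Sequence[GenomicInterval]] = None,
) -> list[AntisensePair]:
    """Set known_nat where the sense span intersects a documented NAT locus
    (strand-agnostic intersection); with no list supplied all flags are False."""
    out = []
    for p in pairs:
        hit = False
        if known:
            span = p.sense_transcript.span
            hit = any(
                span.chrom == k.chrom and span.start < k.end and k.start < span.end
                for k in known
            )
        out.append(
            AntisensePair(
                p.sense_transcript,
                p.antisense_rpkm,
                p.antisense_extent,
                p.orientation,
                p.partner_model,
                known_nat=hit,
            )
        )
    return out
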