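"""Alternative exon-junction calling and event classification.

Junction tags carry exact donor/acceptor boundaries (they originate from a
curated junction library), so boundary matching is exact by default, with a
configurable tolerance. Event vocabulary: canonical, exon_skip, alt_donor,
alt_acceptor, cassette_exon, alt_5prime, novel_unclassified. Retained introns
leave no junction signature and are detected separately from contiguous
same-strand coverage across an annotated intron.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .genome import (
    AnnotationSet,
    GenomicInterval,
    JunctionTag,
    StrandedCoverage,
    TranscriptModel,
)
from .quantify import rpkm
from .utr import UtrScanParams

JUNCTION_KINDS = (
    "canonical",
    "cassette_exon",
    "exon_skip",
    "alt_donor",
    "alt_acceptor",
    "alt_5prime",
    "novel_unclassified",
)


@dataclass(frozen=True)
class JunctionCall:
    junction: JunctionTag
    gene_id: Optional[str]
    transcript_id: Optional[str]
    kind: str
    skipped_exons: tuple[int, ...] = ()
    reportable: bool = False


def canonical_junctions(ann: AnnotationSet) -> list[JunctionTag]:
    """Deduplicated skeletons of every adjacent-exon junction in the annotation."""
    seen: set[tuple[str, str, int, int]] = set()
    out: list[JunctionTag] = []
    for t in ann:
        for a, b in zip(t.exons, t.exons[1:]):
            key = (t.chrom, t.strand, a.end, b.start)
            if key not in seen:
                seen.add(key)
                out.append(JunctionTag(t.chrom, t.strand, a.end, b.start, tag_count=1))
    out.sort(key=lambda j: (j.chrom, j.donor_end, j.acceptor_start, j.strand))
    return out


def _boundary_match(boundaries: Sequence[int], coord: int, tol: int) -> Optional[int]:
    for i, b in enumerate(boundaries):
        if abs(b - coord) <= tol:
            return i
    return None


def _classify_against(
    j: JunctionTag, t: TranscriptModel, tol: int
) -> tuple[str, tuple[int, ...]]:
    """Classify a junction against one same-strand transcript."""
    ends = [e.end for e in t.exons]
    starts = [e.start for e in t.exons]
    L, R = j.donor_end, j.acceptor_start
    li = _boundary_match(ends, L, tol)       # genomic-left boundary vs exon ends
    ri = _boundary_match(starts, R, tol)     # genomic-right boundary vs exon starts

    n = t.n_exons
    if li is not None and ri is not None:
        if ri == li + 1:
            return "canonical", ()
        if ri > li + 1:
            # skipped exon numbers reported in transcript (5'->3') orientation
            genomic = range(li + 1, ri)
            if t.strand == "+":
                skipped = tuple(g + 1 for g in genomic)
            else:
                skipped = tuple(sorted(n - g for g in genomic))
            return "exon_skip", skipped

    # upstream boundary beyond the transcript's 5' start (transcript orientation)
    if t.strand == "+" and L < t.span.start:
        return "alt_5prime", ()
    if t.strand == "-" and R > t.span.end:
        return "alt_5prime", ()

    # directional donor/acceptor matching: on the minus strand the biological
    # donor sits at the genomic-right boundary
    if t.strand == "+":
        donor_matched, acceptor_matched = li is not None, ri is not None
    else:
        donor_matched = _boundary_match(starts, R, tol) is not None
        acceptor_matched = _boundary_match(ends, L, tol) is not None
    if donor_matched and not acceptor_matched:
        return "alt_acceptor", ()
    if acceptor_matched and not donor_matched:
        return "alt_donor", ()

    if not donor_matched and not acceptor_matched:
        for intron in t.introns():
            if intron.start <= L and R <= intron.end:
                return "cassette_exon", ()

    return "novel_unclassified", ()


def _n_matching_boundaries(j: JunctionTag, t: TranscriptModel, tol: int) -> int:
    ends = [e.end for e in t.exons]
    starts = [e.start for e in t.exons]
    return int(_boundary_match(ends, j.donor_end, tol) is not None) + int(
        _boundary_match(starts, j.acceptor_start, tol) is not None
    )


def classify_junction(
    j: JunctionTag, ann: AnnotationSet, tol: int = 0
) -> JunctionCall:
    """Classify one junction against same-strand overlapping transcripts.

    A junction overlapping several transcripts is assigned to the one with
    the most matching boundaries; ties are broken by smallest span, then by
    transcript id (deterministic and order-independent).
    """
    # widen by 1 bp so a junction whose boundary touches a span boundary
    # (e.g. an alt-5' junction ending exactly at the annotated start) still
    # finds the transcript
    query = GenomicInterval(j.chrom, max(0, j.donor_end - 1), j.acceptor_start + 1)
    candidates = ann.overlapping(query, strand=j.strand)
    if not candidates:
        return JunctionCall(j, None, None, "novel_unclassified")
    # canonical anywhere wins outright
    for t in candidates:
        kind, _ = _classify_against(j, t, tol)
        if kind == "canonical":
            return JunctionCall(j, t.gene_id, t.transcript_id, "canonical")
    best = min(
        candidates,
        key=lambda t: (
            -_n_matching_boundaries(j, t, tol),
            len(t.span),
            t.transcript_id,
        ),
    )
    kind, skipped = _classify_against(j, best, tol)
    return JunctionCall(j, best.gene_id, best.transcript_id, kind, skipped)


def call_alternative_junctions(
    junctions: Iterable[JunctionTag],
    ann: AnnotationSet,
    min_candidate: int = 2,
    min_report: int = 5,
    tol: int = 0,
) -> list[JunctionCall]:
    """Non-canonical junction calls above the candidate threshold.

    Junctions supported by at least ``min_candidate`` tags (default 2) are
    retained as candidates; those with at least ``min_report`` tags (default
    5) carry the reportable flag. Output sorted by gene then coordinate.
    """
    calls = []
    for j in junctions:
        call = classify_junction(j, ann, tol)
        if call.kind == "canonical":
            continue
        if j.tag_count < min_candidate:
            continue
        calls.append(
            JunctionCall(
                call.junction,
                call.gene_id,
                call.transcript_id,
                call.kind,
                call.skipped_exons,
                reportable=j.tag_count >= min_report,
            )
        )
    calls.sort(
        key=lambda c: (c.gene_id or "~", c.junction.chrom, c.junction.donor_end, c.junction.acceptor_start)
    )
    return calls


def call_alternative_5prime(
    junctions: Iterable[JunctionTag],
    ann: AnnotationSet,
    min_tags: int = 10,
    tol: int = 0,
) -> list[JunctionCall]:
    """Alt-5'-exon calls: junctions whose 5'-most boundary (transcript
    orientation) lies upstream of the assigned model's annotated start,
    supported by at least ``min_tags`` tags (default 10)."""
    out = []
    for j in junctions:
        if j.tag_count < min_tags:
            continue
        call = classify_junction(j, ann, tol)
        if call.kind == "alt_5prime":
            out.append(
                JunctionCall(
                    call.junction, call.gene_id, call.transcript_id,
                    call.kind, call.skipped_exons, reportable=True,
                )
            )
    out.sort(key=lambda c: (c.gene_id or "~", c.junction.chrom, c.junction.donor_end))
    return out


@dataclass(frozen=True)
class RetainedIntronEvent:
    gene_id: str
    transcript_id: str
    intron: GenomicInterval
    intron_number: int  # 1-based, transcript orientation
    mean_rpkm: float


def detect_retained_introns(
    cov: StrandedCoverage,
    ann: AnnotationSet,
    gene_rpkms: dict[str, float],
    params: UtrScanParams = UtrScanParams(),
) -> list[RetainedIntronEvent]:
    """Retained introns: contiguous same-strand coverage across an annotated
    intron at >= f of the gene's RPKM, using the same window grain as the
    3'UTR scan (every window of the intron must be expressed)."""
    events = []
    for t in ann:
        g_rpkm = gene_rpkms.get(t.gene_id, 0.0)
        if g_rpkm < params.min_gene_rpkm:
            continue
        introns = t.introns()
        for gi, intron in enumerate(introns):
            ok = True
            total = 0
            pos = intron.start
            while pos < intron.end:
                w_end = min(pos + params.w, intron.end)
                iv = GenomicInterval(t.chrom, pos, w_end, t.strand)
                c = cov.count_in(iv)
                total += c
                if rpkm(c, len(iv), cov.library_total_tags) < params.f * g_rpkm:
                    ok = False
                    break
                pos = w_end
            if ok:
                number = gi + 1 if t.strand == "+" else len(introns) - gi
                events.append(
                    RetainedIntronEvent(
                        t.gene_id,
                        t.transcript_id,
                        intron,
                        number,
                        rpkm(total, len(intron), cov.library_total_tags),
                    )
                )
    events.sort(key=lambda e: (e.gene_id, e.intron.chrom, e.intron.start))
    return events
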