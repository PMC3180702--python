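"""Core genomic data model: intervals, transcript models, stranded coverage.

All coordinates throughout the package are 0-based, half-open (BED dialect).
"Downstream" of a minus-strand transcript means decreasing genomic
coordinates: every scan is expressed in transcript orientation and then
mapped back to genome space, so plus and minus strands are handled
symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")
BIOTYPES = ("coding", "noncoding")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a chromosome.

    ``strand`` is "+", "-" or "." (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def opposite_strand(strand: str) -> str:
    if strand == "+":
        return "-"
    if strand == "-":
        return "+"
    return "."


@dataclass
class TranscriptModel:
    """An annotated transcript: exon structure on one strand of one chromosome.

    Invariants: exons are sorted by start, pairwise disjoint, on the span's
    chromosome and strand; the first exon starts at the span start and the
    last exon ends at the span end.
    """

    transcript_id: str
    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval]
    cds: Optional[GenomicInterval] = None
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"biotype must be one of {BIOTYPES}")
        if self.span.strand not in ("+", "-"):
            raise ValidationError("transcript span must be stranded (+/-)")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >= 1 exon")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValidationError(
                    f"{self.transcript_id}: exon {ex} not on span chrom/strand"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons not sorted/disjoint at {ex}"
                )
            prev_end = ex.end
        if self.exons[0].start != self.span.start or self.exons[-1].end != self.span.end:
            raise ValidationError(
                f"{self.transcript_id}: exons do not tile span boundaries"
            )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_length(self) -> int:
        """Total exonic length in bp (the L of the RPKM formula)."""
        return sum(len(e) for e in self.exons)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' terminus (transcript orientation)."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the annotated 3' end."""
        return self.span.end if self.strand == "+" else self.span.start

    def exons_in_order(self) -> list[GenomicInterval]:
        """Exons in transcript (5'->3') order; exon 1 is the 5'-most."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> list[GenomicInterval]:
        """Introns in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class JunctionTag:
    """A donor-acceptor pair with supporting tag count.

    ``donor_end`` and ``acceptor_start`` are stored in genomic order
    (donor_end < acceptor_start) regardless of strand; for minus-strand
    transcripts the biological splice donor is the genomic-right boundary.
    """

    chrom: str
    strand: str
    donor_end: int
    acceptor_start: int
    tag_count: int

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValidationError(
                f"junction boundaries out of order: {self.donor_end} >= {self.acceptor_start}"
            )
        if self.tag_count < 1:
            raise ValidationError(f"tag_count must be >= 1, got {self.tag_count}")
        if self.strand not in ("+", "-"):
            raise ValidationError("junction strand must be + or -")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.donor_end, self.acceptor_start, self.strand)


class AnnotationSet:
    """A collection of TranscriptModel with strand-aware interval lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._transcripts: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self._trees.setdefault(t.chrom, IntervalTree()).addi(
            t.span.start, t.span.end, t.transcript_id
        )

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(sorted(self._transcripts.values(),
                           key=lambda t: (t.chrom, t.span.start, t.transcript_id)))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    def gene_ids(self) -> list[str]:
        return sorted({t.gene_id for t in self._transcripts.values()})

    def by_gene(self) -> dict[str, list[TranscriptModel]]:
        out: dict[str, list[TranscriptModel]] = {}
        for t in self:
            out.setdefault(t.gene_id, []).append(t)
        return out

    def overlapping(
        self,
        interval: GenomicInterval,
        strand: Optional[str] = None,
    ) -> list[TranscriptModel]:
        """Transcripts whose span intersects ``interval``.

        ``strand`` filters to the given strand when "+" or "-"; None (or ".")
        returns both strands. Results sorted by (start, transcript_id).
        """
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [self._transcripts[iv.data] for iv in tree.overlap(interval.start, interval.end)]
        if strand in ("+", "-"):
            hits = [t for t in hits if t.strand == strand]
        return sorted(hits, key=lambda t: (t.span.start, t.transcript_id))


class StrandedCoverage:
    """Per-chromosome, per-strand dense vectors of tag-start counts.

    ``library_total_tags`` is N, the total mapped tags of the library used in
    RPKM normalization; the sum of all stored counts never exceeds it.
    """

    def __init__(
        self,
        chrom_lengths: dict[str, int],
        library_total_tags: int,
    ) -> None:
        if library_total_tags <= 0:
            raise ValidationError("library_total_tags N must be positive")
        self.chrom_lengths = dict(chrom_lengths)
        self.library_total_tags = int(library_total_tags)
        self._arrays: dict[tuple[str, str], np.ndarray] = {}

    def _key(self, chrom: str, strand: str) -> tuple[str, str]:
        if strand not in ("+", "-"):
            raise ValidationError("coverage strand must be + or -")
        if chrom not in self.chrom_lengths:
            raise KeyError(f"chromosome {chrom!r} absent from coverage")
        return (chrom, strand)

    def counts(self, chrom: str, strand: str) -> np.ndarray:
        key = self._key(chrom, strand)
        arr = self._arrays.get(key)
        if arr is None:
            arr = np.zeros(self.chrom_lengths[chrom], dtype=np.int64)
            self._arrays[key] = arr
        return arr

    def add(self, chrom: str, strand: str, start: int, values: np.ndarray) -> None:
        arr = self.counts(chrom, strand)
        values = np.asarray(values, dtype=np.int64)
        if np.any(values < 0):
            raise ValidationError("tag-start counts must be non-negative")
        arr[start : start + len(values)] += values

    def total_tags_stored(self) -> int:
        return int(sum(int(a.sum()) for a in self._arrays.values()))

    def validate(self) -> None:
        if self.total_tags_stored() > self.library_total_tags:
            raise ValidationError(
                "stored tag starts exceed library_total_tags N"
            )

    def count_in(self, interval: GenomicInterval, strand: Optional[str] = None) -> int:
        """Sum of tag starts at positions in [start, end) on one strand."""
        s = strand if strand is not None else interval.strand
        arr = self.counts(interval.chrom, s)
        lo = max(0, interval.start)
        hi = min(len(arr), interval.end)
        if hi <= lo:
            return 0
        return int(arr[lo:hi].sum())

    def count_exons(self, model: TranscriptModel, strand: Optional[str] = None) -> int:
        s = strand if strand is not None else model.strand
        return sum(self.count_in(e, strand=s) for e in model.exons)

    def covered_runs(
        self, chrom: str, strand: str, start: int, end: int, max_gap: int = 0
    ) -> list[tuple[int, int]]:
        """Maximal runs of covered positions in [start, end).

        Runs separated by a gap of <= ``max_gap`` zero positions are merged.
        """
        arr = self.counts(chrom, strand)
        lo, hi = max(0, start), min(len(arr), end)
        if hi <= lo:
            return []
        nz = np.flatnonzero(arr[lo:hi] > 0) + lo
        if nz.size == 0:
            return []
        runs: list[tuple[int, int]] = []
        run_start = int(nz[0])
        prev = int(nz[0])
        for p in nz[1:]:
            p = int(p)
            if p - prev - 1 > max_gap:
                runs.append((run_start, prev + 1))
                run_start = p
            prev = p
        runs.append((run_start, prev + 1))
        return runs
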