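"""Readers and writers for the standard formats the pipeline touches.

BED12 and bedGraph are 0-based half-open and map directly onto the internal
convention; GTF is 1-based inclusive and is converted on read and write.
Parsers raise :class:`ParseError` naming the offending line number so that
malformed annotation files fail loudly rather than silently shifting
coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome import (
    AnnotationSet,
    GenomicInterval,
    JunctionTag,
    StrandedCoverage,
    TranscriptModel,
    ValidationError,
)


class ParseError(ValueError):
    """A malformed input line; message names the file and line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


# ---------------------------------------------------------------------------
# transcript models


def read_models(path, format: str = "bed12") -> AnnotationSet:
    """Read transcript models from BED12 or GTF into an AnnotationSet."""
    if format == "bed12":
        return _read_bed12(path)
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_bed12(path) -> AnnotationSet:
    ann = AnnotationSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = _split(line)
            if len(f) < 12:
                raise ParseError(path, lineno, f"expected 12 BED fields, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                thick_start, thick_end = int(f[6]), int(f[7])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as e:
                raise ParseError(path, lineno, f"malformed BED12 fields: {e}") from e
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(path, lineno, "blockCount disagrees with block lists")
            exons = []
            try:
                for off, size in zip(offsets, sizes):
                    exons.append(GenomicInterval(chrom, start + off, start + off + size, strand))
                gene_id = name.rsplit("|", 1)[1] if "|" in name else name
                tid = name.rsplit("|", 1)[0] if "|" in name else name
                cds = None
                if thick_end > thick_start:
                    cds = GenomicInterval(chrom, thick_start, thick_end, strand)
                biotype = "coding" if cds is not None else "noncoding"
                model = TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    span=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    cds=cds,
                    biotype=biotype,
                )
            except ValidationError as e:
                raise ParseError(path, lineno, f"invalid transcript model: {e}") from e
            ann.add(model)
    return ann


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf(path) -> AnnotationSet:
    # collect exon and CDS records per transcript, then assemble
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    biotypes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _split(line)
            if len(f) < 9:
                raise ParseError(path, lineno, f"expected 9 GTF fields, got {len(f)}")
            chrom, _source, feature, start1, end1, _score, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(start1) - 1  # GTF is 1-based inclusive
                end = int(end1)
            except ValueError as e:
                raise ParseError(path, lineno, f"malformed coordinates: {e}") from e
            attrs = dict(_GTF_ATTR.findall(f[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(path, lineno, "missing transcript_id attribute")
            genes[tid] = attrs.get("gene_id", tid)
            if "transcript_biotype" in attrs:
                biotypes[tid] = (
                    "coding" if attrs["transcript_biotype"] in ("protein_coding", "coding")
                    else "noncoding"
                )
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValidationError as e:
                raise ParseError(path, lineno, str(e)) from e
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)
    ann = AnnotationSet()
    for tid in sorted(exons):
        ex = sorted(exons[tid], key=lambda e: e.start)
        chrom, strand = ex[0].chrom, ex[0].strand
        span = GenomicInterval(chrom, ex[0].start, ex[-1].end, strand)
        c = None
        if tid in cds:
            cd = sorted(cds[tid], key=lambda e: e.start)
            c = GenomicInterval(chrom, cd[0].start, cd[-1].end, strand)
        biotype = biotypes.get(tid, "coding" if c is not None else "noncoding")
        try:
            ann.add(TranscriptModel(tid, genes[tid], span, ex, cds=c, biotype=biotype))
        except ValidationError as e:
            raise ParseError(path, 0, f"transcript {tid}: {e}") from e
    return ann


def write_models_bed12(ann: AnnotationSet, path) -> None:
    """Write transcript models as BED12 (name = transcript_id|gene_id)."""
    with open(path, "w") as fh:
        for t in ann:
            sizes = ",".join(str(len(e)) for e in t.exons)
            offsets = ",".join(str(e.start - t.span.start) for e in t.exons)
            thick = (t.cds.start, t.cds.end) if t.cds else (t.span.start, t.span.start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.chrom, t.span.start, t.span.end,
                        f"{t.transcript_id}|{t.gene_id}", 0, t.strand,
                        thick[0], thick[1], 0,
                        t.n_exons, sizes, offsets,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# stranded bedGraph coverage


def _read_bedgraph_into(cov: StrandedCoverage, path, strand: str) -> None:
    last_end: dict[str, int] = {}
    records: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = _split(line)
            if len(f) < 4:
                raise ParseError(path, lineno, f"expected 4 bedGraph fields, got {len(f)}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            value = int(float(f[3]))
            if value < 0:
                raise ParseError(path, lineno, f"negative coverage value {value}")
            if end <= start:
                raise ParseError(path, lineno, "empty or inverted interval")
            if start < last_end.get(chrom, 0):
                raise ParseError(path, lineno, "overlapping or unsorted bedGraph records")
            last_end[chrom] = end
            records.append((chrom, start, end, value))
    # size chromosomes once, then fill
    for chrom, end in last_end.items():
        old_len = cov.chrom_lengths.get(chrom, 0)
        if end > old_len:
            cov.chrom_lengths[chrom] = end
            for s in ("+", "-"):
                arr = cov._arrays.pop((chrom, s), None)
                if arr is not None:
                    new = np.zeros(end, dtype=np.int64)
                    new[: len(arr)] = arr
                    cov._arrays[(chrom, s)] = new
    for chrom, start, end, value in records:
        cov.counts(chrom, strand)[start:end] = value


def read_coverage(
    path_plus,
    path_minus,
    library_total_tags: Optional[int] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> StrandedCoverage:
    """Read per-strand tag-start bedGraph files into StrandedCoverage.

    When ``library_total_tags`` (N) is not given it is set to the total number
    of tag starts present in the two files.
    """
    cov = StrandedCoverage(chrom_lengths or {}, library_total_tags or 1)
    _read_bedgraph_into(cov, path_plus, "+")
    _read_bedgraph_into(cov, path_minus, "-")
    if library_total_tags is None:
        cov.library_total_tags = max(1, cov.total_tags_stored())
    cov.validate()
    return cov


def _runs(arr: np.ndarray) -> Iterable[tuple[int, int, int]]:
    """Maximal runs of equal nonzero value as (start, end, value)."""
    if len(arr) == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(arr)]))
    for s, e in zip(starts, ends):
        v = int(arr[s])
        if v != 0:
            yield int(s), int(e), v


def write_coverage(cov: StrandedCoverage, path_plus, path_minus) -> None:
    """Write per-strand bedGraph with maximal runs of equal value; zero runs omitted."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            for chrom in sorted(cov.chrom_lengths):
                arr = cov._arrays.get((chrom, strand))
                if arr is None:
                    continue
                for s, e, v in _runs(arr):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


# ---------------------------------------------------------------------------
# junction tags


def read_junctions(path) -> list[JunctionTag]:
    """Read junction tags from BED-like records.

    Columns: chrom, donor_end, acceptor_start, name, tag_count, strand.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            f = _split(line)
            if len(f) < 6:
                raise ParseError(path, lineno, f"expected 6 junction fields, got {len(f)}")
            try:
                j = JunctionTag(
                    chrom=f[0],
                    donor_end=int(f[1]),
                    acceptor_start=int(f[2]),
                    tag_count=int(f[4]),
                    strand=f[5],
                )
            except (ValueError, ValidationError) as e:
                raise ParseError(path, lineno, f"invalid junction record: {e}") from e
            out.append(j)
    return out


def write_junctions(junctions: Sequence[JunctionTag], path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(
            sorted(junctions, key=lambda j: (j.chrom, j.donor_end, j.acceptor_start, j.strand))
        ):
            fh.write(
                f"{j.chrom}\t{j.donor_end}\t{j.acceptor_start}\tjxn{i}\t{j.tag_count}\t{j.strand}\n"
            )


# ---------------------------------------------------------------------------
# generic BED tracks


def write_track(
    records: Iterable[tuple[GenomicInterval, str, float]],
    path,
    track_name: str = "txcomplexity",
    append: bool = False,
) -> None:
    """Write labeled scored intervals as a BED6 custom track.

    ``records`` are (interval, name, score); output is deterministically
    ordered by (chrom, start, name) under a ``track`` header line.
    """
    rows = sorted(records, key=lambda r: (r[0].chrom, r[0].start, r[1]))
    with open(path, "a" if append else "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for iv, name, score in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")
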