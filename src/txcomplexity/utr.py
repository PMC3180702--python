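"""Sliding-window detection of expression extending beyond annotated 3' ends.

The scan tiles non-overlapping windows of ``w`` bp (default 30) downstream of
a transcript's annotated 3' end, out to a radius of ``R`` bp (default 20 kb),
in transcript orientation. A window is "expressed" when its window RPKM is at
least a fraction ``f`` (default 0.5) of the gene's RPKM. An extension is
called when the run of consecutive expressed windows anchored at the 3' end
has at least ``k`` windows (default 10) and spans strictly more than ``m`` bp
(default 500); with the defaults both conditions bind and a call needs a run
of at least 17 windows (17 x 30 = 510 > 500).

Windows overlapping any other annotated transcript — coding or noncoding, on
either strand — are masked, and a masked window terminates the anchored run
(configurable to be skipped instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome import AnnotationSet, GenomicInterval, StrandedCoverage, TranscriptModel
from .quantify import rpkm


@dataclass(frozen=True)
class UtrScanParams:
    """Tunable parameters of the extended-3'UTR scan.

    w: window size in bp; R: scan radius in bp; f: required window-signal
    fraction of the gene's RPKM; k: minimum consecutive expressed windows;
    m: minimum extension length in bp (strict); min_gene_rpkm: genes below
    this RPKM are not scanned; step: tiling step (defaults to w, i.e.
    non-overlapping windows); mask_policy: what a masked window does to the
    anchored run ("terminate" or "skip"); mask_same_strand_only: restrict
    masking to same-strand transcripts; mode: compare per-window RPKM
    ("window", default) or the whole-extension RPKM ("extension") against
    f x gene RPKM.
    """

    w: int = 30
    R: int = 20_000
    f: float = 0.5
    k: int = 10
    m: int = 500
    min_gene_rpkm: float = 1.0
    step: Optional[int] = None
    mask_policy: str = "terminate"
    mask_same_strand_only: bool = False
    mode: str = "window"

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("window size w must be positive")
        if self.R < self.w:
            raise ValueError("scan radius R must be >= w")
        if not (0 < self.f <= 1):
            raise ValueError("signal fraction f must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.mask_policy not in ("terminate", "skip"):
            raise ValueError("mask_policy must be 'terminate' or 'skip'")
        if self.mode not in ("window", "extension"):
            raise ValueError("mode must be 'window' or 'extension'")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else self.w


@dataclass(frozen=True)
class Window:
    """One scan window: genomic interval, tag-start count, masked flag."""

    interval: GenomicInterval
    count: int
    masked: bool


@dataclass(frozen=True)
class UtrExtensionCall:
    """A called 3'UTR extension abutting the annotated 3' end."""

    gene_id: str
    transcript_id: str
    extension: GenomicInterval
    extension_length: int
    run_length: int
    n_expressed_windows: int
    masked_windows: int
    previously_annotated: Optional[bool] = None


def scan_downstream_windows(
    cov: StrandedCoverage,
    model: TranscriptModel,
    ann: AnnotationSet,
    params: UtrScanParams = UtrScanParams(),
) -> list[Window]:
    """Tile windows downstream of the 3' end in transcript orientation.

    Counts same-strand tag starts per window; windows intersecting any other
    annotated transcript span are flagged masked. The scan truncates at the
    chromosome edge.
    """
    w, step = params.w, params.effective_step
    n_windows = params.R // step
    chrom_len = cov.chrom_lengths[model.chrom]
    windows: list[Window] = []
    for i in range(n_windows):
        if model.strand == "+":
            start = model.three_prime + i * step
            end = start + w
            if end > chrom_len:
                break
        else:
            end = model.three_prime - i * step
            start = end - w
            if start < 0:
                break
        iv = GenomicInterval(model.chrom, start, end, model.strand)
        count = cov.count_in(iv)
        mask_strand = model.strand if params.mask_same_strand_only else None
        others = [
            t
            for t in ann.overlapping(GenomicInterval(model.chrom, start, end), strand=mask_strand)
            if t.transcript_id != model.transcript_id
        ]
        windows.append(Window(iv, count, masked=bool(others)))
    return windows


def call_extension(
    windows: list[Window],
    gene_rpkm: float,
    N: int,
    params: UtrScanParams = UtrScanParams(),
    gene_id: str = "",
    transcript_id: str = "",
    strand: str = "+",
) -> Optional[UtrExtensionCall]:
    """Apply the three extension criteria to a downstream window vector.

    (a) signal at or above ``f`` x gene RPKM, (b) at least ``k`` consecutive
    expressed windows anchored at the 3' end, (c) extension strictly longer
    than ``m`` bp. Returns the call, or None when any criterion fails.
    """
    if not windows:
        return None

    def expressed(win: Window) -> bool:
        return rpkm(win.count, len(win.interval), N) >= params.f * gene_rpkm

    run = 0
    for win in windows:
        if win.masked:
            if params.mask_policy == "terminate":
                break
            continue
        if expressed(win):
            run += 1
        else:
            break

    n_expressed = sum(1 for win in windows if not win.masked and expressed(win))
    n_masked = sum(1 for win in windows if win.masked)
    if run < params.k:
        return None
    extension_length = run * params.w
    if extension_length <= params.m:
        return None
    if params.mode == "extension":
        total = sum(win.count for win in windows[:run])
        if rpkm(total, extension_length, N) < params.f * gene_rpkm:
            return None
    first = windows[0].interval
    if strand == "+":
        ext = GenomicInterval(first.chrom, first.start, first.start + extension_length, strand)
    else:
        ext = GenomicInterval(first.chrom, first.end - extension_length, first.end, strand)
    return UtrExtensionCall(
        gene_id=gene_id,
        transcript_id=transcript_id,
        extension=ext,
        extension_length=extension_length,
        run_length=run,
        n_expressed_windows=n_expressed,
        masked_windows=n_masked,
    )


def annotate_known_extension(
    call: UtrExtensionCall, known: Optional[AnnotationSet]
) -> UtrExtensionCall:
    """Flag a call previously annotated when a same-strand known model covers it."""
    annotated = False
    if known is not None:
        for t in known.overlapping(call.extension, strand=call.extension.strand):
            if t.span.contains(call.extension):
                annotated = True
                break
    return UtrExtensionCall(
        gene_id=call.gene_id,
        transcript_id=call.transcript_id,
        extension=call.extension,
        extension_length=call.extension_length,
        run_length=call.run_length,
        n_expressed_windows=call.n_expressed_windows,
        masked_windows=call.masked_windows,
        previously_annotated=annotated,
    )


def detect_extensions(
    cov: StrandedCoverage,
    ann: AnnotationSet,
    gene_rpkms: dict[str, float],
    params: UtrScanParams = UtrScanParams(),
    known: Optional[AnnotationSet] = None,
) -> list[UtrExtensionCall]:
    """Scan every sufficiently expressed transcript for a 3'UTR extension.

    One call at most per gene: among a gene's transcripts the call from the
    transcript with the 3'-most annotated end is kept.
    """
    calls: dict[str, UtrExtensionCall] = {}
    for t in ann:
        g_rpkm = gene_rpkms.get(t.gene_id, 0.0)
        if g_rpkm < params.min_gene_rpkm:
            continue
        windows = scan_downstream_windows(cov, t, ann, params)
        call = call_extension(
            windows,
            g_rpkm,
            cov.library_total_tags,
            params,
            gene_id=t.gene_id,
            transcript_id=t.transcript_id,
            strand=t.strand,
        )
        if call is None:
            continue
        call = annotate_known_extension(call, known)
        prev = calls.get(t.gene_id)
        if prev is None or call.extension_length > prev.extension_length:
            calls[t.gene_id] = call
    return [calls[g] for g in sorted(calls)]
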