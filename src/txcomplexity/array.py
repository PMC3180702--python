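"""Microarray probeset integration: genome anchoring, heatmap tracks,
concordance and probeset-feature intersection.

Probeset placements (consensus-sequence alignment footprints) are accepted
as input; a probeset whose consensus sequence ties at several genomic
locations keeps every tied placement. The per-subcompartment heatmap is
encoded as one BED score track per compartment (scores scaled 0-1000 within
each probeset row), which is browser-loadable and diffable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, ValidationError


@dataclass
class ProbeSet:
    """A probeset anchored to the genome by one or more placements."""

    probeset_id: str
    placements: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValidationError(f"{self.probeset_id}: needs >= 1 placement")


@dataclass
class CompartmentMatrix:
    """Probeset-by-subcompartment intensity table (columns in fixed order)."""

    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValidationError("duplicate probeset row ids")
        if (self.intensities.to_numpy() < 0).any():
            raise ValidationError("intensities must be non-negative")

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.intensities.columns)

    @property
    def probeset_ids(self) -> tuple[str, ...]:
        return tuple(self.intensities.index)


@dataclass(frozen=True)
class ConcordanceResult:
    id_pair: tuple[str, str]
    r: Optional[float]
    n: int


def load_probesets(
    placements_path, matrix_path
) -> tuple[list[ProbeSet], CompartmentMatrix, list[str]]:
    """Load probeset placements (BED) and an intensity matrix (TSV).

    Returns (probesets, matrix, unplaced_ids); matrix rows without any
    placement are logged with a warning and excluded from genomic operations
    but kept in the matrix. Duplicate (probeset, placement) records raise.
    """
    placements: dict[str, list[GenomicInterval]] = {}
    seen: set[tuple] = set()
    with open(placements_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "."
            key = (name, chrom, start, end, strand)
            if key in seen:
                raise ValidationError(
                    f"{placements_path}:{lineno}: duplicate placement for {name}"
                )
            seen.add(key)
            placements.setdefault(name, []).append(
                GenomicInterval(chrom, start, end, strand)
            )
    matrix = CompartmentMatrix(pd.read_csv(matrix_path, sep="\t", index_col=0))
    probesets = [
        ProbeSet(pid, placements[pid]) for pid in matrix.probeset_ids if pid in placements
    ]
    unplaced = [pid for pid in matrix.probeset_ids if pid not in placements]
    if unplaced:
        warnings.warn(
            f"{len(unplaced)} probeset(s) in matrix without placement: excluded "
            "from genomic operations",
            stacklevel=2,
        )
    return probesets, matrix, unplaced


def place_by_substring(
    probeset_sequences: dict[str, str], genome: dict[str, str]
) -> list[ProbeSet]:
    """Exact-substring placement helper for synthetic genomes.

    All occurrences (both strands) are reported, mirroring the tied
    multi-mapping rule for real consensus alignments.
    """
    comp = str.maketrans("ACGT", "TGCA")
    out = []
    for pid, seq in sorted(probeset_sequences.items()):
        placements = []
        rc = seq.translate(comp)[::-1]
        for chrom, ref in genome.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                start = ref.find(query)
                while start != -1:
                    placements.append(
                        GenomicInterval(chrom, start, start + len(query), strand)
                    )
                    start = ref.find(query, start + 1)
        if placements:
            out.append(ProbeSet(pid, placements))
    return out


def emit_heatmap_track(
    probesets: Sequence[ProbeSet], matrix: CompartmentMatrix, out_path
) -> None:
    """Per-compartment BED score tracks at each placement.

    Scores are scaled 0-1000 within each probeset row (row maximum maps to
    1000; an all-zero row scores 0 everywhere); compartments are emitted as
    separate track blocks in the fixed column order of the matrix.
    """
    with open(out_path, "w") as fh:
        for comp in matrix.compartments:
            fh.write(f'track name="{comp}" useScore=1\n')
            rows = []
            for ps in probesets:
                if ps.probeset_id not in matrix.intensities.index:
                    continue
                row = matrix.intensities.loc[ps.probeset_id]
                row_max = float(row.max())
                score = 0 if row_max == 0 else int(round(1000 * float(row[comp]) / row_max))
                for iv in ps.placements:
                    rows.append((iv.chrom, iv.start, iv.end, ps.probeset_id, score, iv.strand))
            rows.sort(key=lambda r: (r[0], r[1], r[3]))
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")


def concordance(
    x: Sequence[float],
    y: Sequence[float],
    id_pair: tuple[str, str] = ("x", "y"),
) -> ConcordanceResult:
    """Pearson product-moment correlation of two equal-length intensity vectors.

    Zero variance in either vector makes r undefined; it is reported as None.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    if denom == 0:
        return ConcordanceResult(id_pair, None, n)
    return ConcordanceResult(id_pair, float((xd * yd).sum() / denom), n)


@dataclass(frozen=True)
class OverlapRecord:
    probeset_id: str
    placement: GenomicInterval
    feature_id: str
    feature: GenomicInterval
    overlap_bp: int
    relative_position: str  # inside-gene / downstream-of-3prime / over-mirna


_FEATURE_POSITION = {
    "utr_extension": "downstream-of-3prime",
    "mirna": "over-mirna",
}


def probeset_feature_overlap(
    probesets: Sequence[ProbeSet],
    features: Iterable[tuple[str, str, GenomicInterval]],
) -> list[OverlapRecord]:
    """Intersect probeset placements with labeled feature intervals.

    ``features`` are (feature_id, feature_kind, interval) triples; the
    relative position label derives from the feature kind (3'UTR extension
    calls map to downstream-of-3prime, embedded miRNAs to over-mirna,
    anything else to inside-gene).
    """
    out = []
    feats = list(features)
    for ps in probesets:
        for iv in ps.placements:
            for fid, kind, fiv in feats:
                bp = iv.intersection_length(fiv)
                if bp > 0:
                    out.append(
                        OverlapRecord(
                            ps.probeset_id, iv, fid, fiv, bp,
                            _FEATURE_POSITION.get(kind, "inside-gene"),
                        )
                    )
    out.sort(key=lambda r: (r.probeset_id, r.placement.start, r.feature_id))
    return out
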