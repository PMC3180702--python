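"""Small-RNA tag counting against pre-miRNA hairpins and pri-miRNA association.

Tags are adapter-stripped (longest tag suffix matching a prefix of the
adapter, minimum 6 bases) and matched against each hairpin in nucleotide
space with up to ``max_mismatch`` substitutions (U and T are identical). A
hit inside a hairpin's annotated mature interval increments that mature's
count; a tag tying across several hairpins contributes fractional weight
1/ties to each, so total fractional counts equal the number of matched tags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome import GenomicInterval, TranscriptModel
from .quantify import ExpressionRecord


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA hairpin with annotated mature interval(s) (0-based, half-open)."""

    hairpin_id: str
    sequence: str
    matures: tuple[tuple[str, int, int], ...]  # (mature_id, start, end)


@dataclass
class MirnaCount:
    mature_id: str
    hairpin_id: str
    tag_count: float = 0.0


@dataclass(frozen=True)
class PriMirna:
    """An intergenic noncoding primary transcript hosting mature miRNAs."""

    host: TranscriptModel
    embedded: tuple[tuple[str, GenomicInterval], ...]

    def __post_init__(self) -> None:
        for mid, iv in self.embedded:
            if not self.host.span.contains(iv):
                raise ValueError(f"embedded miRNA {mid} outside host span")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def strip_adapter(tag: str, adapter: str, min_overlap: int = 6) -> str:
    """Remove the longest tag suffix equal to a prefix of the adapter (>= 6 nt)."""
    tag_n = _normalize(tag)
    ad = _normalize(adapter)
    best = 0
    upper = min(len(tag_n), len(ad))
    for k in range(min_overlap, upper + 1):
        if tag_n.endswith(ad[:k]):
            best = k
    return tag_n[: len(tag_n) - best] if best else tag_n


def _best_alignment(
    tag: str, hairpin_seq: str, max_mismatch: int
) -> Optional[tuple[int, int]]:
    """Best (mismatches, offset) of ``tag`` within ``hairpin_seq`` by
    substitution-only alignment at every offset; None if nothing is within
    the mismatch budget."""
    L, H = len(tag), len(hairpin_seq)
    if L == 0 or L > H:
        return None
    best: Optional[tuple[int, int]] = None
    for off in range(H - L + 1):
        mm = 0
        window = hairpin_seq[off : off + L]
        for a, b in zip(tag, window):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            if best is None or mm < best[0]:
                best = (mm, off)
                if mm == 0:
                    break
    return best


def count_small_rna_tags(
    tags: Sequence[str],
    hairpins: Sequence[Hairpin],
    adapter: str,
    max_mismatch: int = 2,
    mature_slop: int = 4,
) -> list[MirnaCount]:
    """Adapter-strip and count tags against hairpin mature intervals.

    The alignment must lie within the annotated mature interval padded by
    ``mature_slop`` nt on each side (isomiR tolerance). Tags tying across
    hairpins at the minimum mismatch count are split fractionally; counting
    is order-independent over tags.
    """
    counts: dict[tuple[str, str], MirnaCount] = {}
    for hp in hairpins:
        for mid, _a, _b in hp.matures:
            counts[(mid, hp.hairpin_id)] = MirnaCount(mid, hp.hairpin_id, 0.0)
    norm_hp = [(hp, _normalize(hp.sequence)) for hp in hairpins]
    for tag in tags:
        trimmed = strip_adapter(tag, adapter)
        if not trimmed:
            warnings.warn("tag empty after adapter stripping; skipped", stacklevel=2)
            continue
        hits: list[tuple[int, str, str]] = []  # (mismatches, mature_id, hairpin_id)
        for hp, seq in norm_hp:
            aln = _best_alignment(trimmed, seq, max_mismatch)
            if aln is None:
                continue
            mm, off = aln
            end = off + len(trimmed)
            for mid, a, b in hp.matures:
                if a - mature_slop <= off and end <= b + mature_slop:
                    hits.append((mm, mid, hp.hairpin_id))
                    break
        if not hits:
            continue
        best_mm = min(h[0] for h in hits)
        winners = [h for h in hits if h[0] == best_mm]
        w = 1.0 / len(winners)
        for _mm, mid, hid in winners:
            counts[(mid, hid)].tag_count += w
    return sorted(counts.values(), key=lambda c: (c.mature_id, c.hairpin_id))


def expressed_mirnas(
    counts: Iterable[MirnaCount], min_tags: float = 100
) -> list[MirnaCount]:
    """Matures with strictly more than ``min_tags`` mapped tags (default > 100)."""
    return [c for c in counts if c.tag_count > min_tags]


@dataclass(frozen=True)
class PriMirnaAssociation:
    mature_id: str
    host_id: str
    host_rpkm: float


def associate_pri_mirna(
    expressed: Iterable[str],
    pris: Sequence[PriMirna],
    mrna_expr: Iterable[ExpressionRecord],
    min_host_rpkm: float = 1.0,
) -> list[PriMirnaAssociation]:
    """Join expressed matures to intergenic pri-miRNA hosts that are
    themselves expressed in the mRNA data (host RPKM >= min_host_rpkm)."""
    expr = {r.gene_id: r.rpkm for r in mrna_expr}
    expressed_set = set(expressed)
    out = []
    for pri in pris:
        host_rpkm = expr.get(pri.host.gene_id, 0.0)
        if host_rpkm < min_host_rpkm:
            continue
        for mid, _iv in pri.embedded:
            if mid in expressed_set:
                out.append(PriMirnaAssociation(mid, pri.host.gene_id, host_rpkm))
    out.sort(key=lambda a: (a.mature_id, a.host_id))
    return out


# ---------------------------------------------------------------------------
# FASTA / BED plumbing


def read_hairpins(fasta_path, mature_bed_path) -> list[Hairpin]:
    """Hairpin FASTA plus a BED of mature intervals (chrom = hairpin id)."""
    from Bio import SeqIO

    matures: dict[str, list[tuple[str, int, int]]] = {}
    with open(mature_bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            matures.setdefault(f[0], []).append((f[3], int(f[1]), int(f[2])))
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(Hairpin(rec.id, str(rec.seq), tuple(matures.get(rec.id, ()))))
    return out


def read_tags(path) -> list[str]:
    """Small-RNA tags from FASTA or one-sequence-per-line text."""
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO

        return [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
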