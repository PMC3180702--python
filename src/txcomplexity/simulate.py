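"""Synthetic stranded RNA-seq data with planted, machine-readable ground truth.

The generator emulates the study conditions of a deep stranded tag-start
library over an embryonic-kidney-like annotation: per-base tag-start counts
are drawn independently from a Poisson law with rate
``lambda = target_RPKM x N / 1e9`` over each transcript's exonic bases, with
``N`` defaulting to 136,122,785 mapped tags and gene targets drawn from
10-50 RPKM (the range in which most active loci sit). Planted features —
3'UTR extensions contiguous from the annotated 3' end, antisense partner
transcripts of each overlap orientation, alternative junctions of every
event class, alt-5' junctions and compartment marker probesets — are
recorded in a TruthTable so that every caller can be scored against known
ground truth.

A single master seed derives per-stage substreams, so simulation is
deterministic end to end. A "none" noise mode replaces the Poisson draw with
a largest-remainder integerization of the expected per-base rate, for exact
noise-free recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .array import CompartmentMatrix, ProbeSet
from .genome import (
    AnnotationSet,
    GenomicInterval,
    JunctionTag,
    StrandedCoverage,
    TranscriptModel,
    opposite_strand,
)

#: The eleven profiled kidney subcompartments, in fixed heatmap order.
COMPARTMENTS = (
    "ureteric tip",
    "s-shaped body",
    "proximal tubule",
    "cortical interstitium",
    "medullary interstitium",
    "medullary collecting duct",
    "cortical collecting duct",
    "renal corpuscle",
    "cap mesenchyme",
    "loop of Henle",
    "renal vesicle",
)

ORIENTATIONS = ("head_to_head", "tail_to_tail", "embedded", "full_span")
JUNCTION_KINDS = ("exon_skip", "alt_donor", "alt_acceptor", "cassette_exon")


class ConfigurationError(ValueError):
    """Simulation request that cannot be satisfied (placement, geometry...)."""


@dataclass(frozen=True)
class PlantedUtrExtension:
    gene: str
    extension_length: int
    signal_fraction: float = 1.0


@dataclass(frozen=True)
class PlantedAntisense:
    gene: str
    orientation: str
    target_rpkm: float

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ConfigurationError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )


@dataclass(frozen=True)
class PlantedJunction:
    gene: str
    kind: str
    tag_count: int
    n_skip: int = 1

    def __post_init__(self) -> None:
        if self.kind not in JUNCTION_KINDS:
            raise ConfigurationError(f"unknown junction kind {self.kind!r}")


@dataclass(frozen=True)
class PlantedAlt5Prime:
    gene: str
    upstream_offset: int
    tag_count: int


@dataclass(frozen=True)
class PlantedMarker:
    gene: str
    compartment: str
    target_rpkm: float


@dataclass
class PlantedFeatureSpec:
    utr_extensions: list[PlantedUtrExtension] = field(default_factory=list)
    antisense: list[PlantedAntisense] = field(default_factory=list)
    alt_junctions: list[PlantedJunction] = field(default_factory=list)
    alt_5prime: list[PlantedAlt5Prime] = field(default_factory=list)
    compartment_markers: list[PlantedMarker] = field(default_factory=list)

    def referenced_genes(self) -> set[str]:
        return (
            {p.gene for p in self.utr_extensions}
            | {p.gene for p in self.antisense}
            | {p.gene for p in self.alt_junctions}
            | {p.gene for p in self.alt_5prime}
            | {p.gene for p in self.compartment_markers}
        )


@dataclass
class SimulationConfig:
    genome: list[tuple[str, int]] = field(default_factory=lambda: [("chr1", 4_000_000)])
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    exon_count_range: tuple[int, int] = (4, 8)
    target_rpkm_range: tuple[float, float] = (10.0, 50.0)
    library_total_tags: int = 136_122_785
    seed: int = 0
    noise: str = "poisson"  # "poisson" or "none"
    background: float = 0.0  # per-base rate outside any feature
    intergenic_clearance: int = 25_000
    planted: PlantedFeatureSpec = field(default_factory=PlantedFeatureSpec)

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.library_total_tags <= 0:
            raise ConfigurationError("n_genes must be >= 0 and N > 0")
        for lo, hi in (self.gene_length_range, self.exon_count_range, self.target_rpkm_range):
            if hi < lo:
                raise ConfigurationError("empty range in configuration")
        if self.noise not in ("poisson", "none"):
            raise ConfigurationError("noise must be 'poisson' or 'none'")

    def rng(self, stage: int) -> np.random.Generator:
        # one master seed; per-stage substreams
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass(frozen=True)
class TruthRecord:
    feature_kind: str
    gene_id: str
    footprint: GenomicInterval
    attrs: tuple[tuple[str, object], ...]

    def attr(self, key: str):
        return dict(self.attrs)[key]


@dataclass
class TruthTable:
    records: list[TruthRecord]
    gene_targets: dict[str, float]
    library_total_tags: int
    compartments: tuple[str, ...] = COMPARTMENTS

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.feature_kind == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "feature_kind": r.feature_kind,
                    "gene_id": r.gene_id,
                    "chrom": r.footprint.chrom,
                    "start": r.footprint.start,
                    "end": r.footprint.end,
                    "strand": r.footprint.strand,
                    "attrs": ";".join(f"{k}={v}" for k, v in r.attrs),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["feature_kind", "gene_id", "chrom", "start", "end", "strand", "attrs"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation


def _allocate(total: int, weights: np.ndarray, minimum: int) -> list[int]:
    """Integer partition of ``total`` proportional to weights, each >= minimum."""
    k = len(weights)
    if total < k * minimum:
        raise ConfigurationError("segment too short to partition")
    spare = total - k * minimum
    raw = spare * weights / weights.sum()
    parts = np.floor(raw).astype(int)
    rem = spare - parts.sum()
    order = np.argsort(raw - parts)[::-1]
    for i in range(rem):
        parts[order[i % k]] += 1
    return [int(p) + minimum for p in parts]


def _make_exons(
    rng: np.random.Generator, chrom: str, start: int, span_len: int, n_exons: int, strand: str
) -> list[GenomicInterval]:
    if n_exons == 1:
        return [GenomicInterval(chrom, start, start + span_len, strand)]
    exonic_total = max(n_exons * 60, int(span_len * 0.4))
    intronic_total = span_len - exonic_total
    exon_lens = _allocate(exonic_total, rng.uniform(0.5, 1.5, n_exons), 60)
    intron_lens = _allocate(intronic_total, rng.uniform(0.5, 1.5, n_exons - 1), 80)
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_lens[i], strand))
        pos += exon_lens[i]
        if i < n_exons - 1:
            pos += intron_lens[i]
    return exons


def _required_exons(planted: PlantedFeatureSpec) -> dict[str, int]:
    req: dict[str, int] = {}
    for pj in planted.alt_junctions:
        need = pj.n_skip + 2 if pj.kind == "exon_skip" else 2
        req[pj.gene] = max(req.get(pj.gene, 0), need)
    return req


def _plan_junction(
    pj: PlantedJunction, t: TranscriptModel
) -> tuple[int, int, tuple[int, ...]]:
    """Genomic (donor_end, acceptor_start) and expected skipped exon numbers."""
    n = t.n_exons
    ex = t.exons  # genomic order
    if pj.kind == "exon_skip":
        j = 2 + pj.n_skip  # transcript index of acceptor exon
        if n < j:
            raise ConfigurationError(
                f"{pj.gene}: exon_skip of {pj.n_skip} needs >= {j} exons, has {n}"
            )
        if t.strand == "+":
            L, R = ex[0].end, ex[j - 1].start
        else:
            L, R = ex[n - j].end, ex[n - 1].start
        return L, R, tuple(range(2, j))
    if n < 2:
        raise ConfigurationError(f"{pj.gene}: {pj.kind} needs >= 2 exons")
    intron0 = (ex[0].end, ex[1].start) if t.strand == "+" else (ex[n - 2].end, ex[n - 1].start)
    a, b = intron0
    if pj.kind == "alt_donor":
        return ((a + 12, b, ()) if t.strand == "+" else (a, b - 12, ()))
    if pj.kind == "alt_acceptor":
        return ((a, b - 15, ()) if t.strand == "+" else (a + 15, b, ()))
    if pj.kind == "cassette_exon":
        third = max(16, (b - a) // 3)
        L, R = a + third, b - third
        if L >= R:
            L, R = a + 1, b - 1
        return L, R, ()
    raise ConfigurationError(f"unknown junction kind {pj.kind!r}")


def simulate_annotation(config: SimulationConfig) -> tuple[AnnotationSet, TruthTable]:
    """Place gene models and planted features; deterministic given the seed."""
    rng = config.rng(0)
    ann = AnnotationSet()
    truth_records: list[TruthRecord] = []
    gene_targets: dict[str, float] = {}

    req_exons = _required_exons(config.planted)
    lo_e, hi_e = config.exon_count_range
    for g, need in req_exons.items():
        if need > hi_e:
            raise ConfigurationError(
                f"gene {g} needs {need} exons but exon_count_range max is {hi_e}"
            )

    clearance = config.intergenic_clearance
    chrom_iter = iter(config.genome)
    try:
        chrom, chrom_len = next(chrom_iter)
    except StopIteration:
        raise ConfigurationError("empty genome") from None
    cursor = clearance
    models: dict[str, TranscriptModel] = {}
    for i in range(config.n_genes):
        gene = f"g{i:03d}"
        span_len = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        while cursor + span_len + clearance > chrom_len:
            try:
                chrom, chrom_len = next(chrom_iter)
            except StopIteration:
                raise ConfigurationError(
                    f"genome too small to place {config.n_genes} genes with "
                    f"{clearance} bp clearance"
                ) from None
            cursor = clearance
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(max(lo_e, req_exons.get(gene, lo_e)), hi_e + 1))
        exons = _make_exons(rng, chrom, cursor, span_len, n_exons, strand)
        span = GenomicInterval(chrom, cursor, cursor + span_len, strand)
        model = TranscriptModel(
            transcript_id=f"{gene}.t1", gene_id=gene, span=span, exons=exons,
            cds=span, biotype="coding",
        )
        ann.add(model)
        models[gene] = model
        gene_targets[gene] = float(rng.uniform(*config.target_rpkm_range))
        cursor += span_len + clearance

    missing = config.planted.referenced_genes() - set(models)
    if missing:
        raise ConfigurationError(f"planted features reference unknown genes: {sorted(missing)}")

    # planted 3'UTR extensions: contiguous from the annotated 3' end
    for p in config.planted.utr_extensions:
        m = models[p.gene]
        if m.strand == "+":
            fp = GenomicInterval(m.chrom, m.three_prime, m.three_prime + p.extension_length, "+")
        else:
            fp = GenomicInterval(m.chrom, m.three_prime - p.extension_length, m.three_prime, "-")
        truth_records.append(
            TruthRecord(
                "utr_extension", p.gene, fp,
                (("extension_length", p.extension_length),
                 ("signal_fraction", p.signal_fraction)),
            )
        )

    # planted antisense partners: distinct noncoding models on the opposite strand
    for p in config.planted.antisense:
        m = models[p.gene]
        s = m.span
        ext_out = int(rng.integers(800, 2_001))
        ov = int(rng.integers(max(200, len(s) // 4), max(300, len(s) // 2)))
        if p.orientation == "head_to_head":
            a, b = (s.start - ext_out, s.start + ov) if m.strand == "+" else (s.end - ov, s.end + ext_out)
        elif p.orientation == "tail_to_tail":
            a, b = (s.end - ov, s.end + ext_out) if m.strand == "+" else (s.start - ext_out, s.start + ov)
        elif p.orientation == "embedded":
            d = max(150, len(s) // 5)
            a, b = s.start + d, s.end - d
        else:  # full_span
            a, b = s.start - ext_out, s.end + ext_out
        opp = opposite_strand(m.strand)
        partner_gene = f"{p.gene}_as"
        span = GenomicInterval(m.chrom, a, b, opp)
        partner = TranscriptModel(
            transcript_id=f"{partner_gene}.t1", gene_id=partner_gene,
            span=span, exons=[span], biotype="noncoding",
        )
        ann.add(partner)
        gene_targets[partner_gene] = float(p.target_rpkm)
        truth_records.append(
            TruthRecord(
                "antisense", p.gene, span,
                (("orientation", p.orientation), ("target_rpkm", p.target_rpkm),
                 ("partner_gene", partner_gene)),
            )
        )

    # planted alternative junctions: geometry planned here, emitted by simulate_junctions
    for pj in config.planted.alt_junctions:
        m = models[pj.gene]
        L, R, skipped = _plan_junction(pj, m)
        truth_records.append(
            TruthRecord(
                "alt_junction", pj.gene,
                GenomicInterval(m.chrom, L, R, m.strand),
                (("kind", pj.kind), ("tag_count", pj.tag_count),
                 ("skipped_exons", ",".join(map(str, skipped)))),
            )
        )
    for p5 in config.planted.alt_5prime:
        m = models[p5.gene]
        if m.strand == "+":
            L, R = m.span.start - p5.upstream_offset, m.span.start
        else:
            L, R = m.span.end, m.span.end + p5.upstream_offset
        truth_records.append(
            TruthRecord(
                "alt_5prime", p5.gene,
                GenomicInterval(m.chrom, L, R, m.strand),
                (("upstream_offset", p5.upstream_offset), ("tag_count", p5.tag_count)),
            )
        )

    for pm in config.planted.compartment_markers:
        if pm.compartment not in COMPARTMENTS:
            raise ConfigurationError(f"unknown compartment {pm.compartment!r}")
        m = models[pm.gene]
        gene_targets[pm.gene] = float(pm.target_rpkm)
        truth_records.append(
            TruthRecord(
                "compartment_marker", pm.gene, m.span,
                (("compartment", pm.compartment), ("target_rpkm", pm.target_rpkm)),
            )
        )

    truth = TruthTable(
        records=truth_records,
        gene_targets=gene_targets,
        library_total_tags=config.library_total_tags,
    )
    return ann, truth


# ---------------------------------------------------------------------------
# coverage


def _deterministic_counts(lam: float, size: int, phase: float = 0.0) -> np.ndarray:
    """Largest-remainder integerization of a constant per-base rate."""
    idx = np.arange(size + 1, dtype=float) + phase
    cum = np.floor(idx * lam)
    return np.diff(cum).astype(np.int64)


def simulate_coverage(
    models: AnnotationSet, truth: TruthTable, config: SimulationConfig
) -> StrandedCoverage:
    """Per-base Poisson tag-start coverage over exonic bases plus planted
    extension signal; positions outside any feature stay at the background
    rate (default 0)."""
    rng = config.rng(1)
    N = config.library_total_tags
    cov = StrandedCoverage(dict(config.genome), N)

    def draw(lam: float, size: int) -> np.ndarray:
        if lam <= 0 or size <= 0:
            return np.zeros(size, dtype=np.int64)
        if config.noise == "poisson":
            return rng.poisson(lam, size).astype(np.int64)
        return _deterministic_counts(lam, size)

    for t in models:
        target = truth.gene_targets.get(t.gene_id)
        if target is None:
            continue
        lam = target * N / 1e9
        for e in t.exons:
            cov.add(t.chrom, t.strand, e.start, draw(lam, len(e)))

    for r in truth.of_kind("utr_extension"):
        lam = truth.gene_targets[r.gene_id] * N / 1e9 * float(r.attr("signal_fraction"))
        fp = r.footprint
        cov.add(fp.chrom, fp.strand, fp.start, draw(lam, len(fp)))

    if config.background > 0:
        for chrom, length in config.genome:
            for strand in ("+", "-"):
                cov.add(chrom, strand, 0, draw(config.background, length))

    cov.validate()
    return cov


# ---------------------------------------------------------------------------
# junctions


def simulate_junctions(
    models: AnnotationSet, truth: TruthTable, junction_read_span: int = 30
) -> list[JunctionTag]:
    """Canonical junctions with counts proportional to expression, plus
    planted alternative junctions at their specified tag counts."""
    N = truth.library_total_tags
    by_key: dict[tuple[str, str, int, int], int] = {}
    for t in models:
        target = truth.gene_targets.get(t.gene_id, 0.0)
        count = max(1, int(round(target * N / 1e9 * junction_read_span)))
        for a, b in zip(t.exons, t.exons[1:]):
            key = (t.chrom, t.strand, a.end, b.start)
            by_key[key] = max(by_key.get(key, 0), count)
    out = [
        JunctionTag(chrom, strand, L, R, c)
        for (chrom, strand, L, R), c in by_key.items()
    ]
    for r in truth.of_kind("alt_junction") + truth.of_kind("alt_5prime"):
        fp = r.footprint
        out.append(
            JunctionTag(fp.chrom, fp.strand, fp.start, fp.end, int(r.attr("tag_count")))
        )
    out.sort(key=lambda j: (j.chrom, j.donor_end, j.acceptor_start, j.strand))
    return out


# ---------------------------------------------------------------------------
# probesets


def simulate_probeset_matrix(
    models: AnnotationSet,
    truth: TruthTable,
    compartments: Optional[Sequence[str]] = None,
    config: Optional[SimulationConfig] = None,
) -> tuple[list[ProbeSet], CompartmentMatrix]:
    """One probeset footprint per gene near its 3' end; log-normal intensities
    around compartment means, elevated for planted compartment markers."""
    comps = tuple(compartments) if compartments is not None else COMPARTMENTS
    rng = (config.rng(3) if config is not None else np.random.default_rng(3))
    markers = {
        r.gene_id: r.attr("compartment") for r in truth.of_kind("compartment_marker")
    }
    unknown = set(markers.values()) - set(comps)
    if unknown:
        raise ConfigurationError(f"unknown compartment name(s) in markers: {sorted(unknown)}")
    probesets: list[ProbeSet] = []
    rows = {}
    for t in models:
        if t.gene_id.endswith("_as"):
            continue  # antisense partners are not on the array
        ex3 = t.exons_in_order()[-1]  # 3'-most exon
        size = min(300, len(ex3))
        if t.strand == "+":
            fp = GenomicInterval(t.chrom, ex3.end - size, ex3.end, t.strand)
        else:
            fp = GenomicInterval(t.chrom, ex3.start, ex3.start + size, t.strand)
        ps_id = f"ps_{t.gene_id}"
        probesets.append(ProbeSet(ps_id, [fp]))
        base = 50.0 + 5.0 * truth.gene_targets.get(t.gene_id, 1.0)
        row = base * rng.lognormal(mean=0.0, sigma=0.3, size=len(comps))
        if t.gene_id in markers:
            row[comps.index(markers[t.gene_id])] *= 20.0
        rows[ps_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(comps))
    frame = frame.sort_index()
    return probesets, CompartmentMatrix(frame)


# ---------------------------------------------------------------------------
# small RNA


def emit_bundle(config: SimulationConfig, outdir) -> dict:
    """Simulate a complete input bundle and write it in the formats the
    pipeline reads (BED12 models, per-strand bedGraph, junction BED, probeset
    BED + TSV matrix, miRNA FASTA, truth TSV, and a ready run-all config)."""
    from . import io as aio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann, truth = simulate_annotation(config)
    cov = simulate_coverage(ann, truth, config)
    junctions = simulate_junctions(ann, truth)
    probesets, matrix = simulate_probeset_matrix(ann, truth, config=config)

    aio.write_models_bed12(ann, outdir / "models.bed")
    aio.write_coverage(cov, outdir / "coverage_plus.bedGraph", outdir / "coverage_minus.bedGraph")
    aio.write_junctions(junctions, outdir / "junctions.bed")
    with open(outdir / "probesets.bed", "w") as fh:
        for ps in probesets:
            for iv in ps.placements:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ps.probeset_id}\t0\t{iv.strand}\n")
    matrix.intensities.round(4).to_csv(outdir / "probeset_matrix.tsv", sep="\t")
    truth.write(outdir / "truth.tsv")

    tags, hairpins = simulate_small_rna(seed=config.seed)
    with open(outdir / "mirna_tags.fa", "w") as fh:
        for i, t in enumerate(tags):
            fh.write(f">tag{i}\n{t}\n")
    with open(outdir / "hairpins.fa", "w") as fh, open(outdir / "mature.bed", "w") as bh:
        for hid, seq, matures in hairpins:
            fh.write(f">{hid}\n{seq}\n")
            for mid, a, b in matures:
                bh.write(f"{hid}\t{a}\t{b}\t{mid}\t0\t+\n")

    run_config = {
        "inputs": {
            "models": "models.bed",
            "models_format": "bed12",
            "coverage_plus": "coverage_plus.bedGraph",
            "coverage_minus": "coverage_minus.bedGraph",
            "junctions": "junctions.bed",
            "library_total_tags": config.library_total_tags,
            "probeset_placements": "probesets.bed",
            "probeset_matrix": "probeset_matrix.tsv",
            "mirna_tags": "mirna_tags.fa",
            "hairpins": "hairpins.fa",
            "mature_bed": "mature.bed",
        },
        "outdir": "out",
        "seed": int(config.seed),
        "params": {},
    }
    import yaml

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    return {
        "annotation": ann,
        "truth": truth,
        "coverage": cov,
        "junctions": junctions,
        "probesets": probesets,
        "matrix": matrix,
    }


def demo_config(seed: int = 0) -> SimulationConfig:
    """The packaged demo: a small genome exercising every planted feature class."""
    planted = PlantedFeatureSpec(
        utr_extensions=[
            PlantedUtrExtension("g000", 1500, 1.0),
            PlantedUtrExtension("g001", 900, 1.0),
            PlantedUtrExtension("g002", 3000, 1.0),
        ],
        antisense=[
            PlantedAntisense("g004", "head_to_head", 30.0),
            PlantedAntisense("g005", "tail_to_tail", 30.0),
            PlantedAntisense("g006", "embedded", 40.0),
            PlantedAntisense("g007", "full_span", 30.0),
        ],
        alt_junctions=[
            PlantedJunction("g008", "exon_skip", 350, n_skip=1),
            PlantedJunction("g009", "exon_skip", 10, n_skip=2),
            PlantedJunction("g010", "alt_donor", 83),
            PlantedJunction("g011", "alt_acceptor", 13),
            PlantedJunction("g012", "cassette_exon", 13),
        ],
        alt_5prime=[PlantedAlt5Prime("g013", 10_000, 10)],
        compartment_markers=[
            PlantedMarker("g014", "cap mesenchyme", 25.0),
            PlantedMarker("g015", "renal vesicle", 16.0),
        ],
    )
    return SimulationConfig(
        genome=[("chr1", 1_200_000)],
        n_genes=20,
        seed=seed,
        planted=planted,
    )


BASES = np.array(list("ACGT"))


def simulate_small_rna(
    n_mirnas: int = 5,
    counts: Optional[Sequence[int]] = None,
    adapter: str = "CTGTAGGCACCATCAAT",
    seed: int = 0,
    hairpin_length: int = 70,
    mature_span: tuple[int, int] = (20, 42),
):
    """Random hairpins with one annotated mature interval each, and tags that
    read the mature sequence followed by adapter bases.

    Returns (tags, hairpins) where hairpins are (hairpin_id, sequence,
    [(mature_id, start, end)]) triples and tags are plain sequences.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 4])
    if counts is None:
        counts = [150] * n_mirnas
    hairpins = []
    tags: list[str] = []
    for i in range(n_mirnas):
        seq = "".join(rng.choice(BASES, hairpin_length))
        hid, mid = f"hp{i}", f"miR-{i}"
        a, b = mature_span
        hairpins.append((hid, seq, [(mid, a, b)]))
        mature = seq[a:b]
        for _ in range(int(counts[i])):
            n_adapter = int(rng.integers(6, min(12, len(adapter)) + 1))
            tags.append(mature + adapter[:n_adapter])
    return tags, hairpins
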