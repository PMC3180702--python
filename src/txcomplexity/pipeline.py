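"""Pipeline orchestration and the per-gene transcriptional-complexity report.

``run_all`` chains quantification, 3'UTR-extension scanning, junction
classification, antisense detection, probeset integration and miRNA
association over one configuration, writing TSV/BED outputs plus a run log
that records the resolved parameter set and input checksums. Outputs are
deterministically ordered and carry no timestamps, so two runs on identical
inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as aio
from .antisense import detect_antisense, flag_known_nat
from .genome import AnnotationSet, GenomicInterval
from .mirna import (
    PriMirna,
    associate_pri_mirna,
    count_small_rna_tags,
    expressed_mirnas,
    read_hairpins,
    read_tags,
)
from .quantify import expressed_loci, gene_expression_table
from .splicing import (
    call_alternative_5prime,
    call_alternative_junctions,
    detect_retained_introns,
)
from .utr import UtrScanParams, detect_extensions


class PipelineError(RuntimeError):
    """A stage failure; message names the stage and cause."""


@dataclass
class PipelineConfig:
    models: Path
    coverage_plus: Path
    coverage_minus: Path
    outdir: Path
    junctions: Optional[Path] = None
    models_format: str = "bed12"
    library_total_tags: Optional[int] = None
    probeset_placements: Optional[Path] = None
    probeset_matrix: Optional[Path] = None
    mirna_tags: Optional[Path] = None
    hairpins: Optional[Path] = None
    mature_bed: Optional[Path] = None
    pri_mirna_bed: Optional[Path] = None
    known_nat: Optional[Path] = None
    known_models: Optional[Path] = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        inputs = raw.get("inputs", {})
        kwargs = {}
        for key in (
            "models", "coverage_plus", "coverage_minus", "junctions",
            "probeset_placements", "probeset_matrix", "mirna_tags",
            "hairpins", "mature_bed", "pri_mirna_bed", "known_nat", "known_models",
        ):
            if inputs.get(key) is not None:
                kwargs[key] = base / inputs[key]
        if "models_format" in inputs:
            kwargs["models_format"] = inputs["models_format"]
        if inputs.get("library_total_tags") is not None:
            kwargs["library_total_tags"] = int(inputs["library_total_tags"])
        outdir = raw.get("outdir", "out")
        return cls(
            outdir=base / outdir,
            seed=int(raw.get("seed", 0)),
            params=raw.get("params", {}),
            **kwargs,
        )

    def validate(self) -> None:
        for name in (
            "models", "coverage_plus", "coverage_minus", "junctions",
            "probeset_placements", "probeset_matrix", "mirna_tags",
            "hairpins", "mature_bed", "pri_mirna_bed", "known_nat", "known_models",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: missing input file for {name!r}: {p}")

    def utr_params(self) -> UtrScanParams:
        return UtrScanParams(**self.params.get("utr", {}))


@dataclass(frozen=True)
class ComplexityReportRow:
    gene_id: str
    has_alt_splicing: bool
    has_alt_5prime: bool
    has_extended_3utr: bool
    has_antisense: bool
    supporting_calls: tuple[str, ...]


def complexity_report(genes, bundle: dict) -> list[ComplexityReportRow]:
    """One row per requested gene; each flag is backed by >= 1 call record."""
    splice_by_gene: dict[str, list[str]] = {}
    for c in bundle.get("alt_junctions", []):
        if c.gene_id:
            splice_by_gene.setdefault(c.gene_id, []).append(
                f"junction:{c.kind}:{c.junction.donor_end}-{c.junction.acceptor_start}"
            )
    for e in bundle.get("retained_introns", []):
        splice_by_gene.setdefault(e.gene_id, []).append(
            f"retained_intron:{e.intron.start}-{e.intron.end}"
        )
    alt5_by_gene: dict[str, list[str]] = {}
    for c in bundle.get("alt_5prime", []):
        if c.gene_id:
            alt5_by_gene.setdefault(c.gene_id, []).append(
                f"alt5:{c.junction.donor_end}-{c.junction.acceptor_start}"
            )
    utr_by_gene: dict[str, list[str]] = {}
    for u in bundle.get("utr_extensions", []):
        utr_by_gene.setdefault(u.gene_id, []).append(
            f"utr3:{u.extension.start}-{u.extension.end}"
        )
    as_by_gene: dict[str, list[str]] = {}
    for p in bundle.get("antisense", []):
        as_by_gene.setdefault(p.sense_transcript.gene_id, []).append(
            f"antisense:{p.orientation}"
        )
    known = (
        {r.gene_id for r in bundle.get("expression", [])}
        | set(splice_by_gene) | set(alt5_by_gene) | set(utr_by_gene) | set(as_by_gene)
    )
    rows = []
    for g in genes:
        if g not in known:
            warnings.warn(f"unknown gene id {g!r} in complexity report", stacklevel=2)
        supporting = (
            splice_by_gene.get(g, []) + alt5_by_gene.get(g, [])
            + utr_by_gene.get(g, []) + as_by_gene.get(g, [])
        )
        rows.append(
            ComplexityReportRow(
                gene_id=g,
                has_alt_splicing=g in splice_by_gene,
                has_alt_5prime=g in alt5_by_gene,
                has_extended_3utr=g in utr_by_gene,
                has_antisense=g in as_by_gene,
                supporting_calls=tuple(supporting),
            )
        )
    return rows


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_known_nat(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]),
                                       f[5] if len(f) > 5 else "."))
    return out


def _read_pri_mirnas(path, ann: AnnotationSet) -> list[PriMirna]:
    """BED of embedded matures: name field is 'host_gene|mature_id'."""
    embedded: dict[str, list[tuple[str, GenomicInterval]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            f = line.split()
            host, mature = f[3].split("|", 1)
            embedded.setdefault(host, []).append(
                (mature, GenomicInterval(f[0], int(f[1]), int(f[2]),
                                         f[5] if len(f) > 5 else "."))
            )
    pris = []
    by_gene = ann.by_gene()
    for host, matures in sorted(embedded.items()):
        models = by_gene.get(host)
        if not models:
            warnings.warn(f"pri-miRNA host {host!r} absent from annotation", stacklevel=2)
            continue
        host_model = models[0]
        if host_model.biotype != "noncoding":
            continue  # restricted to intergenic noncoding hosts
        pris.append(PriMirna(host_model, tuple(matures)))
    return pris


def run_all(config: PipelineConfig) -> dict:
    """Run every stage over the configured inputs; returns the report bundle.

    Stage order: quantify -> utr -> splice -> antisense -> array -> mirna ->
    report. Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "load"
    try:
        ann = aio.read_models(config.models, format=config.models_format)
        cov = aio.read_coverage(
            config.coverage_plus,
            config.coverage_minus,
            library_total_tags=config.library_total_tags,
        )
        known_models = (
            aio.read_models(config.known_models, format="bed12")
            if config.known_models else None
        )

        stage = "quantify"
        qparams = config.params.get("quantify", {})
        expression = gene_expression_table(cov, ann)
        bundle["expression"] = expression
        active = expressed_loci(expression, threshold=float(qparams.get("min_rpkm", 1.0)))
        bundle["active_loci"] = active
        gene_rpkms = {r.gene_id: r.rpkm for r in expression}
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "transcript_ids": ",".join(r.transcript_ids),
                    "C": r.C,
                    "L_bp": r.L,
                    "RPKM": round(r.rpkm, 6),
                    "biotype": r.biotype,
                }
                for r in expression
            ]
        ).to_csv(outdir / "expression.tsv", sep="\t", index=False)

        stage = "utr"
        uparams = config.utr_params()
        utr_calls = detect_extensions(cov, ann, gene_rpkms, uparams, known=known_models)
        bundle["utr_extensions"] = utr_calls
        pd.DataFrame(
            [
                {
                    "gene_id": u.gene_id,
                    "transcript_id": u.transcript_id,
                    "chrom": u.extension.chrom,
                    "start": u.extension.start,
                    "end": u.extension.end,
                    "strand": u.extension.strand,
                    "extension_length": u.extension_length,
                    "run_length": u.run_length,
                    "n_expressed_windows": u.n_expressed_windows,
                    "masked_windows": u.masked_windows,
                    "previously_annotated": bool(u.previously_annotated),
                }
                for u in utr_calls
            ]
        ).to_csv(outdir / "utr_extensions.tsv", sep="\t", index=False)
        aio.write_track(
            [(u.extension, u.gene_id, u.run_length) for u in utr_calls],
            outdir / "utr_extensions.bed",
            track_name="extended_3utr",
        )

        stage = "splice"
        jparams = config.params.get("junctions", {})
        junctions = aio.read_junctions(config.junctions) if config.junctions else []
        alt_calls = call_alternative_junctions(
            junctions, ann,
            min_candidate=int(jparams.get("min_candidate", 2)),
            min_report=int(jparams.get("min_report", 5)),
        )
        alt5_calls = call_alternative_5prime(
            junctions, ann, min_tags=int(jparams.get("alt5_min_tags", 10))
        )
        retained = detect_retained_introns(cov, ann, gene_rpkms, uparams)
        bundle["alt_junctions"] = alt_calls
        bundle["alt_5prime"] = alt5_calls
        bundle["retained_introns"] = retained
        pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id or "",
                    "kind": c.kind,
                    "chrom": c.junction.chrom,
                    "donor_end": c.junction.donor_end,
                    "acceptor_start": c.junction.acceptor_start,
                    "strand": c.junction.strand,
                    "tag_count": c.junction.tag_count,
                    "skipped_exons": ",".join(map(str, c.skipped_exons)),
                    "reportable": c.reportable,
                }
                for c in alt_calls + alt5_calls
            ]
        ).to_csv(outdir / "junction_calls.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene_id": e.gene_id,
                    "transcript_id": e.transcript_id,
                    "chrom": e.intron.chrom,
                    "start": e.intron.start,
                    "end": e.intron.end,
                    "intron_number": e.intron_number,
                    "mean_rpkm": round(e.mean_rpkm, 6),
                }
                for e in retained
            ]
        ).to_csv(outdir / "retained_introns.tsv", sep="\t", index=False)

        stage = "antisense"
        aparams = config.params.get("antisense", {})
        pairs = detect_antisense(
            cov, ann,
            min_rpkm=float(aparams.get("min_rpkm", 10.0)),
            min_sense_rpkm=float(aparams.get("min_sense_rpkm", 0.0)),
            gap_tolerance=int(aparams.get("gap_tolerance", 30)),
        )
        known_nat = _read_known_nat(config.known_nat) if config.known_nat else None
        pairs = flag_known_nat(pairs, known_nat)
        bundle["antisense"] = pairs
        pd.DataFrame(
            [
                {
                    "sense_transcript": p.sense_transcript.transcript_id,
                    "sense_gene": p.sense_transcript.gene_id,
                    "antisense_rpkm": round(p.antisense_rpkm, 6),
                    "chrom": p.antisense_extent.chrom,
                    "extent_start": p.antisense_extent.start,
                    "extent_end": p.antisense_extent.end,
                    "orientation": p.orientation,
                    "partner": p.partner_model.transcript_id if p.partner_model else "",
                    "known_nat": p.known_nat,
                }
                for p in pairs
            ]
        ).to_csv(outdir / "antisense.tsv", sep="\t", index=False)
        aio.write_track(
            [
                (p.antisense_extent, p.sense_transcript.gene_id, round(p.antisense_rpkm, 3))
                for p in pairs
            ],
            outdir / "antisense_extents.bed",
            track_name="antisense_extents",
        )

        stage = "array"
        if config.probeset_placements and config.probeset_matrix:
            from .array import emit_heatmap_track, load_probesets, probeset_feature_overlap

            probesets, matrix, _unplaced = load_probesets(
                config.probeset_placements, config.probeset_matrix
            )
            bundle["probesets"] = probesets
            bundle["compartment_matrix"] = matrix
            emit_heatmap_track(probesets, matrix, outdir / "heatmap_tracks.bed")
            features = [
                (u.gene_id, "utr_extension", u.extension) for u in utr_calls
            ]
            overlaps = probeset_feature_overlap(probesets, features)
            bundle["probeset_overlaps"] = overlaps
            pd.DataFrame(
                [
                    {
                        "probeset_id": o.probeset_id,
                        "feature_id": o.feature_id,
                        "overlap_bp": o.overlap_bp,
                        "relative_position": o.relative_position,
                    }
                    for o in overlaps
                ]
            ).to_csv(outdir / "probeset_overlaps.tsv", sep="\t", index=False)

        stage = "mirna"
        if config.mirna_tags and config.hairpins and config.mature_bed:
            mparams = config.params.get("mirna", {})
            hairpins = read_hairpins(config.hairpins, config.mature_bed)
            tags = read_tags(config.mirna_tags)
            counts = count_small_rna_tags(
                tags, hairpins,
                adapter=mparams.get("adapter", "CTGTAGGCACCATCAAT"),
                max_mismatch=int(mparams.get("max_mismatch", 2)),
            )
            bundle["mirna_counts"] = counts
            expressed = expressed_mirnas(counts, min_tags=float(mparams.get("min_tags", 100)))
            bundle["expressed_mirnas"] = expressed
            pd.DataFrame(
                [
                    {"mature_id": c.mature_id, "hairpin_id": c.hairpin_id,
                     "tag_count": round(c.tag_count, 3)}
                    for c in counts
                ]
            ).to_csv(outdir / "mirna_counts.tsv", sep="\t", index=False)
            if config.pri_mirna_bed:
                pris = _read_pri_mirnas(config.pri_mirna_bed, ann)
                assoc = associate_pri_mirna(
                    [c.mature_id for c in expressed], pris, expression,
                    min_host_rpkm=float(mparams.get("min_host_rpkm", 1.0)),
                )
                bundle["pri_mirna_associations"] = assoc
                pd.DataFrame(
                    [
                        {"mature_id": a.mature_id, "host_id": a.host_id,
                         "host_rpkm": round(a.host_rpkm, 6)}
                        for a in assoc
                    ]
                ).to_csv(outdir / "pri_mirna_associations.tsv", sep="\t", index=False)

        stage = "report"
        genes = [g for g in ann.gene_ids() if not g.endswith("_as")]
        rows = complexity_report(genes, bundle)
        bundle["complexity_report"] = rows
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "has_alt_splicing": r.has_alt_splicing,
                    "has_alt_5prime": r.has_alt_5prime,
                    "has_extended_3utr": r.has_extended_3utr,
                    "has_antisense": r.has_antisense,
                    "supporting_calls": ";".join(r.supporting_calls),
                }
                for r in rows
            ]
        ).to_csv(outdir / "complexity_report.tsv", sep="\t", index=False)

        stage = "log"
        resolved = {
            "inputs": {
                k: (_md5(getattr(config, k)) if getattr(config, k) else None)
                for k in (
                    "models", "coverage_plus", "coverage_minus", "junctions",
                    "probeset_placements", "probeset_matrix", "mirna_tags",
                    "hairpins", "mature_bed", "pri_mirna_bed", "known_nat",
                    "known_models",
                )
            },
            "library_total_tags": cov.library_total_tags,
            "params": {
                "utr": {
                    "w": uparams.w, "R": uparams.R, "f": uparams.f,
                    "k": uparams.k, "m": uparams.m,
                    "min_gene_rpkm": uparams.min_gene_rpkm,
                    "mask_policy": uparams.mask_policy, "mode": uparams.mode,
                },
                "junctions": {
                    "min_candidate": int(jparams.get("min_candidate", 2)),
                    "min_report": int(jparams.get("min_report", 5)),
                    "alt5_min_tags": int(jparams.get("alt5_min_tags", 10)),
                },
                "antisense": {
                    "min_rpkm": float(aparams.get("min_rpkm", 10.0)),
                    "min_sense_rpkm": float(aparams.get("min_sense_rpkm", 0.0)),
                    "gap_tolerance": int(aparams.get("gap_tolerance", 30)),
                },
                "quantify": {"min_rpkm": float(qparams.get("min_rpkm", 1.0))},
                "mirna": config.params.get("mirna", {}),
            },
            "seed": config.seed,
        }
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(resolved, fh, sort_keys=True)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 — re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {e}") from e
    return bundle
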