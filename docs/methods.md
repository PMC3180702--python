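# Methods

## Data model and coordinate conventions

All coordinates are 0-based, half-open (the BED convention); GTF input
(1-based inclusive) is converted on read. The primary expression signal is
**tag-start coverage**: for each chromosome and strand, a dense vector of
non-negative integers counting the reads whose 5'-most mapped coordinate is
that position. The library size `N` (total mapped tags) travels with the
coverage object and is the normalizer of every RPKM in the package.
"Downstream" of a minus-strand transcript means decreasing genomic
coordinates; every scan is defined in transcript orientation and mapped back
to genome space, so the two strands are treated symmetrically. Transcript
models are exon lists that tile their span; a strand-aware interval index
over spans answers all overlap queries. Chromosome names are taken verbatim
from inputs.

## Quantification

For a gene, `C` is the strand-matched tag-start count inside the union of
its transcripts' exons, `L` the union length in bp, and
`RPKM = C x 10^9 / (N x L)`. Counting is strictly strand-matched; antisense
signal never enters a gene's `C` (it is analysed separately). The
active-locus threshold is inclusive (`>= 1 RPKM`), so a gene at exactly
1 RPKM — around one to two transcripts per cell at this depth — counts as
active. Both gene-level (exon-union) and per-transcript tables are
available. The subcompartment sensitivity report summarizes marker-gene RPKM
per compartment with Tukey hinges (median-of-halves quartiles, the "lower
hinge/upper hinge" convention of classical box plots); a marker without an
expression record counts as undetected, and a compartment without markers
reports a missing fraction rather than a fabricated one.

## Extended 3'UTR scan

Windows of `w = 30` bp tile the region downstream of the annotated 3' end,
non-overlapping (step = `w`, configurable), out to a radius `R = 20,000` bp,
for genes at `>= 1 RPKM`. Windows overlapping any *other* annotated
transcript — coding or noncoding, on either strand — are masked; masking is
strand-agnostic because the exclusion is about annotated transcribed
territory, not same-strand signal (a same-strand-only switch exists). A
window is *expressed* when its window RPKM (`count x 10^9 / (N x w)`) is at
least `f = 0.5` of the gene's RPKM; applying the fraction criterion per
window makes it composable with the run criterion, and a whole-extension
mode is available as an alternative reading. The anchored run is the maximal
block of consecutive expressed windows starting at the first window (gap
tolerance 0); by default a masked window terminates the run (a "skip" policy
is available). A call requires run length `>= k = 10` windows **and** run
span `> m = 500` bp; the criteria are enforced independently, so with the
defaults the binding constraint is a 17-window run (17 x 30 = 510 > 500),
and 16 windows (480 bp) never call. The extension interval abuts the 3' end
and spans the run; a supplied set of longer known models (e.g. orthologous
annotations) flags calls as previously annotated when a same-strand known
span covers the extension.

## Junction classification

Junction tags carry exact donor/acceptor boundaries — they originate from
alignment to a curated junction-sequence library — so boundary matching is
exact (0 bp tolerance, configurable). Boundaries are stored in genomic order
(left boundary < right boundary); on the minus strand the biological donor
is the genomic-right boundary, and the classifier matches directionally.
Classification order per candidate transcript: adjacent exon pair ->
canonical; non-adjacent matched pair -> exon_skip with skipped exon numbers
reported in transcript (5'->3') orientation; upstream boundary beyond the 5'
start -> alt_5prime (tested before donor/acceptor matching so that an
upstream junction landing exactly on the first exon start is a 5' event, not
an alt_donor); one matched boundary -> alt_donor or alt_acceptor; both
boundaries unannotated and inside the same annotated intron -> cassette_exon
(the parsimonious explanation is an unannotated intervening exon — note a
physical cassette-inclusion junction with one annotated boundary classifies
as alt_donor/alt_acceptor, which is the evidence it actually carries);
otherwise novel_unclassified. A junction overlapping several transcripts is
assigned to the same-strand transcript with the most matching boundaries,
ties broken by smaller span then transcript id, which makes classification
deterministic and input-order independent. Thresholds: `>= 2` tags to be a
candidate, `>= 5` to be reportable, and a stricter `>= 10` for alt-5'
events (the 5' end of tag libraries is depleted by 3' bias, so 5' calls need
stronger support). Retained introns have no junction signature; they are
called from coverage instead, by tiling the intron with the same 30 bp
window grain and requiring *every* window at `>= f` of the gene's RPKM.

## Sense–antisense survey

Antisense expression of a transcript is the RPKM computed from
opposite-strand tag starts within its own exon union; pairs are emitted at
`>= 10 RPKM` of antisense signal (the threshold's subject is the antisense
partner; an independent minimum on the sense RPKM is exposed but defaults
off). The antisense extent is the bounding interval of opposite-strand
covered runs intersecting the sense span, after merging runs separated by
`<= 30` bp — tag-start sparsity fragments contiguous transcription, and the
gap matches the window grain used elsewhere. Orientation is classified from
the extent in sense-transcript orientation: beyond both termini ->
full_span; beyond the 5' terminus only -> head_to_head (divergent); beyond
the 3' terminus only -> tail_to_tail (convergent); otherwise embedded.
Deciding orientation from signal extent rather than from partner annotation
means uncharacterized antisense transcription is classifiable; when an
annotated opposite-strand transcript overlaps the extent it is attached as
the partner model. Note that the valid symmetry for this geometry is
reflection *plus* strand swap: relabeling strands alone exchanges 5' and 3'
termini and therefore maps head-to-head onto tail-to-tail.

## Microarray integration

Probeset placements (consensus-sequence alignment footprints) are accepted
as input; probesets whose consensus ties at several locations keep every
tied placement, and matrix rows without placements are excluded from genomic
operations with a warning. The subcompartment heatmap is encoded as one BED
score track per compartment in the fixed column order of the matrix, scores
scaled 0–1000 within each probeset row (rank order is preserved under the
quantization; an all-zero row scores 0). Concordance is the plain Pearson
product-moment correlation with `n >= 3`; zero variance reports a missing
value rather than NaN arithmetic. An exact-substring placement helper is
provided for synthetic genomes; real consensus alignment is out of scope and
its placements are an input. An optional raw-intensity row filter exists for
arrays with a background floor, with no default.

## Small-RNA counting

Tags are matched in nucleotide space (U and T identical). The longest tag
suffix equal to an adapter prefix (minimum 6 nt) is stripped; the trimmed
tag is aligned to each hairpin at every offset allowing substitutions only,
up to 2 mismatches. A hit counts for a mature miRNA when the alignment lies
within the hairpin's annotated mature interval padded by 4 nt per side
(isomiR tolerance). A tag tying across hairpins at its minimum mismatch
count contributes `1/ties` to each, so total fractional counts equal the
number of matched tags (mass conservation) and counting is order
independent. Matures above the strict `> 100` tag cutoff are "expressed";
association joins them to intergenic noncoding pri-miRNA hosts whose own
mRNA RPKM is `>= 1`.

## Synthetic data generator

The generator emulates the study conditions of a deep stranded library:
`N = 136,122,785` mapped tags by default, gene expression targets drawn
uniformly from 10–50 RPKM (the range where most active loci sit), genes of
2–8 kb with 4–8 exons (~40% exonic), placed with 25 kb intergenic clearance
so downstream scan radii stay free of neighboring annotation. Tag starts are
drawn independently per base from a Poisson law with rate
`lambda = RPKM x N / 10^9` over exonic bases; positions outside any feature
stay at a background rate (default 0). Planted features: 3'UTR extensions
are contiguous signal from the annotated 3' end at a chosen fraction of the
host's rate; antisense partners are distinct single-exon noncoding
transcripts on the opposite strand with head-to-head, tail-to-tail, embedded
or full-span geometry; alternative junctions of every class are planned
against the host's exon structure at exact tag counts; one probeset per gene
sits on the 3'-most 300 exonic bp with log-normal intensities (sigma 0.3)
elevated 20x in a marker's compartment, over the eleven kidney
subcompartments in fixed heatmap order. A single master seed derives
per-stage substreams, so the full bundle is byte-reproducible. A "none"
noise mode replaces the Poisson draw with a largest-remainder integerization
of the expected per-base rate, giving exactly recoverable noise-free
datasets for recovery checks.

What the generator does *not* emulate: mapping artifacts and multi-mapping
ambiguity, positional (3') coverage bias, fragment-length effects,
overdispersion beyond Poisson, cross-hybridization on the array side, and
sequencing errors in small-RNA tags. Passing the planted-recovery suite
therefore demonstrates that the callers implement their rules exactly and
are robust to sampling noise at realistic depth — not that they are robust
to alignment artifacts in real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so the full suite
and script each complete in minutes on one CPU: 200 genes for the RPKM
oracle (relative error vs a per-base recount < 1e-9), 100 genes with 30
planted extensions (600–5000 bp) and 30 single-violation decoys for the
3'UTR recovery experiment, 16 planted antisense pairs (4 per orientation at
60 RPKM), a 12-transcript hand-built annotation for junction classes, 1000
random vector pairs for the Pearson oracle (agreement to 1e-12), and the
~20-gene demo bundle for end-to-end determinism. All thresholds sit exactly
at their documented inclusive/exclusive boundaries (>= for window
expression and candidate tags, strict > for extension length and the
100-tag miRNA cutoff), and all randomness flows from explicit seeds.

## Known limitations

- The extension caller reports one call per gene (the longest) and does not
  model alternative polyadenylation quantitatively.
- Cassette-exon evidence from a single junction is indirect (see above);
  full cassette reconstruction would require junction pairing.
- The antisense extent is a single bounding interval; genuinely bimodal
  antisense signal over one sense transcript is summarized, not split.
- The 59.7%-style genome-wide antisense fraction depends on annotation
  completeness and library depth and is not a target of the synthetic
  experiments.
- Junction coordinates in external tables may follow either base convention;
  this package documents its own (0-based half-open, genomic order) and
  makes no attempt to guess foreign conventions.
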