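"""Classify exon-junction tags into alternative-splicing event classes.

Plants one junction of each class on simulated genes, then classifies every
junction tag against the annotation: canonical junctions are recognized and
dropped, the rest are typed (exon_skip with skipped exon numbers, alt donor/
acceptor, cassette, alt 5') and filtered at the 2-tag candidate and 5-tag
reporting thresholds (10 tags for alt-5' events).
"""

from txcomplexity import (
    PlantedAlt5Prime,
    PlantedFeatureSpec,
    PlantedJunction,
    SimulationConfig,
    call_alternative_5prime,
    call_alternative_junctions,
    simulate_annotation,
    simulate_junctions,
)

planted = PlantedFeatureSpec(
    alt_junctions=[
        PlantedJunction("g000", "exon_skip", 350, n_skip=2),  # skips two exons
        PlantedJunction("g001", "alt_donor", 83),
        PlantedJunction("g002", "alt_acceptor", 13),
        PlantedJunction("g003", "cassette_exon", 5),
        PlantedJunction("g004", "exon_skip", 4),  # candidate, below reporting cutoff
    ],
    alt_5prime=[PlantedAlt5Prime("g005", 8_000, 10)],
)
config = SimulationConfig(genome=[("chr1", 700_000)], n_genes=8, seed=3, planted=planted)
ann, truth = simulate_annotation(config)
junctions = simulate_junctions(ann, truth)

calls = call_alternative_junctions(junctions, ann)
print(f"{'gene':<8}{'kind':<16}{'tags':>6}{'skipped':>9}{'reportable':>12}")
for c in calls:
    skipped = ",".join(map(str, c.skipped_exons)) or "-"
    print(f"{c.gene_id:<8}{c.kind:<16}{c.junction.tag_count:>6}{skipped:>9}{str(c.reportable):>12}")

alt5 = call_alternative_5prime(junctions, ann, min_tags=10)
print(f"\nalt-5' calls at the 10-tag cutoff: {[c.gene_id for c in alt5]}")
print(f"total junction tags seen: {len(junctions)} (canonical ones are not reported)")
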