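#!/usr/bin/env python
"""Generate the synthetic study inputs: genome, TE annotation, genes, tags.

Writes the RepeatMasker-dialect TE annotation, the gene table with
expression values, chromosome sizes, and one BED tag library per histone
modification into results/demo/.
"""

from pathlib import Path

from temark import pipeline
from temark.io_formats import write_tags
from temark.simulate import apply_expression_effects, generate_genome, generate_tags

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"
SEED = 1


def main() -> None:
    config = pipeline.demo_config()
    OUT.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config.genome, pipeline._stage_seed(SEED, "genome"))
    genome = apply_expression_effects(genome, config.spec)
    from temark.simulate import write_genome

    write_genome(genome, OUT)
    (OUT / "tags").mkdir(exist_ok=True)
    total = 0
    for mod in config.spec.modifications:
        lib = generate_tags(genome, config.spec, mod, SEED)
        total += lib.total_count
        write_tags(lib, OUT / "tags" / f"{mod}.bed")
    pipeline.save_config(config, OUT / "config.yaml")
    by_family = {}
    for te in genome.te_insertions:
        by_family[te.family] = by_family.get(te.family, 0) + 1
    print(f"simulated {sum(s for _, s in genome.chromosomes):,} bp over "
          f"{len(genome.chromosomes)} chromosomes")
    print(f"TE insertions per family: {by_family}")
    print(f"{len(genome.genes)} genes; {len(config.spec.modifications)} tag libraries, "
          f"{total:,} tags total -> {OUT}")


if __name__ == "__main__":
    main()
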