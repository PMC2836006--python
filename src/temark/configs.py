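"""The bundled demo study conditions.

The demo emulates the structure of the CD4+ T-cell histone-modification
panel at desk scale: 38 modification libraries (28 active, 10 repressive),
six TE family groups, and planted qualitative patterns —

* family-level enrichment increasing with family age (young-to-old
  Alu < L1 < LTR < DNA < L2 < MIR);
* within-family subfamily gradients: Alu densities rising with divergence
  for both classes; L1 active rising and L1 repressive falling with
  divergence;
* a gene-proximity decay of TE tag rates, so elements near genes carry
  more tags;
* promoter marking with expression effects of 3 (active marks) and 1/3
  (repressive marks) on 20% of genes per modification.

Genome size, element counts and tag depths are scaled so a full run
completes in well under two minutes on one CPU while every planted
pattern remains clearly recoverable.
"""

from __future__ import annotations

from .simulate import EnrichmentSpec, GenomeConfig, PromoterMark, SubfamilyConfig

ACTIVE_MODS = [
    "H2AK5ac", "H2AK9ac", "H2BK5ac", "H2BK12ac", "H2BK20ac", "H2BK120ac",
    "H3K4ac", "H3K9ac", "H3K14ac", "H3K18ac", "H3K23ac", "H3K27ac", "H3K36ac",
    "H4K5ac", "H4K8ac", "H4K12ac", "H4K16ac", "H4K91ac",
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9me1", "H3K27me1", "H3K36me3",
    "H3K79me1", "H3K79me2", "H4K20me1", "H2AZ",
]

REPRESSIVE_MODS = [
    "H3K9me2", "H3K9me3", "H3K27me2", "H3K27me3", "H3K79me3",
    "H4K20me3", "H2BK5me1", "H3R2me1", "H3R2me2", "H4R3me2",
]

ALL_MODS = ACTIVE_MODS + REPRESSIVE_MODS

# subfamily: (count, mean_length, mean_divergence); ordered young -> old
_SUBFAMILIES: dict[str, list[tuple[str, int, int, float]]] = {
    "Alu": [("AluYa5", 60, 300, 1.0), ("AluYb8", 60, 300, 3.0), ("AluY", 60, 300, 6.0),
            ("AluSc", 60, 300, 10.0), ("AluSx", 60, 300, 14.0), ("AluJb", 60, 300, 18.0)],
    "L1": [("L1HS", 40, 800, 1.0), ("L1PA3", 40, 800, 4.0), ("L1PA7", 40, 800, 8.0),
           ("L1PA13", 40, 800, 12.0), ("L1MB3", 40, 800, 16.0), ("L1MA5", 40, 800, 20.0)],
    "LTR": [("MLT1A", 90, 500, 10.0), ("MSTA", 90, 500, 16.0)],
    "DNA": [("MER5A", 90, 400, 12.0), ("Tigger1", 90, 400, 18.0)],
    "L2": [("L2a", 120, 350, 15.0), ("L2b", 120, 350, 20.0)],
    "MIR": [("MIRb", 150, 250, 18.0), ("MIR3", 150, 250, 24.0)],
}

#: Family-level log2 fold step per age rank in the demo.
_AGE_LOG2_STEP = 0.3

#: Within-family subfamily multipliers, young -> old (6 subfamilies).
_GRADIENT_UP = [0.60, 0.75, 0.95, 1.20, 1.50, 1.80]


def demo_genome_config() -> GenomeConfig:
    families = {
        fam: {
            name: SubfamilyConfig(count=count, mean_length=length, mean_divergence=div,
                                  length_sd=length * 0.1, divergence_sd=1.0)
            for name, count, length, div in subs
        }
        for fam, subs in _SUBFAMILIES.items()
    }
    return GenomeConfig(
        chromosomes=[("chr1", 4_000_000), ("chr2", 4_000_000)],
        families=families,
        n_genes=600,
        gene_mean_length=5000,
        gene_length_sd=1500.0,
        expression_meanlog=3.0,
        expression_sdlog=1.0,
    )


def demo_enrichment_spec() -> EnrichmentSpec:
    import numpy as np

    from .models import FAMILY_AGE_RANK

    # Modification-to-modification variation of the planted fold within each
    # family (fixed; part of the study conditions).  Without it every
    # modification of a family would share one fold and the across-
    # modification spread of enrichments would be pure sampling noise.
    jitter_rng = np.random.default_rng(20100125)
    jitter = {
        (fam, mod): 2.0 ** jitter_rng.uniform(-0.8, 0.8)
        for fam in FAMILY_AGE_RANK
        for mod in ALL_MODS
    }

    family_fold: dict[tuple[str, str], float] = {}
    subfamily_fold: dict[tuple[str, str], float] = {}
    for fam, rank in FAMILY_AGE_RANK.items():
        base = 2.0 ** (_AGE_LOG2_STEP * (rank - 3.5))
        for mod in ALL_MODS:
            family_fold[(fam, mod)] = base * jitter[(fam, mod)]
    # Within-family gradients for the two abundant families.
    alu_base = 2.0 ** (_AGE_LOG2_STEP * (FAMILY_AGE_RANK["Alu"] - 3.5))
    l1_base = 2.0 ** (_AGE_LOG2_STEP * (FAMILY_AGE_RANK["L1"] - 3.5))
    for i, (name, *_rest) in enumerate(_SUBFAMILIES["Alu"]):
        for mod in ALL_MODS:  # both classes rise with age
            subfamily_fold[(name, mod)] = alu_base * jitter[("Alu", mod)] * _GRADIENT_UP[i]
    for i, (name, *_rest) in enumerate(_SUBFAMILIES["L1"]):
        for mod in ACTIVE_MODS:  # active rises with age
            subfamily_fold[(name, mod)] = l1_base * jitter[("L1", mod)] * _GRADIENT_UP[i]
        for mod in REPRESSIVE_MODS:  # repressive falls with age
            subfamily_fold[(name, mod)] = (
                l1_base * jitter[("L1", mod)] * _GRADIENT_UP[len(_GRADIENT_UP) - 1 - i]
            )
    marks = {}
    for mod in ACTIVE_MODS:
        marks[mod] = PromoterMark(marked_gene_fraction=0.2, promoter_fold=6.0, expression_effect=3.0)
    for mod in REPRESSIVE_MODS:
        marks[mod] = PromoterMark(marked_gene_fraction=0.2, promoter_fold=6.0, expression_effect=1 / 3)
    return EnrichmentSpec(
        modifications=list(ALL_MODS),
        background_rate=0.004,
        nonunique_fraction=0.39,
        family_fold=family_fold,
        subfamily_fold=subfamily_fold,
        promoter_marks=marks,
        gene_proximity={mod: (3.0, 20_000.0) for mod in ALL_MODS},
    )
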