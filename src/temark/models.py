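"""Core domain records: TE insertions, genes, and the genome model.

Coordinates are 0-based half-open throughout.  A :class:`TEInsertion`
carries its repeat family group (one of the six groups analysed:
Alu, L1, LTR, DNA, L2, MIR), its subfamily name, and the percent
divergence of the element from the subfamily consensus — the standard
proxy for the time elapsed since insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The six repeat family groups, ordered young to old by average insertion age.
FAMILIES = ("Alu", "L1", "LTR", "DNA", "L2", "MIR")

#: Age rank per family (1 = youngest).
FAMILY_AGE_RANK = {fam: i + 1 for i, fam in enumerate(FAMILIES)}


@dataclass(frozen=True)
class TEInsertion:
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    subfamily: str
    divergence: float  # percent substitution from subfamily consensus

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty TE interval {self.chrom}:{self.start}-{self.end}")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    tss: int
    strand: str
    start: int
    end: int
    expression: float  # linear-scale expression value

    def __post_init__(self):
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"gene {self.id}: tss {self.tss} outside span [{self.start}, {self.end})")
        if self.expression < 0:
            raise ValueError(f"gene {self.id}: negative expression")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: bad strand {self.strand!r}")


@dataclass
class GenomeModel:
    """A genome annotation bundle: chromosome sizes, TE insertions, genes."""

    chromosomes: list[tuple[str, int]]
    te_insertions: list[TEInsertion] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genome_length(self) -> int:
        return sum(size for _, size in self.chromosomes)

    def validate(self) -> None:
        sizes = self.chrom_sizes
        for te in self.te_insertions:
            if te.chrom not in sizes or not (0 <= te.start < te.end <= sizes[te.chrom]):
                raise ValueError(f"TE outside chromosome bounds: {te}")
        for g in self.genes:
            if g.chrom not in sizes or not (0 <= g.start < g.end <= sizes[g.chrom]):
                raise ValueError(f"gene outside chromosome bounds: {g}")

    def te_frame(self) -> pd.DataFrame:
        """TE insertions as a DataFrame (chrom, start, end, strand, family, subfamily, divergence)."""
        return pd.DataFrame(
            [
                (t.chrom, t.start, t.end, t.strand, t.family, t.subfamily, t.divergence)
                for t in self.te_insertions
            ],
            columns=["chrom", "start", "end", "strand", "family", "subfamily", "divergence"],
        )

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.id, g.chrom, g.tss, g.strand, g.start, g.end, g.expression)
                for g in self.genes
            ],
            columns=["id", "chrom", "tss", "strand", "start", "end", "expression"],
        )
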