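"""Synthetic genomes, TE annotations, genes, and ChIP-Seq tag libraries.

The generator emulates the inputs of the TE histone-modification analysis
at desk scale: chromosomes carrying non-overlapping TE insertions from the
six repeat family groups (with subfamily-structured consensus divergence),
genes with a TSS, strand and log-normal expression, and per-modification
tag libraries drawn as a piecewise-homogeneous Poisson point process.

Planted structure is controlled by :class:`EnrichmentSpec`:

* per (family, modification) — and optionally per subfamily — fold changes
  of the tag rate inside TE intervals;
* promoter marking: a seeded subset of genes is "marked" for each
  modification; tags inside their promoters are boosted by
  ``promoter_fold`` and their expression is shifted multiplicatively by
  ``expression_effect`` (> 1 emulates an active mark, < 1 a repressive
  one);
* optional gene-proximity decay of TE tag rates (for distance-to-gene
  analyses) and explicit regional rate multipliers (for local-background
  scenarios);
* a configurable fraction of tags flagged as non-uniquely mapped.

Because the planted folds and the generating process are known exactly,
every downstream estimate has a ground truth to be checked against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from bisect import bisect_left, insort

import numpy as np
import pandas as pd

from .intervals import distance_to_spans, merge_intervals
from .io_formats import TagLibrary, write_chrom_sizes, write_genes, write_repeatmasker
from .models import Gene, GenomeModel, TEInsertion


def _h(name: str) -> int:
    """Stable 32-bit stream index for a name (used to derive substreams)."""
    return zlib.crc32(name.encode())


def substream(seed: int, *names: str) -> np.random.Generator:
    """Deterministic RNG substream for (seed, names...)."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *(_h(n) for n in names)])


@dataclass(frozen=True)
class SubfamilyConfig:
    count: int
    mean_length: int
    mean_divergence: float
    length_sd: float = 0.0
    divergence_sd: float = 1.0


@dataclass
class GenomeConfig:
    """Parameters of the synthetic genome.

    ``families`` maps family group -> subfamily name -> SubfamilyConfig.
    Gene expression is log-normal on the linear scale
    (``exp(N(meanlog, sdlog))``), mimicking microarray intensity values.
    """

    chromosomes: list[tuple[str, int]]
    families: dict[str, dict[str, SubfamilyConfig]] = field(default_factory=dict)
    n_genes: int = 0
    gene_mean_length: int = 8000
    gene_length_sd: float = 2000.0
    expression_meanlog: float = 3.0
    expression_sdlog: float = 1.0
    promoter_up: int = 1000
    promoter_down: int = 200
    max_place_attempts: int = 200


@dataclass(frozen=True)
class PromoterMark:
    marked_gene_fraction: float
    promoter_fold: float
    expression_effect: float

    def __post_init__(self):
        if not (0 <= self.marked_gene_fraction <= 1):
            raise ValueError("marked_gene_fraction must lie in [0, 1]")
        if self.promoter_fold <= 0 or self.expression_effect <= 0:
            raise ValueError("folds and effects must be positive")


@dataclass(frozen=True)
class RegionBias:
    """A regional multiplicative tag-rate bias (not tied to any feature)."""

    chrom: str
    start: int
    end: int
    fold: float
    modification: str | None = None  # None applies to every library


@dataclass
class EnrichmentSpec:
    """Planted statistical structure for tag generation."""

    modifications: list[str]
    background_rate: float = 0.005  # tags per bp per library
    nonunique_fraction: float = 0.1
    family_fold: dict[tuple[str, str], float] = field(default_factory=dict)  # (family, mod) -> fold
    subfamily_fold: dict[tuple[str, str], float] = field(default_factory=dict)  # (subfamily, mod)
    promoter_marks: dict[str, PromoterMark] = field(default_factory=dict)  # mod -> mark
    gene_proximity: dict[str, tuple[float, float]] = field(default_factory=dict)  # mod -> (max_fold, decay_bp)
    region_bias: list[RegionBias] = field(default_factory=list)
    promoter_up: int = 1000
    promoter_down: int = 200
    mark_seed: int = 0

    def __post_init__(self):
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not (0 <= self.nonunique_fraction <= 1):
            raise ValueError("nonunique_fraction must lie in [0, 1]")
        for table in (self.family_fold, self.subfamily_fold):
            for key, fold in table.items():
                if fold <= 0:
                    raise ValueError(f"fold for {key} must be positive")

    def fold_for(self, family: str, subfamily: str, modification: str) -> float:
        if (subfamily, modification) in self.subfamily_fold:
            return self.subfamily_fold[(subfamily, modification)]
        return self.family_fold.get((family, modification), 1.0)


class _Blocked:
    """Sorted non-overlapping blocked intervals per chromosome, for rejection placement."""

    def __init__(self):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def seed_from(self, df: pd.DataFrame) -> None:
        merged = merge_intervals(df)
        for chrom, sub in merged.groupby("chrom"):
            self._by_chrom.setdefault(chrom, []).extend(
                zip(sub["start"].tolist(), sub["end"].tolist())
            )
            self._by_chrom[chrom].sort()

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        idx = bisect_left(ivs, (end, -1))
        return idx > 0 and ivs[idx - 1][1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._by_chrom.setdefault(chrom, []), (start, end))


def promoter_interval(tss: int, strand: str, up: int, down: int, chrom_len: int) -> tuple[int, int]:
    """Half-open promoter window: ``up`` bp upstream through ``down`` bp downstream of the TSS."""
    if strand == "+":
        lo, hi = tss - up, tss + down
    else:
        lo, hi = tss - down, tss + up
    return max(0, lo), min(chrom_len, hi)


def generate_genome(config: GenomeConfig, seed: int) -> GenomeModel:
    """Build a genome with non-overlapping genes and TE insertions.

    Genes are placed first (mutually separated by at least one promoter
    window so promoters never overlap a neighbouring gene body), then TEs
    are placed by bounded rejection sampling avoiding other TEs and all
    promoter windows, so that planted promoter folds and TE folds stay
    identifiable.  Raises RuntimeError when placement fails repeatedly.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_lens = np.array([l for _, l in config.chromosomes], dtype=float)
    sizes = dict(config.chromosomes)
    genes: list[Gene] = []
    blocked = _Blocked()  # genes + margins during gene placement
    margin = config.promoter_up + config.promoter_down

    if config.n_genes and not config.chromosomes:
        raise ValueError("cannot place genes without chromosomes")
    for i in range(config.n_genes):
        length = int(max(1000, rng.normal(config.gene_mean_length, config.gene_length_sd)))
        placed = False
        for _ in range(config.max_place_attempts):
            ci = rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum())
            chrom = chrom_names[ci]
            span = sizes[chrom] - length - 2 * margin
            if span <= 0:
                continue
            start = int(rng.integers(margin, margin + span))
            end = start + length
            if blocked.overlaps(chrom, start - margin, end + margin):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            expression = float(rng.lognormal(config.expression_meanlog, config.expression_sdlog))
            genes.append(Gene(f"gene{i:05d}", chrom, tss, strand, start, end, expression))
            blocked.add(chrom, start, end)
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place gene {i} after {config.max_place_attempts} attempts")

    # TEs avoid promoters and each other but may fall inside gene bodies.
    te_blocked = _Blocked()
    prom_rows = []
    for g in genes:
        lo, hi = promoter_interval(g.tss, g.strand, config.promoter_up, config.promoter_down, sizes[g.chrom])
        prom_rows.append((g.chrom, lo, hi))
    if prom_rows:
        te_blocked.seed_from(pd.DataFrame(prom_rows, columns=["chrom", "start", "end"]))

    tes: list[TEInsertion] = []
    for family in sorted(config.families):
        for subfamily in sorted(config.families[family]):
            sf = config.families[family][subfamily]
            for j in range(sf.count):
                length = int(max(50, rng.normal(sf.mean_length, sf.length_sd)))
                divergence = float(max(0.0, rng.normal(sf.mean_divergence, sf.divergence_sd)))
                placed = False
                for _ in range(config.max_place_attempts):
                    ci = rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum())
                    chrom = chrom_names[ci]
                    if sizes[chrom] <= length:
                        continue
                    start = int(rng.integers(0, sizes[chrom] - length))
                    end = start + length
                    if te_blocked.overlaps(chrom, start, end):
                        continue
                    strand = "+" if rng.random() < 0.5 else "-"
                    tes.append(TEInsertion(chrom, start, end, strand, family, subfamily, divergence))
                    te_blocked.add(chrom, start, end)
                    placed = True
                    break
                if not placed:
                    raise RuntimeError(
                        f"could not place {family}/{subfamily} element {j} after "
                        f"{config.max_place_attempts} attempts; reduce TE content or enlarge chromosomes"
                    )
    genome = GenomeModel(chromosomes=list(config.chromosomes), te_insertions=tes, genes=genes)
    genome.validate()
    return genome


def marked_gene_ids(genome: GenomeModel, spec: EnrichmentSpec, modification: str) -> set[str]:
    """The seeded subset of genes marked for a modification (sampling without replacement)."""
    mark = spec.promoter_marks.get(modification)
    if mark is None or not genome.genes:
        return set()
    n = len(genome.genes)
    k = int(round(mark.marked_gene_fraction * n))
    rng = np.random.default_rng([spec.mark_seed & 0x7FFFFFFF, _h("mark"), _h(modification)])
    idx = rng.choice(n, size=k, replace=False)
    return {genome.genes[i].id for i in idx}


def apply_expression_effects(genome: GenomeModel, spec: EnrichmentSpec) -> GenomeModel:
    """Return a genome whose marked genes have expression shifted by each
    modification's ``expression_effect`` (effects compound across marks)."""
    factor = {g.id: 1.0 for g in genome.genes}
    for mod, mark in spec.promoter_marks.items():
        if mark.expression_effect == 1.0:
            continue
        for gid in marked_gene_ids(genome, spec, mod):
            factor[gid] *= mark.expression_effect
    genes = [
        Gene(g.id, g.chrom, g.tss, g.strand, g.start, g.end, g.expression * factor[g.id])
        for g in genome.genes
    ]
    return GenomeModel(genome.chromosomes, genome.te_insertions, genes)


def _te_proximity_factors(genome: GenomeModel, max_fold: float, decay_bp: float) -> np.ndarray:
    """Per-TE rate multiplier 1 + (max_fold - 1) * exp(-d / decay_bp),
    d = distance of the TE to the nearest gene span (0 inside genes)."""
    te_df = genome.te_frame()
    gene_df = genome.gene_frame().rename(columns={})[["chrom", "start", "end"]]
    dist, _, _ = distance_to_spans(te_df, gene_df)
    dist = np.where(np.isnan(dist), np.inf, dist)
    return 1.0 + (max_fold - 1.0) * np.exp(-dist / decay_bp)


def generate_tags(genome: GenomeModel, spec: EnrichmentSpec, modification: str, seed: int) -> TagLibrary:
    """Draw one modification's tag library from the planted point process.

    The genome is partitioned into segments of constant rate
    ``background_rate * fold``: TE intervals use the spec's family or
    subfamily fold (times any gene-proximity factor), promoters of marked
    genes use ``promoter_fold``, everything else is background; explicit
    region biases multiply on top.  Tag counts per segment are Poisson,
    positions uniform within the segment; each tag is flagged non-unique
    with probability ``nonunique_fraction``.
    """
    if modification not in spec.modifications:
        raise KeyError(f"unknown modification {modification!r}")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, _h("tags"), _h(modification)])
    sizes = genome.chrom_sizes
    mark = spec.promoter_marks.get(modification)
    marked = marked_gene_ids(genome, spec, modification) if mark else set()

    prox = None
    if modification in spec.gene_proximity:
        max_fold, decay_bp = spec.gene_proximity[modification]
        prox = _te_proximity_factors(genome, max_fold, decay_bp)

    features: dict[str, list[tuple[int, int, float]]] = {c: [] for c in sizes}
    for i, te in enumerate(genome.te_insertions):
        fold = spec.fold_for(te.family, te.subfamily, modification)
        if prox is not None:
            fold *= float(prox[i])
        features[te.chrom].append((te.start, te.end, fold))
    if mark:
        for g in genome.genes:
            if g.id in marked:
                lo, hi = promoter_interval(g.tss, g.strand, spec.promoter_up, spec.promoter_down, sizes[g.chrom])
                features[g.chrom].append((lo, hi, mark.promoter_fold))

    biases = [
        b for b in spec.region_bias if b.modification in (None, modification)
    ]

    chroms_out, pos_out = [], []
    for chrom, size in sizes.items():
        feats = sorted(features[chrom])
        cuts = {0, size}
        for s, e, _ in feats:
            cuts.add(s)
            cuts.add(e)
        for b in biases:
            if b.chrom == chrom:
                cuts.add(max(0, b.start))
                cuts.add(min(size, b.end))
        edges = np.array(sorted(cuts), dtype=np.int64)
        seg_start, seg_end = edges[:-1], edges[1:]
        mid = (seg_start + seg_end) // 2
        fold = np.ones(len(seg_start), dtype=float)
        if feats:
            f_start = np.array([f[0] for f in feats])
            f_end = np.array([f[1] for f in feats])
            f_fold = np.array([f[2] for f in feats])
            idx = np.searchsorted(f_start, mid, side="right") - 1
            hit = (idx >= 0) & (mid < f_end[np.clip(idx, 0, None)])
            fold[hit] = f_fold[idx[hit]]
        for b in biases:
            if b.chrom == chrom:
                fold[(mid >= b.start) & (mid < b.end)] *= b.fold
        mu = spec.background_rate * fold * (seg_end - seg_start)
        counts = rng.poisson(mu)
        total = int(counts.sum())
        if total == 0:
            continue
        starts_rep = np.repeat(seg_start, counts)
        lens_rep = np.repeat(seg_end - seg_start, counts)
        positions = starts_rep + (rng.random(total) * lens_rep).astype(np.int64)
        chroms_out.append(np.full(total, chrom, dtype=object))
        pos_out.append(positions)

    if chroms_out:
        chrom_arr = np.concatenate(chroms_out)
        pos_arr = np.concatenate(pos_out)
    else:
        chrom_arr = np.array([], dtype=object)
        pos_arr = np.array([], dtype=np.int64)
    n = len(pos_arr)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    unique = rng.random(n) >= spec.nonunique_fraction
    df = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr, "strand": strand, "unique": unique})
    return TagLibrary(modification=modification, tags=df)


def write_genome(genome: GenomeModel, outdir) -> dict[str, str]:
    """Write the genome bundle (RepeatMasker .out, gene TSV, chrom.sizes)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "repeats": str(outdir / "repeats.out"),
        "genes": str(outdir / "genes.tsv"),
        "chrom_sizes": str(outdir / "chrom.sizes"),
    }
    write_repeatmasker(genome.te_insertions, paths["repeats"])
    write_genes(genome.genes, paths["genes"])
    write_chrom_sizes(genome.chrom_sizes, paths["chrom_sizes"])
    return paths
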