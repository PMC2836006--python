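"""Readers and writers for the file formats the pipeline touches.

Formats handled: RepeatMasker ``.out`` repeat annotation (1-based inclusive
query coordinates, converted at this boundary to the package-wide 0-based
half-open convention), BED tag files (one mapped ChIP-Seq tag per line, the
``start`` column is the tag position, the score column is the uniqueness
flag), a gene TSV with TSS/strand/span/expression, ``chrom.sizes`` files,
and generic result tables as TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Gene, TEInsertion

logger = logging.getLogger(__name__)

#: Maps RepeatMasker class/family strings to the six analysed family groups.
#: Keys ending in "/*" match any subdivision of that class; this table is
#: data, not code — pass a custom mapping to ``read_repeatmasker`` to regroup.
DEFAULT_FAMILY_MAP: dict[str, str] = {
    "SINE/Alu": "Alu",
    "SINE/MIR": "MIR",
    "LINE/L1": "L1",
    "LINE/L2": "L2",
    "LTR": "LTR",
    "LTR/*": "LTR",
    "DNA": "DNA",
    "DNA/*": "DNA",
}

#: Inverse used when writing synthetic annotations back out.
FAMILY_TO_CLASS = {
    "Alu": "SINE/Alu",
    "MIR": "SINE/MIR",
    "L1": "LINE/L1",
    "L2": "LINE/L2",
    "LTR": "LTR/ERVL",
    "DNA": "DNA/TcMar",
}

RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "       class/family         begin  end (left)   ID\n"
    "\n"
)


def resolve_family(class_family: str, family_map: dict[str, str] | None = None) -> str | None:
    """Map a RepeatMasker class/family string to a family group, or None."""
    table = DEFAULT_FAMILY_MAP if family_map is None else family_map
    if class_family in table:
        return table[class_family]
    head = class_family.split("/", 1)[0]
    return table.get(head + "/*")


def read_repeatmasker(path, family_map: dict[str, str] | None = None) -> list[TEInsertion]:
    """Parse a RepeatMasker ``.out`` file into TE insertions.

    The three header lines are skipped; query coordinates (1-based
    inclusive) become 0-based half-open.  Rows whose class/family does not
    map to one of the six family groups (e.g. Simple_repeat) are skipped
    and counted in a log message.
    """
    insertions: list[TEInsertion] = []
    skipped = 0
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 11:
                raise ValueError(f"{path}: malformed RepeatMasker line {lineno}")
            try:
                divergence = float(parts[1])
                start1 = int(parts[5])
                end1 = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed RepeatMasker line {lineno}: {exc}") from None
            family = resolve_family(parts[10], family_map)
            if family is None:
                skipped += 1
                continue
            strand = "-" if parts[8] == "C" else "+"
            insertions.append(
                TEInsertion(
                    chrom=parts[4],
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    family=family,
                    subfamily=parts[9],
                    divergence=divergence,
                )
            )
    if skipped:
        logger.warning("read_repeatmasker: skipped %d records of unmapped repeat classes", skipped)
    return insertions


def write_repeatmasker(insertions: list[TEInsertion], path) -> None:
    """Write TE insertions in RepeatMasker ``.out`` dialect (1-based inclusive coords)."""
    with open(path, "w") as fh:
        fh.write(RM_HEADER)
        for i, te in enumerate(insertions, start=1):
            strand = "C" if te.strand == "-" else "+"
            cf = FAMILY_TO_CLASS.get(te.family, te.family)
            fh.write(
                f"  225 {te.divergence:5.1f}  0.0  0.0  {te.chrom} "
                f"{te.start + 1} {te.end} (0) {strand} {te.subfamily} {cf} 1 {te.length} (0) {i}\n"
            )


@dataclass
class TagLibrary:
    """One histone modification's mapped tag positions.

    ``tags`` has columns chrom, pos, strand, unique and is kept sorted by
    (chrom, pos).  Each tag is the mapped 5' position of one sequenced
    ChIP fragment; ``unique`` is False for tags whose best alignment was
    ambiguous and was assigned at random.
    """

    modification: str
    tags: pd.DataFrame
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        expected = ["chrom", "pos", "strand", "unique"]
        if list(self.tags.columns[:4]) != expected:
            raise ValueError(f"tag frame must have columns {expected}")
        self.tags = self.tags.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    @property
    def total_count(self) -> int:
        return len(self.tags)

    def positions_by_chrom(self, unique_only: bool = False) -> dict[str, np.ndarray]:
        """Sorted tag position arrays per chromosome (cached)."""
        key = bool(unique_only)
        if key not in self._cache:
            df = self.tags[self.tags["unique"]] if unique_only else self.tags
            self._cache[key] = {
                chrom: sub["pos"].to_numpy(dtype=np.int64) for chrom, sub in df.groupby("chrom")
            }
        return self._cache[key]


@dataclass
class IntervalSet:
    """A labelled set of sorted half-open intervals with its total length."""

    label: str
    intervals: pd.DataFrame  # chrom, start, end; sorted

    def __post_init__(self):
        from .intervals import sort_intervals

        self.intervals = sort_intervals(self.intervals[["chrom", "start", "end"]])

    @property
    def total_length(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


def read_tags(path, modification: str | None = None, sizes: dict[str, int] | None = None) -> TagLibrary:
    """Read a tag BED file (chrom, start, start+1, name, score=uniqueness, strand)."""
    rows = []
    name = modification
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            chrom, pos = parts[0], int(parts[1])
            if name is None and len(parts) >= 4:
                name = parts[3]
            unique = True
            if len(parts) >= 5:
                unique = int(float(parts[4])) != 0
            strand = parts[5] if len(parts) >= 6 else "+"
            if sizes is not None:
                if chrom not in sizes or not (0 <= pos < sizes[chrom]):
                    raise ValueError(f"{path}: line {lineno}: position {chrom}:{pos} out of bounds")
            rows.append((chrom, pos, strand, unique))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "unique"])
    df["unique"] = df["unique"].astype(bool)
    return TagLibrary(modification=name or "unknown", tags=df)


def write_tags(library: TagLibrary, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": library.tags["chrom"],
            "start": library.tags["pos"],
            "end": library.tags["pos"] + 1,
            "name": library.modification,
            "score": library.tags["unique"].astype(int),
            "strand": library.tags["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


GENE_COLUMNS = ["id", "chrom", "tss", "strand", "start", "end", "expression"]


def read_genes(path) -> list[Gene]:
    """Read the gene TSV (id, chrom, tss, strand, start, end, expression)."""
    df = read_table(path, required=GENE_COLUMNS)
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            Gene(
                id=str(row.id),
                chrom=str(row.chrom),
                tss=int(row.tss),
                strand=str(row.strand),
                start=int(row.start),
                end=int(row.end),
                expression=float(row.expression),
            )
        )
    return genes


def write_genes(genes: list[Gene], path) -> None:
    df = pd.DataFrame(
        [(g.id, g.chrom, g.tss, g.strand, g.start, g.end, g.expression) for g in genes],
        columns=GENE_COLUMNS,
    )
    write_table(df, path)


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path, "r", newline=None) as fh:
        for line in fh:
            if line.strip():
                name, size = line.split()[:2]
                sizes[name] = int(size)
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV with header, floats at 10 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df
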