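"""Within-family age analysis and distance-to-gene profiles.

Stage 3 of the analysis.  The age analysis groups elements of a family
(typically Alu and L1) by subfamily, takes each subfamily's mean
element-to-consensus percent divergence as its relative age, and
correlates it (Spearman) with the class-summed tag density over the
subfamily's merged intervals, separately for active and repressive
modifications.

The distance analysis associates every TE with its nearest gene
(distance 0 for elements overlapping a gene body), counts the class tags
falling in each element — by default only uniquely mapped tags, since
repetitively mapping tags assigned at random would blur positional signal
— and bins elements by distance in 10 kb bins for presentation.  The
reported correlation is always computed on the unbinned per-element data
(distance vs. tag count / element length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .intervals import count_points_in_intervals, distance_to_spans, merge_intervals
from .io_formats import TagLibrary
from .models import Gene, TEInsertion

CLASSES = ("active", "repressive")


@dataclass(frozen=True)
class SubfamilyRecord:
    family: str
    subfamily: str
    mean_divergence: float  # unweighted mean over elements, percent
    total_length: int
    active_density: float  # class tags per bp over merged subfamily intervals
    repressive_density: float
    n_elements: int


def subfamily_age_table(
    te_insertions: list[TEInsertion],
    active_tags: TagLibrary,
    repressive_tags: TagLibrary,
    families: tuple[str, ...] = ("Alu", "L1"),
) -> pd.DataFrame:
    """Per-subfamily mean divergence and class tag densities.

    Returns a DataFrame: family, subfamily, mean_divergence, total_length,
    active_density, repressive_density, n_elements.
    """
    rows = []
    chosen = [t for t in te_insertions if t.family in families]
    df = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.family, t.subfamily, t.divergence) for t in chosen],
        columns=["chrom", "start", "end", "family", "subfamily", "divergence"],
    )
    for (fam, sub), grp in df.groupby(["family", "subfamily"], sort=True):
        merged = merge_intervals(grp)
        total_len = int((merged["end"] - merged["start"]).sum())
        if total_len == 0:
            raise ValueError(f"subfamily {sub}: zero total length")
        dens = {}
        for klass, tags in (("active", active_tags), ("repressive", repressive_tags)):
            count = int(count_points_in_intervals(tags.positions_by_chrom(), merged).sum())
            dens[klass] = count / total_len
        rows.append((fam, sub, float(grp["divergence"].mean()), total_len,
                     dens["active"], dens["repressive"], len(grp)))
    return pd.DataFrame(
        rows,
        columns=["family", "subfamily", "mean_divergence", "total_length",
                 "active_density", "repressive_density", "n_elements"],
    )


def age_density_correlation(records: pd.DataFrame, klass: str) -> stats.CorrelationResult:
    """Spearman rho of subfamily mean divergence against the class tag density."""
    if klass not in CLASSES:
        raise ValueError(f"unknown class {klass!r}")
    if len(records) < 3:
        raise ValueError("need at least 3 subfamilies")
    return stats.correlate(
        records["mean_divergence"].to_numpy(),
        records[f"{klass}_density"].to_numpy(),
        method="spearman",
    )


def distance_records(
    te_insertions: list[TEInsertion],
    genes: list[Gene],
    active_tags: TagLibrary,
    repressive_tags: TagLibrary,
    families: tuple[str, ...] = ("Alu", "L1"),
    unique_only: bool = True,
) -> pd.DataFrame:
    """Per-element distance to the nearest gene and class tag counts.

    Distance is measured boundary-to-boundary against gene spans; elements
    overlapping a gene body get distance 0 and inside_gene True.  Ties
    between equally distant genes resolve to the gene with the lower start.
    Elements on chromosomes without genes get distance NaN.

    Returns a DataFrame: te_id, family, chrom, start, end, te_length,
    distance_bp, inside_gene, active_count, repressive_count.
    """
    chosen = [t for t in te_insertions if t.family in families]
    te_df = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.family) for t in chosen],
        columns=["chrom", "start", "end", "family"],
    )
    gene_df = pd.DataFrame(
        [(g.chrom, g.start, g.end) for g in genes], columns=["chrom", "start", "end"]
    )
    if len(gene_df):
        dist, inside, _ = distance_to_spans(te_df, gene_df)
    else:
        dist = np.full(len(te_df), np.nan)
        inside = np.zeros(len(te_df), dtype=bool)
    out = te_df.copy()
    out.insert(0, "te_id", [f"te{i:06d}" for i in range(len(te_df))])
    out["te_length"] = out["end"] - out["start"]
    out["distance_bp"] = dist
    out["inside_gene"] = inside
    for klass, tags in (("active", active_tags), ("repressive", repressive_tags)):
        out[f"{klass}_count"] = count_points_in_intervals(
            tags.positions_by_chrom(unique_only=unique_only), te_df)
    return out


@dataclass
class DistanceProfile:
    bins: pd.DataFrame  # bin, inside_gene, n, total_count, total_length, density
    correlation: stats.CorrelationResult | None  # on unbinned per-element data
    flagged: str = ""


def distance_bin_profile(
    records: pd.DataFrame,
    klass: str,
    bin_bp: int = 10_000,
    max_distance: int = 200_000,
) -> DistanceProfile:
    """Bin elements by distance to the nearest gene and profile class tag density.

    Bin i covers distances [i*bin_bp, (i+1)*bin_bp); elements inside gene
    bodies share bin 0 with the [0, bin_bp) gap elements but are separated
    by the ``inside_gene`` flag (aggregate the two rows for the pooled
    view).  Distances above ``max_distance`` collect in an overflow bin
    (bin index -1).  Per-bin density is sum(counts) / sum(element lengths).

    The correlation is Spearman between the per-element distance and
    per-element density (count / length) over all elements — never on the
    binned values.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if klass not in CLASSES:
        raise ValueError(f"unknown class {klass!r}")
    if len(records) == 0:
        raise ValueError("no distance records")
    rec = records.dropna(subset=["distance_bp"]).copy()
    rec["bin"] = (rec["distance_bp"] // bin_bp).astype(int)
    rec.loc[rec["distance_bp"] > max_distance, "bin"] = -1
    col = f"{klass}_count"
    grouped = rec.groupby(["bin", "inside_gene"]).agg(
        n=("te_id", "size"),
        total_count=(col, "sum"),
        total_length=("te_length", "sum"),
    ).reset_index()
    grouped["density"] = grouped["total_count"] / grouped["total_length"]
    corr = None
    flagged = ""
    density = rec[col].to_numpy() / rec["te_length"].to_numpy()
    try:
        corr = stats.correlate(rec["distance_bp"].to_numpy(), density, method="spearman")
    except ValueError as exc:
        flagged = f"correlation-undefined: {exc}"
    return DistanceProfile(bins=grouped, correlation=corr, flagged=flagged)
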