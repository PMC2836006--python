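"""Promoter modification calls and active/repressive classification.

Stage 1 of the analysis: each gene's promoter (1000 bp upstream through
200 bp downstream of the TSS by default) receives a tag count per histone
modification; counts are converted to binary presence/absence calls with a
conservative Poisson threshold against the genomic background rate,
Bonferroni-corrected over all promoter tests.  A modification's expression
enrichment is then the ratio of mean linear-scale expression of genes
where it is present over genes where it is absent; folds above 1 label the
mark *active*, folds below 1 *repressive*, and the significance of the
group difference comes from a pooled two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .intervals import count_points_in_intervals
from .io_formats import TagLibrary
from .models import Gene
from .simulate import promoter_interval

logger = logging.getLogger(__name__)


def define_promoters(
    genes: list[Gene],
    chrom_sizes: dict[str, int],
    up: int = 1000,
    down: int = 200,
) -> pd.DataFrame:
    """Promoter intervals per gene, strand-aware and clipped to chromosome ends.

    Returns a DataFrame with gene_id, chrom, start, end, clipped.
    """
    rows = []
    for g in genes:
        size = chrom_sizes[g.chrom]
        if not (0 <= g.tss < size):
            raise ValueError(f"gene {g.id}: tss outside chromosome")
        lo, hi = promoter_interval(g.tss, g.strand, up, down, size)
        rows.append((g.id, g.chrom, lo, hi, (hi - lo) != up + down))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "clipped"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def count_tags_in_intervals(tags: TagLibrary, intervals: pd.DataFrame, unique_only: bool = False) -> np.ndarray:
    """Tag count per interval row (half-open; a tag in k overlapping intervals counts k times)."""
    return count_points_in_intervals(tags.positions_by_chrom(unique_only=unique_only), intervals)


@dataclass(frozen=True)
class ModificationGeneCall:
    gene_id: str
    modification: str
    tag_count: int
    threshold: int
    present: bool


def call_presence(
    counts: np.ndarray,
    promoters: pd.DataFrame,
    library: TagLibrary,
    genome_length: int,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Binary presence/absence calls for one modification over all promoters.

    The expected background count for a promoter of length L is
    ``lambda = (total tags / genome length) * L``; the call threshold is the
    smallest count whose Poisson upper-tail probability falls below the
    Bonferroni-corrected level ``alpha / n_tests``.  With an empty library
    every promoter is called absent (threshold undefined).

    Returns a DataFrame: gene_id, modification, tag_count, threshold, present.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if n_tests is None:
        n_tests = len(promoters)
    lengths = (promoters["end"] - promoters["start"]).to_numpy()
    if library.total_count == 0:
        logger.warning("call_presence(%s): empty tag library, all promoters called absent",
                       library.modification)
        thresholds = np.full(len(promoters), -1, dtype=np.int64)
        present = np.zeros(len(promoters), dtype=bool)
    else:
        rate = library.total_count / genome_length
        cache: dict[int, int] = {}
        thresholds = np.empty(len(promoters), dtype=np.int64)
        for i, L in enumerate(lengths):
            k = cache.get(L)
            if k is None:
                k = stats.poisson_presence_threshold(rate * L, alpha, n_tests)
                cache[L] = k
            thresholds[i] = k
        present = counts >= thresholds
    return pd.DataFrame(
        {
            "gene_id": promoters["gene_id"].to_numpy(),
            "modification": library.modification,
            "tag_count": counts,
            "threshold": thresholds,
            "present": present,
        }
    )


@dataclass(frozen=True)
class ExpressionEnrichment:
    """Expression enrichment of one modification and its active/repressive label."""

    modification: str
    fold: float  # mean expression(present) / mean expression(absent); nan when undefined
    t: float
    p: float
    klass: str | None  # "active" | "repressive" | None when undefined
    n_present: int
    n_absent: int
    flagged: str = ""  # "", "empty-group", "fold-boundary"


def expression_enrichment(
    calls: pd.DataFrame, genes: list[Gene], log_scale: bool = False
) -> ExpressionEnrichment:
    """Classify one modification from its presence calls and gene expression.

    By default the fold is a ratio of arithmetic means on the linear
    expression scale.  With ``log_scale=True`` the fold is the ratio of
    geometric means (exponentiated difference of mean log expression) and
    the t-test runs on log values — the robust choice when expression
    spans several orders of magnitude.  A fold of exactly 1 cannot be
    assigned a direction; it is labelled repressive and flagged
    "fold-boundary".
    """
    mod = calls["modification"].iloc[0]
    expr = {g.id: g.expression for g in genes}
    present_mask = calls["present"].to_numpy()
    values = calls["gene_id"].map(expr).to_numpy(dtype=float)
    pres = values[present_mask]
    absent = values[~present_mask]
    if len(pres) == 0 or len(absent) == 0 or absent.mean() == 0:
        return ExpressionEnrichment(mod, float("nan"), float("nan"), float("nan"),
                                    None, len(pres), len(absent), flagged="empty-group")
    if log_scale:
        if np.any(values <= 0):
            raise ValueError("log-scale means require strictly positive expression")
        lp, la = np.log(pres), np.log(absent)
        fold = float(np.exp(lp.mean() - la.mean()))
        pres, absent = lp, la
    else:
        fold = float(pres.mean() / absent.mean())
    try:
        t, p = stats.two_sample_t(pres, absent)
    except ValueError:
        t, p = float("nan"), float("nan")
    if fold > 1:
        klass, flag = "active", ""
    elif fold < 1:
        klass, flag = "repressive", ""
    else:
        klass, flag = "repressive", "fold-boundary"
    return ExpressionEnrichment(mod, fold, t, p, klass, len(pres), len(absent), flagged=flag)


def classify_modifications(
    calls_by_mod: dict[str, pd.DataFrame], genes: list[Gene], log_scale: bool = False
) -> pd.DataFrame:
    """Expression-enrichment classification for every modification.

    Returns a DataFrame: modification, fold, t, p, klass, n_present,
    n_absent, flagged.
    """
    rows = []
    for mod in calls_by_mod:
        e = expression_enrichment(calls_by_mod[mod], genes, log_scale=log_scale)
        rows.append((e.modification, e.fold, e.t, e.p, e.klass, e.n_present, e.n_absent, e.flagged))
    return pd.DataFrame(
        rows,
        columns=["modification", "fold", "t", "p", "klass", "n_present", "n_absent", "flagged"],
    )
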