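"""Family x modification tag enrichment against global and local backgrounds.

Stage 2 of the analysis.  For each TE family and modification library the
length-normalised tag density inside the family's (merged) intervals is
compared to a background density, and the log2 of the density ratio is
reported:

    log2_enrichment = log2( (tags_in_family / family_length) / background )

Two backgrounds are supported: *global* (the library's total tag count
over the genome length) and *local* (tag density in randomly sampled
non-TE segments of matched length inside a 1 Mb window centred on each
element, pooled over elements).  Significance of the partition of tags
into inside/outside counts comes from a 2-cell goodness-of-fit G-test with
expected counts proportional to the corresponding lengths, Bonferroni
corrected over all family x modification cells per background kind.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .intervals import ChromArrays, count_points_in_intervals, sort_intervals
from .io_formats import IntervalSet, TagLibrary
from .models import FAMILIES, FAMILY_AGE_RANK, TEInsertion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRecord:
    family: str
    modification: str  # a library name, or "active"/"repressive" for class records
    te_tag_count: int
    te_length: int
    background_density: float  # tags per bp
    log2_enrichment: float  # nan when te_tag_count == 0
    background_kind: str  # "global" | "local"
    G: float
    df: int
    p: float
    significant: bool
    corrected_level: float
    flagged: str = ""


RECORD_COLUMNS = [
    "family", "modification", "te_tag_count", "te_length", "background_density",
    "log2_enrichment", "background_kind", "G", "df", "p", "significant",
    "corrected_level", "flagged",
]


def records_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)


def family_interval_sets(te_insertions: list[TEInsertion]) -> dict[str, IntervalSet]:
    """Merged (flattened) interval set per family, so tags are never double
    counted within one family."""
    from .intervals import merge_intervals

    df = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.family) for t in te_insertions],
        columns=["chrom", "start", "end", "family"],
    )
    out = {}
    for fam, sub in df.groupby("family"):
        out[fam] = IntervalSet(label=fam, intervals=merge_intervals(sub))
    return out


def _ratio_record(
    family: str,
    modification: str,
    te_count: int,
    te_length: int,
    bg_density: float,
    bg_count: float,
    bg_length: float,
    background_kind: str,
    corrected_level: float,
    flagged: str = "",
) -> EnrichmentRecord:
    """Shared enrichment arithmetic: density ratio + 2-cell G-test.

    The G-test compares observed (tags in family, tags in background
    region) against expectations proportional to the two region lengths.
    """
    if te_length <= 0:
        raise ValueError(f"family {family}: zero total TE length")
    if te_count > 0 and bg_density > 0:
        log2_enr = math.log2((te_count / te_length) / bg_density)
    else:
        log2_enr = float("nan")
        flagged = (flagged + ";" if flagged else "") + "undefined-log2"
    total = te_count + bg_count
    G = df = p = float("nan")
    significant = False
    if total > 0 and bg_length > 0:
        frac = te_length / (te_length + bg_length)
        expected = np.array([total * frac, total * (1 - frac)])
        res = stats.g_test([te_count, bg_count], expected)
        G, df, p = res.G, res.df, res.p
        significant = bool(p < corrected_level)
    return EnrichmentRecord(
        family=family,
        modification=modification,
        te_tag_count=int(te_count),
        te_length=int(te_length),
        background_density=float(bg_density),
        log2_enrichment=log2_enr,
        background_kind=background_kind,
        G=float(G),
        df=int(df) if not isinstance(df, float) or not math.isnan(df) else 1,
        p=float(p),
        significant=significant,
        corrected_level=float(corrected_level),
        flagged=flagged,
    )


def global_enrichment(
    tags: TagLibrary,
    family_intervals: IntervalSet,
    genome_length: int,
    corrected_level: float = 0.05,
    modification: str | None = None,
) -> EnrichmentRecord:
    """Enrichment of one library in one family against the genome-wide background.

    The background density is the library's total tag count over the
    genome length (tags inside TEs are not excluded; see the
    ``exclude_te_tags`` switch in :func:`enrichment_table` for the
    alternative).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    te_len = family_intervals.total_length
    counts = count_points_in_intervals(tags.positions_by_chrom(), family_intervals.intervals)
    te_count = int(counts.sum())
    bg_density = tags.total_count / genome_length
    return _ratio_record(
        family=family_intervals.label,
        modification=modification or tags.modification,
        te_count=te_count,
        te_length=te_len,
        bg_density=bg_density,
        bg_count=tags.total_count - te_count,
        bg_length=genome_length - te_len,
        background_kind="global",
        corrected_level=corrected_level,
    )


@dataclass
class LocalSegmentSample:
    """Matched-length non-TE segments sampled near each element of a family."""

    family: str
    segments: pd.DataFrame  # chrom, start, end (one row per successfully sampled TE)
    n_sampled: int
    n_skipped: int


def sample_local_segments(
    insertions: list[TEInsertion],
    all_te_intervals: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_bp: int = 1_000_000,
    seed: int = 0,
    family: str | None = None,
) -> LocalSegmentSample:
    """For each TE, sample one non-TE segment of the same length uniformly
    from the 1 Mb (by default) window centred on the element.

    Sampling is exact: the non-TE gaps of the window are enumerated and a
    start position is drawn uniformly over all placements that fit, which
    is the same distribution a bounded rejection sampler targets but never
    fails when a placement exists.  Elements whose window holds no gap of
    sufficient length are skipped and counted.
    """
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    blocked = ChromArrays.from_frame(all_te_intervals, merge=True)
    rows = []
    n_skipped = 0
    fam = family or (insertions[0].family if insertions else "NA")
    for te in insertions:
        L = te.length
        if window_bp <= L:
            raise ValueError(f"window_bp {window_bp} not larger than element length {L}")
        mid = (te.start + te.end) // 2
        size = chrom_sizes[te.chrom]
        w0 = max(0, mid - window_bp // 2)
        w1 = min(size, mid + window_bp // 2)
        gaps = [(s, e) for s, e in blocked.gaps_in_window(te.chrom, w0, w1) if e - s >= L]
        weights = np.array([e - s - L + 1 for s, e in gaps], dtype=float)
        if len(gaps) == 0:
            n_skipped += 1
            continue
        gi = rng.choice(len(gaps), p=weights / weights.sum())
        start = int(rng.integers(gaps[gi][0], gaps[gi][1] - L + 1))
        rows.append((te.chrom, start, start + L))
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return LocalSegmentSample(family=fam, segments=segments, n_sampled=len(rows), n_skipped=n_skipped)


@dataclass
class LocalBackgroundEstimate:
    family: str
    modification: str
    sampled_counts: np.ndarray
    sampled_lengths: np.ndarray
    density: float  # pooled: sum(counts) / sum(lengths); nan when nothing sampled
    n_sampled: int
    n_skipped: int
    unreliable: bool = False


def local_background(
    sample: LocalSegmentSample,
    tags: TagLibrary,
    pooled: bool = True,
    unreliable_skip_fraction: float = 0.10,
) -> LocalBackgroundEstimate:
    """Tag density over a family's sampled local segments.

    ``pooled=True`` (default) returns the length-weighted pooled rate
    sum(counts)/sum(lengths) — the maximum-likelihood rate estimate;
    ``pooled=False`` returns the unweighted mean of per-segment densities.
    Estimates with more than ``unreliable_skip_fraction`` of elements
    skipped are flagged unreliable.
    """
    counts = count_points_in_intervals(tags.positions_by_chrom(), sample.segments)
    lengths = (sample.segments["end"] - sample.segments["start"]).to_numpy()
    if sample.n_sampled == 0:
        density = float("nan")
    elif pooled:
        density = float(counts.sum() / lengths.sum())
    else:
        density = float(np.mean(counts / lengths))
    total = sample.n_sampled + sample.n_skipped
    unreliable = total > 0 and sample.n_skipped / total > unreliable_skip_fraction
    if unreliable:
        logger.warning("local background %s/%s: %d of %d elements skipped",
                       sample.family, tags.modification, sample.n_skipped, total)
    return LocalBackgroundEstimate(
        family=sample.family,
        modification=tags.modification,
        sampled_counts=counts,
        sampled_lengths=lengths,
        density=density,
        n_sampled=sample.n_sampled,
        n_skipped=sample.n_skipped,
        unreliable=unreliable,
    )


def local_enrichment(
    tags: TagLibrary,
    family_intervals: IntervalSet,
    local_bg: LocalBackgroundEstimate,
    corrected_level: float = 0.05,
    modification: str | None = None,
) -> EnrichmentRecord:
    """Enrichment of one library in one family against its local background."""
    if math.isnan(local_bg.density):
        raise ValueError(f"local background undefined for {family_intervals.label}")
    te_len = family_intervals.total_length
    counts = count_points_in_intervals(tags.positions_by_chrom(), family_intervals.intervals)
    te_count = int(counts.sum())
    flagged = "unreliable-local-bg" if local_bg.unreliable else ""
    return _ratio_record(
        family=family_intervals.label,
        modification=modification or tags.modification,
        te_count=te_count,
        te_length=te_len,
        bg_density=local_bg.density,
        bg_count=int(local_bg.sampled_counts.sum()),
        bg_length=int(local_bg.sampled_lengths.sum()),
        background_kind="local",
        corrected_level=corrected_level,
        flagged=flagged,
    )


def pool_libraries(libraries: list[TagLibrary], name: str) -> TagLibrary:
    """Concatenate libraries into one (used to sum tags within a class)."""
    frames = [lib.tags for lib in libraries]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "unique"])
    return TagLibrary(modification=name, tags=df)


def enrichment_table(
    libraries: dict[str, TagLibrary],
    family_sets: dict[str, IntervalSet],
    genome_length: int,
    chrom_sizes: dict[str, int] | None = None,
    te_insertions: list[TEInsertion] | None = None,
    background: str = "global",
    alpha: float = 0.05,
    window_bp: int = 1_000_000,
    seed: int = 0,
    exclude_te_tags: bool = False,
) -> list[EnrichmentRecord]:
    """All family x modification enrichment records for one background kind.

    The Bonferroni-corrected significance level is
    ``alpha / (families * modifications)``.  ``exclude_te_tags`` removes
    tags inside any TE annotation from the global background density
    (off by default: the genome-wide background is the total tag count).
    """
    n_cells = len(family_sets) * len(libraries)
    corrected = stats.bonferroni(alpha, max(1, n_cells))
    records: list[EnrichmentRecord] = []
    if background == "global":
        all_te = None
        if exclude_te_tags:
            all_te = sort_intervals(pd.concat([s.intervals for s in family_sets.values()], ignore_index=True))
            from .intervals import merge_intervals

            all_te = merge_intervals(all_te)
            all_len = int((all_te["end"] - all_te["start"]).sum())
        for fam in sorted(family_sets):
            for mod in libraries:
                lib = libraries[mod]
                if exclude_te_tags:
                    in_te = int(count_points_in_intervals(lib.positions_by_chrom(), all_te).sum())
                    te_len = family_sets[fam].total_length
                    fam_count = int(count_points_in_intervals(
                        lib.positions_by_chrom(), family_sets[fam].intervals).sum())
                    bg_count = lib.total_count - in_te
                    bg_len = genome_length - all_len
                    records.append(_ratio_record(
                        fam, mod, fam_count, te_len, bg_count / bg_len, bg_count, bg_len,
                        "global", corrected))
                else:
                    records.append(global_enrichment(
                        lib, family_sets[fam], genome_length, corrected, modification=mod))
    elif background == "local":
        if te_insertions is None or chrom_sizes is None:
            raise ValueError("local background requires te_insertions and chrom_sizes")
        all_te = pd.DataFrame(
            [(t.chrom, t.start, t.end) for t in te_insertions], columns=["chrom", "start", "end"])
        by_family: dict[str, list[TEInsertion]] = {}
        for t in te_insertions:
            by_family.setdefault(t.family, []).append(t)
        for fam in sorted(family_sets):
            sample = sample_local_segments(
                by_family.get(fam, []), all_te, chrom_sizes, window_bp=window_bp,
                seed=int(seed) + FAMILY_AGE_RANK.get(fam, 0), family=fam)
            for mod in libraries:
                bg = local_background(sample, libraries[mod])
                records.append(local_enrichment(
                    libraries[mod], family_sets[fam], bg, corrected, modification=mod))
    else:
        raise ValueError(f"unknown background kind {background!r}")
    return records


def class_enrichment(
    libraries: dict[str, TagLibrary],
    classification: pd.DataFrame,
    family_sets: dict[str, IntervalSet],
    genome_length: int,
    chrom_sizes: dict[str, int] | None = None,
    te_insertions: list[TEInsertion] | None = None,
    background: str = "global",
    alpha: float = 0.05,
    window_bp: int = 1_000_000,
    seed: int = 0,
) -> list[EnrichmentRecord]:
    """Family x {active, repressive} enrichment, with tags summed within class
    before the enrichment formula is applied."""
    klass_of = dict(zip(classification["modification"], classification["klass"]))
    unknown = [m for m in libraries if m not in klass_of or klass_of[m] not in ("active", "repressive")]
    if unknown:
        raise ValueError(f"unclassified libraries: {unknown}")
    pooled = {}
    for klass in ("active", "repressive"):
        members = [libraries[m] for m in libraries if klass_of[m] == klass]
        if members:
            pooled[klass] = pool_libraries(members, klass)
    return enrichment_table(
        pooled, family_sets, genome_length, chrom_sizes=chrom_sizes,
        te_insertions=te_insertions, background=background, alpha=alpha,
        window_bp=window_bp, seed=seed)


def family_age_correlation(
    class_records: list[EnrichmentRecord],
    klass: str,
    age_ranks: dict[str, int] | None = None,
) -> stats.CorrelationResult:
    """Spearman correlation of a class's log2 enrichment with family age rank.

    Default age ranks follow the young-to-old family ordering
    Alu < L1 < LTR < DNA < L2 < MIR.
    """
    ranks = age_ranks or FAMILY_AGE_RANK
    recs = {r.family: r for r in class_records if r.modification == klass}
    missing = [f for f in ranks if f not in recs]
    if missing:
        raise ValueError(f"missing families for age correlation: {missing}")
    fams = sorted(ranks, key=ranks.get)
    x = np.array([ranks[f] for f in fams], dtype=float)
    y = np.array([recs[f].log2_enrichment for f in fams], dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("undefined log2 enrichment among families")
    return stats.correlate(x, y, method="spearman")
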