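"""Half-open genomic interval arithmetic on plain numpy arrays.

Every coordinate in this package is 0-based half-open ``[start, end)``;
conversions to and from 1-based file formats happen only in
:mod:`temark.io_formats`.  Interval tables are pandas DataFrames with at
least ``chrom``, ``start`` and ``end`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy sorted by (chrom, start, end)."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def total_length(df: pd.DataFrame) -> int:
    return int((df["end"] - df["start"]).sum())


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or bookended intervals are fused per chromosome."""
    if len(df) == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    out = []
    for chrom, sub in sort_intervals(df).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def complement_intervals(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Gaps not covered by ``df`` over whole chromosomes (``df`` need not be merged)."""
    merged = merge_intervals(df)
    out = []
    for chrom, size in chrom_sizes.items():
        sub = merged[merged["chrom"] == chrom]
        pos = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > pos:
                out.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < size:
            out.append((chrom, pos, size))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


@dataclass
class ChromArrays:
    """Per-chromosome (starts, ends) arrays of merged, sorted intervals."""

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, merge: bool = True) -> "ChromArrays":
        src = merge_intervals(df) if merge else sort_intervals(df)
        obj = cls()
        for chrom, sub in src.groupby("chrom"):
            obj.starts[chrom] = sub["start"].to_numpy(dtype=np.int64)
            obj.ends[chrom] = sub["end"].to_numpy(dtype=np.int64)
        return obj

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any stored (merged) interval."""
        starts = self.starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        idx = int(np.searchsorted(starts, end, side="left"))
        if idx == 0:
            return False
        return bool(self.ends[chrom][idx - 1] > start)

    def gaps_in_window(self, chrom: str, win_start: int, win_end: int) -> list[tuple[int, int]]:
        """Sub-intervals of [win_start, win_end) not covered by any stored interval."""
        starts = self.starts.get(chrom)
        if starts is None or len(starts) == 0:
            return [(win_start, win_end)] if win_end > win_start else []
        ends = self.ends[chrom]
        lo = int(np.searchsorted(ends, win_start, side="right"))
        gaps = []
        pos = win_start
        for i in range(lo, len(starts)):
            s, e = int(starts[i]), int(ends[i])
            if s >= win_end:
                break
            if s > pos:
                gaps.append((pos, min(s, win_end)))
            pos = max(pos, e)
            if pos >= win_end:
                break
        if pos < win_end:
            gaps.append((pos, win_end))
        return gaps


def count_points_in_intervals(
    positions_by_chrom: dict[str, np.ndarray], intervals: pd.DataFrame
) -> np.ndarray:
    """Number of points falling in each interval (half-open; overlapping
    intervals each count any shared point).

    ``positions_by_chrom`` maps chromosome name to a *sorted* int array.
    Returns an int64 array aligned with ``intervals`` rows.
    """
    counts = np.zeros(len(intervals), dtype=np.int64)
    if len(intervals) == 0:
        return counts
    for chrom, sub in intervals.groupby("chrom"):
        pos = positions_by_chrom.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="left")
        counts[sub.index.to_numpy()] = hi - lo
    return counts


def distance_to_spans(
    query: pd.DataFrame, spans: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distance from each query interval to the nearest span on its chromosome.

    Returns ``(distance_bp, inside, nearest_start)`` arrays aligned with
    ``query`` rows.  ``distance_bp`` is 0 when the query overlaps a span
    (``inside`` True); it is ``nan`` when the chromosome holds no span.
    Ties between an equally distant left and right span resolve to the span
    with the lower start coordinate, recorded in ``nearest_start``.
    """
    n = len(query)
    dist = np.full(n, np.nan)
    inside = np.zeros(n, dtype=bool)
    nearest = np.full(n, -1, dtype=np.int64)
    spans_sorted = sort_intervals(spans)
    by_chrom = {c: sub for c, sub in spans_sorted.groupby("chrom")}
    for chrom, sub in query.groupby("chrom"):
        sp = by_chrom.get(chrom)
        if sp is None or len(sp) == 0:
            continue
        s_starts = sp["start"].to_numpy(dtype=np.int64)
        s_ends = sp["end"].to_numpy(dtype=np.int64)
        # rightmost span end among spans starting before a position, in start order
        prefix_max_end = np.maximum.accumulate(s_ends)
        q_start = sub["start"].to_numpy(dtype=np.int64)
        q_end = sub["end"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(s_starts, q_end, side="left")  # spans with start < q_end
        for row, (qs, qe, i) in zip(sub.index.to_numpy(), zip(q_start, q_end, idx)):
            left_gap = np.inf
            left_j = -1
            if i > 0:
                max_end = prefix_max_end[i - 1]
                if max_end > qs:  # some span with start < qe ends past qs -> overlap
                    dist[row] = 0.0
                    inside[row] = True
                    j = int(np.argmax(s_ends[:i] > qs))
                    nearest[row] = s_starts[j]
                    continue
                left_gap = qs - max_end
                left_j = int(np.argmax(s_ends[:i] == max_end))
            right_gap = np.inf
            if i < len(s_starts):
                right_gap = s_starts[i] - qe
            if left_gap <= right_gap and left_j >= 0:
                dist[row] = float(left_gap)
                nearest[row] = s_starts[left_j]
            elif right_gap < np.inf:
                dist[row] = float(right_gap)
                nearest[row] = s_starts[i]
    return dist, inside, nearest
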