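"""Profile-vs-hotspot and profile-vs-profile overlap comparison.

Counts how many breakpoints of a query profile fall inside a set of
intervals (hotspots) or lie within a proximity window of another profile's
breakpoints. Counting is directional by design: the result counts QUERY
breakpoints, each at most once, so swapping query and target can change the
number.
"""
from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import BreakpointProfile

__all__ = ["OverlapReport", "overlap_with_intervals", "overlap_with_profile", "compare_all"]


@dataclass(frozen=True)
class OverlapReport:
    """Per-target overlap counts of one query profile.

    ``rows`` has columns target_id, target_kind ('hotspot_set' or
    'profile') and n_query_overlapping, sorted descending by count with a
    stable tie-break by target label.
    """

    rows: pd.DataFrame
    query_id: str
    window: int


def overlap_with_intervals(
    query: BreakpointProfile, intervals: Iterable[tuple[str, int, int]]
) -> int:
    """Count query breakpoints inside ≥1 half-open interval (each once)."""
    merged: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, start, end in intervals:
        merged[chrom].append((start, end))
    # merge overlapping intervals so each chromosome is a sorted disjoint set
    flat: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in merged.items():
        ivs.sort()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        flat[chrom] = (starts, ends)
    count = 0
    for bp in query.breakpoints:
        if bp.chrom not in flat:
            continue
        starts, ends = flat[bp.chrom]
        i = bisect_right(starts, bp.pos) - 1
        if i >= 0 and bp.pos < ends[i]:
            count += 1
    return count


def overlap_with_profile(
    query: BreakpointProfile, target: BreakpointProfile, window: int
) -> int:
    """Count query breakpoints with a same-chromosome target breakpoint within ±window.

    Each query breakpoint counts at most once regardless of how many target
    breakpoints fall in its window.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for bp in target.breakpoints:
        by_chrom[bp.chrom].append(bp.pos)
    for positions in by_chrom.values():
        positions.sort()
    count = 0
    for bp in query.breakpoints:
        positions = by_chrom.get(bp.chrom)
        if not positions:
            continue
        lo = bisect_left(positions, bp.pos - window)
        hi = bisect_right(positions, bp.pos + window)
        if hi > lo:
            count += 1
    return count


def compare_all(
    query: BreakpointProfile,
    hotspot_sets: Mapping[str, Sequence[tuple[str, int, int]]],
    profiles: Mapping[str, BreakpointProfile],
    window: int = 10_000,
) -> OverlapReport:
    """Compare a query profile against labelled hotspot sets and profiles.

    Returns one row per target, sorted descending by overlap count (stable
    tie-break by label). Labels must be unique across both target kinds.
    """
    labels = list(hotspot_sets) + list(profiles)
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate target label(s): {', '.join(dup)}")
    rows = []
    for label, intervals in hotspot_sets.items():
        rows.append((label, "hotspot_set", overlap_with_intervals(query, intervals)))
    for label, target in profiles.items():
        rows.append((label, "profile", overlap_with_profile(query, target, window)))
    df = pd.DataFrame(rows, columns=["target_id", "target_kind", "n_query_overlapping"])
    df = df.sort_values(
        ["n_query_overlapping", "target_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return OverlapReport(rows=df, query_id=query.sample_id, window=window)
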