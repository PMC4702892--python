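"""High-confidence and somatic filters for structural alterations.

The pipeline keeps alterations supported by at least ``min_discordant``
discordant read pairs AND ``min_softclip`` soft-clipped reads, drops events
larger than ``max_size`` (strictly greater; inter-chromosomal events have no
size and are never size-filtered), subtracts alterations matching any pooled
normal-genome alteration (germline), and removes alterations whose
breakpoints fall in population-variant blacklist intervals. Filters select
records — they never mutate them — and each is idempotent.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import AlterationRecord

__all__ = [
    "FilterConfig",
    "filter_support",
    "filter_size",
    "subtract_germline",
    "subtract_blacklist",
    "filter_pipeline",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the filter cascade.

    min_discordant, min_softclip
        Minimum read support of each kind (default 2 and 2).
    max_size
        Events strictly larger than this (bases) are dropped; default 10 Mb.
    germline_tolerance
        Per-breakpoint positional slack (bases) when matching a cancer
        alteration against pooled normals; default 100 bp absorbs alignment
        jitter at breakpoint resolution.
    blacklist_mode
        Only ``breakpoint_in_region`` is implemented: a record is removed
        when any of its breakpoints lies inside a blacklist interval.
    """

    min_discordant: int = 2
    min_softclip: int = 2
    max_size: int = 10_000_000
    germline_tolerance: int = 100
    blacklist_mode: str = "breakpoint_in_region"

    def __post_init__(self) -> None:
        for name in ("min_discordant", "min_softclip", "max_size", "germline_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.blacklist_mode != "breakpoint_in_region":
            raise ValueError(f"unsupported blacklist_mode {self.blacklist_mode!r}")


def filter_support(
    records: Sequence[AlterationRecord], cfg: FilterConfig = FilterConfig()
) -> list[AlterationRecord]:
    """Keep records with ≥ min_discordant discordant pairs AND ≥ min_softclip soft-clips."""
    return [
        r
        for r in records
        if r.discordant_pairs >= cfg.min_discordant and r.softclip_reads >= cfg.min_softclip
    ]


def filter_size(
    records: Sequence[AlterationRecord], cfg: FilterConfig = FilterConfig()
) -> list[AlterationRecord]:
    """Drop intra-chromosomal records with size strictly greater than max_size.

    Records with undefined size (inter-chromosomal translocations,
    single-breakpoint events) are always kept.
    """
    return [r for r in records if r.size is None or r.size <= cfg.max_size]


def _germline_match(cancer: AlterationRecord, normal: AlterationRecord, tol: int) -> bool:
    if cancer.event_type != normal.event_type:
        return False
    if (cancer.bp2 is None) != (normal.bp2 is None):
        return False
    for c_bp, n_bp in zip(cancer.breakpoints, normal.breakpoints):
        if c_bp.chrom != n_bp.chrom or abs(c_bp.pos - n_bp.pos) > tol:
            return False
    return True


def subtract_germline(
    cancer_records: Sequence[AlterationRecord],
    normal_records: Sequence[AlterationRecord],
    cfg: FilterConfig = FilterConfig(),
) -> list[AlterationRecord]:
    """Remove cancer alterations matching any pooled-normal alteration.

    A cancer record is removed iff some normal record has the same event
    type, the same breakpoint arity, and every defined breakpoint on the
    same chromosome within ``germline_tolerance`` bases of the corresponding
    cancer breakpoint. Survivors keep input order.
    """
    tol = cfg.germline_tolerance
    # Index normals by (event_type, arity, bp1 chrom) and sort by bp1 pos so
    # each cancer record only scans a tolerance-wide slice.
    from bisect import bisect_left, bisect_right
    from collections import defaultdict

    index: dict[tuple, list[tuple[int, AlterationRecord]]] = defaultdict(list)
    for n in normal_records:
        index[(n.event_type, n.bp2 is None, n.bp1.chrom)].append((n.bp1.pos, n))
    for bucket in index.values():
        bucket.sort(key=lambda t: t[0])

    survivors = []
    for c in cancer_records:
        bucket = index.get((c.event_type, c.bp2 is None, c.bp1.chrom), [])
        positions = [p for p, _ in bucket]
        lo = bisect_left(positions, c.bp1.pos - tol)
        hi = bisect_right(positions, c.bp1.pos + tol)
        if not any(_germline_match(c, n, tol) for _, n in bucket[lo:hi]):
            survivors.append(c)
    return survivors


def subtract_blacklist(
    records: Sequence[AlterationRecord],
    blacklist: Iterable[tuple[str, int, int]],
    cfg: FilterConfig = FilterConfig(),
) -> list[AlterationRecord]:
    """Remove records with any breakpoint inside a blacklist interval.

    Containment is half-open: a breakpoint at ``end`` is outside
    ``[start, end)``.
    """
    from collections import defaultdict

    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, start, end in blacklist:
        by_chrom[chrom].append((start, end))

    def hit(record: AlterationRecord) -> bool:
        return any(
            start <= bp.pos < end
            for bp in record.breakpoints
            for start, end in by_chrom.get(bp.chrom, ())
        )

    return [r for r in records if not hit(r)]


def filter_pipeline(
    cancer_records: Sequence[AlterationRecord],
    cfg: FilterConfig = FilterConfig(),
    normal_records: Sequence[AlterationRecord] = (),
    blacklist: Iterable[tuple[str, int, int]] = (),
) -> dict[str, list[AlterationRecord]]:
    """Run the default cascade: support → size → germline → blacklist.

    Returns the survivors after each stage keyed by stage name (the final
    stage is ``"blacklist"``), so per-stage counts are auditable.
    """
    stages = {}
    stages["support"] = filter_support(cancer_records, cfg)
    stages["size"] = filter_size(stages["support"], cfg)
    stages["germline"] = subtract_germline(stages["size"], normal_records, cfg)
    stages["blacklist"] = subtract_blacklist(stages["germline"], blacklist, cfg)
    return stages
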