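"""Breakpoint-hotspot detection by boundary segmentation and permutation.

The strategy:

1. Extend every breakpoint of every sample by ``flank`` bases upstream and
   downstream (default 10 kb), clipped to chromosome bounds.
2. Using the boundaries of all samples' extended regions, segment each
   chromosome into non-overlapping bins of unequal sizes; each bin's
   enrichment score is the number of DISTINCT samples whose extended regions
   overlap it.
3. Bins overlapped by at least ``min_samples_tested`` samples are tested:
   breakpoints of all samples are relocated uniformly over the genome
   (chromosome chosen proportional to length) ``n_perm`` times, re-extended,
   and re-scored on the FIXED observed bins; the empirical upper-tail
   p-value uses the +1 pseudocount so it is never exactly zero.
4. p-values are corrected for multiple testing (Benjamini–Hochberg step-up
   by default, plain Bonferroni optionally) over the tested bins; bins with
   adjusted p below ``alpha`` are the hotspots, book-ended significant bins
   optionally merged.

Everything is seeded: one master seed spawns one deterministic substream per
permutation, so results are bit-reproducible and independent of execution
order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome import GenomeAssembly
from .records import Breakpoint, BreakpointProfile

__all__ = [
    "PermutationConfig",
    "HotspotResult",
    "extend_breakpoints",
    "segment_by_boundaries",
    "permute_profiles",
    "empirical_pvalues",
    "bh_adjust",
    "call_hotspots",
    "merge_book_ended",
    "summarize_profiles",
    "summarize_counts",
]

BIN_COLUMNS = ("chrom", "start", "end", "score", "tested", "p_value", "q_value")


@dataclass(frozen=True)
class PermutationConfig:
    """Configuration of the permutation test.

    n_perm
        Number of genome-wide randomizations of all samples (default 10,000).
    seed
        Master RNG seed; one substream per permutation is derived from it.
    alpha
        Significance level applied to adjusted p-values (default 0.05).
    flank
        Breakpoint extension, bases up- and downstream (default 10,000).
    min_samples_tested
        Bins overlapped by fewer distinct samples than this are scored but
        not tested (recurrence requires more than one genome; default 2).
    placement
        ``uniform_genome`` relocates each breakpoint anywhere (chromosome
        chosen with probability proportional to its length);
        ``within_chromosome`` keeps each breakpoint's chromosome.
    correction
        ``bh`` (Benjamini–Hochberg step-up FDR, default) or ``bonferroni``.
    pooled_null
        If True, compare each observed score against the pooled distribution
        of permuted scores across all tested bins instead of per-bin.
    merge
        Merge book-ended significant bins into single reported hotspots.
    """

    n_perm: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    flank: int = 10_000
    min_samples_tested: int = 2
    placement: str = "uniform_genome"
    correction: str = "bh"
    pooled_null: bool = False
    merge: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be ≥ 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")
        if self.placement not in ("uniform_genome", "within_chromosome"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.correction not in ("bh", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class HotspotResult:
    """Output of :func:`call_hotspots`.

    ``hotspots`` holds the significant (optionally merged) bins; ``all_bins``
    the full scored segmentation with p/q values on tested bins; ``config``
    the exact permutation configuration that produced them.
    """

    hotspots: pd.DataFrame
    all_bins: pd.DataFrame
    config: PermutationConfig


# ---------------------------------------------------------------------------
# extension and segmentation


def extend_breakpoints(
    profile: BreakpointProfile, flank: int, genome: GenomeAssembly
) -> pd.DataFrame:
    """Extend each breakpoint to ``[pos - flank, pos + flank + 1)``, clipped.

    Returns a frame with columns chrom, start, end, sample_id — one region
    per breakpoint.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    rows = []
    for bp in profile.breakpoints:
        start, end = genome.clip(bp.chrom, bp.pos - flank, bp.pos + flank + 1)
        rows.append((bp.chrom, start, end, profile.sample_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id"])


def _profiles_to_arrays(
    profiles: Sequence[BreakpointProfile], genome: GenomeAssembly
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per profile: (chromosome index array, position array), validated."""
    out = []
    for prof in profiles:
        prof.validate(genome)
        cidx = np.array([genome.index_of(bp.chrom) for bp in prof.breakpoints], dtype=np.int64)
        pos = np.array([bp.pos for bp in prof.breakpoints], dtype=np.int64)
        out.append((cidx, pos))
    return out


class _BinIndex:
    """Per-chromosome sorted bin arrays plus a distinct-sample scorer."""

    def __init__(self, bins: pd.DataFrame, genome: GenomeAssembly, n_samples: int):
        self.genome = genome
        self.n_samples = n_samples
        self.n_bins = len(bins)
        self.by_chrom: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in bins.groupby("chrom", sort=False):
            ci = genome.index_of(chrom)
            self.by_chrom[ci] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp.index.to_numpy(np.int64),
            )

    def score(
        self,
        samples: Sequence[tuple[np.ndarray, np.ndarray]],
        flank: int,
    ) -> np.ndarray:
        """Distinct-sample count per bin for flank-extended positions."""
        lengths = self.genome.lengths
        counts = np.zeros(self.n_bins, dtype=np.int64)
        for cidx, pos in samples:
            covered: list[np.ndarray] = []
            for ci, (starts, ends, gidx) in self.by_chrom.items():
                mask = cidx == ci
                if not mask.any():
                    continue
                p = pos[mask]
                a = np.maximum(p - flank, 0)
                b = np.minimum(p + flank + 1, lengths[ci])
                lo = np.searchsorted(ends, a, side="right")
                hi = np.searchsorted(starts, b, side="left")
                keep = lo < hi
                if not keep.any():
                    continue
                diff = np.zeros(len(starts) + 1, dtype=np.int32)
                np.add.at(diff, lo[keep], 1)
                np.add.at(diff, hi[keep], -1)
                hit = np.cumsum(diff[:-1]) > 0
                covered.append(gidx[hit])
            if covered:
                counts[np.concatenate(covered)] += 1
        return counts


def segment_by_boundaries(
    regions: pd.DataFrame,
    genome: GenomeAssembly,
    min_samples_tested: int = 2,
) -> pd.DataFrame:
    """Segment the genome at all region boundaries and score the bins.

    ``regions`` is the concatenation of all samples' extended regions
    (columns chrom, start, end, sample_id). Per chromosome, the sorted
    distinct starts and ends of the regions become bin boundaries;
    consecutive boundaries form half-open bins. Bins covered by no region
    are dropped. Each bin's score is the number of distinct samples with at
    least one overlapping region, and ``tested`` marks bins with
    score ≥ ``min_samples_tested``.
    """
    frames = []
    for chrom in genome.names:
        grp = regions[regions["chrom"] == chrom]
        if grp.empty:
            continue
        bounds = np.unique(
            np.concatenate([grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)])
        )
        starts, ends = bounds[:-1], bounds[1:]
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not frames:
        bins = pd.DataFrame(columns=list(BIN_COLUMNS))
        return bins.astype({"start": np.int64, "end": np.int64, "score": np.int64, "tested": bool})
    bins = pd.concat(frames, ignore_index=True)

    sample_ids = regions["sample_id"].unique()
    index = _BinIndex(bins, genome, len(sample_ids))
    counts = np.zeros(len(bins), dtype=np.int64)
    for sid in sample_ids:
        sgrp = regions[regions["sample_id"] == sid]
        covered = []
        for ci, (bstarts, bends, gidx) in index.by_chrom.items():
            cgrp = sgrp[sgrp["chrom"] == genome.names[ci]]
            if cgrp.empty:
                continue
            a = cgrp["start"].to_numpy(np.int64)
            b = cgrp["end"].to_numpy(np.int64)
            lo = np.searchsorted(bends, a, side="right")
            hi = np.searchsorted(bstarts, b, side="left")
            keep = lo < hi
            if not keep.any():
                continue
            diff = np.zeros(len(bstarts) + 1, dtype=np.int32)
            np.add.at(diff, lo[keep], 1)
            np.add.at(diff, hi[keep], -1)
            hit = np.cumsum(diff[:-1]) > 0
            covered.append(gidx[hit])
        if covered:
            counts[np.concatenate(covered)] += 1

    bins["score"] = counts
    bins = bins[bins["score"] > 0].reset_index(drop=True)
    bins["tested"] = bins["score"] >= min_samples_tested
    bins["p_value"] = np.nan
    bins["q_value"] = np.nan
    return bins


# ---------------------------------------------------------------------------
# permutation null


def _permuted_positions(
    observed: Sequence[tuple[np.ndarray, np.ndarray]],
    genome: GenomeAssembly,
    rng: np.random.Generator,
    placement: str = "uniform_genome",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Relocate every breakpoint of every sample; one uniform draw per breakpoint.

    Draw order is per profile, in input order — the contract that makes the
    object-level and array-level permutation paths produce identical streams.
    """
    lengths = genome.lengths
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = offsets[-1]
    out = []
    for cidx, pos in observed:
        n = len(pos)
        u = rng.random(n)
        if placement == "uniform_genome":
            scaled = u * total
            new_cidx = np.searchsorted(offsets[1:], scaled, side="right")
            new_pos = np.minimum(
                (scaled - offsets[new_cidx]).astype(np.int64), lengths[new_cidx] - 1
            )
        else:  # within_chromosome
            new_cidx = cidx.copy()
            new_pos = np.minimum((u * lengths[cidx]).astype(np.int64), lengths[cidx] - 1)
        out.append((new_cidx, new_pos))
    return out


def permute_profiles(
    profiles: Sequence[BreakpointProfile],
    genome: GenomeAssembly,
    rng: np.random.Generator,
    placement: str = "uniform_genome",
) -> list[BreakpointProfile]:
    """One genome-wide randomization of all samples' breakpoints.

    Each sample keeps its breakpoint count; each breakpoint is relocated
    independently and uniformly over the genome (chromosome with probability
    proportional to length, position uniform on it), keeping its event-type
    label. Pass a seeded ``numpy.random.Generator`` for reproducibility.
    """
    observed = _profiles_to_arrays(profiles, genome)
    permuted = _permuted_positions(observed, genome, rng, placement)
    names = genome.names
    out = []
    for prof, (cidx, pos) in zip(profiles, permuted):
        bps = tuple(
            Breakpoint(
                chrom=names[ci],
                pos=int(p),
                sample_id=prof.sample_id,
                event_type=bp.event_type,
            )
            for bp, ci, p in zip(prof.breakpoints, cidx, pos)
        )
        out.append(
            BreakpointProfile(
                sample_id=prof.sample_id, breakpoints=bps, cancer_type=prof.cancer_type
            )
        )
    return out


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def empirical_pvalues(
    observed_bins: pd.DataFrame,
    profiles: Sequence[BreakpointProfile],
    genome: GenomeAssembly,
    cfg: PermutationConfig,
) -> pd.DataFrame:
    """Fill per-bin empirical p-values on the fixed observed segmentation.

    For each of ``cfg.n_perm`` permutations, all breakpoints are relocated,
    re-extended by ``cfg.flank``, and the distinct-sample score of every
    observed bin recomputed. The upper-tail p-value of a tested bin is
    ``(1 + #{permutations with permuted score ≥ observed}) / (n_perm + 1)``;
    ties count toward the tail. Untested bins keep p = NaN.
    """
    bins = observed_bins.copy()
    if bins.empty:
        return bins
    observed = _profiles_to_arrays(profiles, genome)
    index = _BinIndex(bins[["chrom", "start", "end"]], genome, len(profiles))
    obs_scores = bins["score"].to_numpy(np.int64)
    tested = bins["tested"].to_numpy(bool)

    exceed = np.zeros(len(bins), dtype=np.int64)
    if cfg.pooled_null:
        # histogram of permuted scores over tested bins; scores ≤ n_samples
        pooled_hist = np.zeros(len(profiles) + 1, dtype=np.int64)

    for rng in _spawn_rngs(cfg.seed, cfg.n_perm):
        permuted = _permuted_positions(observed, genome, rng, cfg.placement)
        perm_scores = index.score(permuted, cfg.flank)
        exceed += perm_scores >= obs_scores
        if cfg.pooled_null:
            np.add.at(pooled_hist, perm_scores[tested], 1)

    p = np.full(len(bins), np.nan)
    if cfg.pooled_null:
        pooled_total = int(pooled_hist.sum())
        tail = np.cumsum(pooled_hist[::-1])[::-1]  # tail[s] = #{scores ≥ s}
        p[tested] = (1 + tail[obs_scores[tested]]) / (pooled_total + 1)
    else:
        p[tested] = (1 + exceed[tested]) / (cfg.n_perm + 1)
    bins["p_value"] = p
    return bins


# ---------------------------------------------------------------------------
# multiple-testing correction and hotspot selection


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, take ``q_i = min_{j ≥ i} (m * p_j / j)`` capped at 1.
    Inputs must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def merge_book_ended(bins: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent (end == next start, same chromosome) bins.

    A merged hotspot spans the union; its score is the maximum member score
    and its p/q values the minimum member values.
    """
    if bins.empty:
        return bins.copy()
    bins = bins.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    group = np.zeros(len(bins), dtype=np.int64)
    g = 0
    for i in range(1, len(bins)):
        prev, cur = bins.iloc[i - 1], bins.iloc[i]
        if not (cur["chrom"] == prev["chrom"] and cur["start"] == prev["end"]):
            g += 1
        group[i] = g
    merged = (
        bins.assign(_g=group)
        .groupby("_g", sort=True)
        .agg(
            chrom=("chrom", "first"),
            start=("start", "min"),
            end=("end", "max"),
            score=("score", "max"),
            tested=("tested", "all"),
            p_value=("p_value", "min"),
            q_value=("q_value", "min"),
        )
        .reset_index(drop=True)
    )
    return merged


def call_hotspots(
    profiles: Sequence[BreakpointProfile],
    genome: GenomeAssembly,
    cfg: PermutationConfig = PermutationConfig(),
) -> HotspotResult:
    """End-to-end hotspot calling: extend → segment → permute → correct → select.

    Requires at least two profiles — a hotspot is a recurrence statement and
    cannot be defined on a single genome. With a fixed seed and config the
    result is bit-reproducible.
    """
    if len(profiles) < 2:
        raise ValueError(
            "hotspot calling needs ≥ 2 profiles: a hotspot is a region recurrently "
            "hit across samples, undefined for a single genome"
        )
    regions = pd.concat(
        [extend_breakpoints(p, cfg.flank, genome) for p in profiles], ignore_index=True
    )
    bins = segment_by_boundaries(regions, genome, cfg.min_samples_tested)
    bins = empirical_pvalues(bins, profiles, genome, cfg)

    tested = bins["tested"].to_numpy(bool)
    q = np.full(len(bins), np.nan)
    if tested.any():
        p_tested = bins.loc[tested, "p_value"].to_numpy(float)
        if cfg.correction == "bh":
            q[tested] = bh_adjust(p_tested)
        else:
            q[tested] = np.minimum(p_tested * tested.sum(), 1.0)
    bins["q_value"] = q

    sig = bins[tested & (q < cfg.alpha)].reset_index(drop=True)
    hotspots = merge_book_ended(sig) if cfg.merge else sig
    return HotspotResult(hotspots=hotspots, all_bins=bins, config=cfg)


# ---------------------------------------------------------------------------
# cohort summary arithmetic


def summarize_counts(counts: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Cohort summary from per-group (n_samples, n_breakpoints) counts.

    Returns one row per group — n_samples, n_breakpoints, and the
    per-genome average as floor(n_breakpoints / n_samples) — plus a Total
    row with the grand sums and floor(grand total / total samples). Groups
    with zero samples are omitted with a warning.
    """
    rows = []
    for label, (n_samples, n_bps) in counts.items():
        if n_samples <= 0:
            warnings.warn(f"group {label!r} has no samples; omitted from summary")
            continue
        rows.append((label, int(n_samples), int(n_bps), int(n_bps) // int(n_samples)))
    columns = ["cancer_type", "n_samples", "n_breakpoints", "breakpoints_per_genome"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows, columns=columns)
    total_samples = int(df["n_samples"].sum())
    total_bps = int(df["n_breakpoints"].sum())
    total = pd.DataFrame(
        [("Total", total_samples, total_bps, total_bps // total_samples)], columns=columns
    )
    return pd.concat([df, total], ignore_index=True)


def summarize_profiles(profiles: Sequence[BreakpointProfile]) -> pd.DataFrame:
    """Cohort summary (samples, breakpoints, per-genome average) by cancer type."""
    counts: dict[str, tuple[int, int]] = {}
    for prof in profiles:
        label = prof.cancer_type or "unlabelled"
        n_s, n_b = counts.get(label, (0, 0))
        counts[label] = (n_s + 1, n_b + len(prof))
    return summarize_counts(counts)
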