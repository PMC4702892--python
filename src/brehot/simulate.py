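"""Synthetic breakpoint-profile generator with known ground truth.

Emulates per-sample somatic breakpoint profiles: a uniform genome-wide
background of alterations (chromosome chosen proportional to length),
optional recurrent hotspot loci hit by a configurable fraction of samples
(penetrance), an event-type mixture over the closed event set, synthetic
mates at ``size_range`` distances for intra-chromosomal events (so size
filtering is exercised), and read-support counts from ``support_range``.
The simulation unit is the breakpoint: each simulated event contributes one
profile breakpoint at its primary locus, with the mate kept on the
alteration record as annotation.

Ground truth tables make exact precision/recall of hotspot calling and of
germline subtraction computable on any simulated instance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAssembly
from .records import EVENT_TYPES, AlterationRecord, Breakpoint, BreakpointProfile

__all__ = [
    "DEFAULT_EVENT_WEIGHTS",
    "SimulationConfig",
    "SimulationResult",
    "GermlinePair",
    "toy_genome",
    "simulate_profiles",
    "simulate_germline_pair",
]

#: Default event-type mixture: deletion-dominated, as somatic SV spectra are.
DEFAULT_EVENT_WEIGHTS: dict[str, float] = {
    "DEL": 0.30,
    "TDUP": 0.15,
    "INS": 0.10,
    "INV": 0.15,
    "TRA_INTRA": 0.10,
    "TRA_INTER": 0.15,
    "COMPLEX": 0.05,
}

#: Event types that get a synthetic same-chromosome mate at a size_range distance.
_MATED_INTRA = ("DEL", "TDUP", "INV", "TRA_INTRA", "COMPLEX")


def toy_genome() -> GenomeAssembly:
    """Three-chromosome 100 Mb toy genome (50 + 30 + 20 Mb).

    Large enough for hotspot-calibration experiments, small enough for
    seconds-scale tests.
    """
    return GenomeAssembly([("chr1", 50_000_000), ("chr2", 30_000_000), ("chr3", 20_000_000)])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    hotspot_loci are ``(chrom, center, half_width, penetrance)`` tuples: a
    sample hits the locus with probability ``penetrance`` and, if it does,
    receives one breakpoint uniform in ``center ± half_width``.
    """

    genome: GenomeAssembly = field(default_factory=toy_genome)
    n_samples: int = 20
    background_per_sample: int = 50
    hotspot_loci: tuple[tuple[str, int, int, float], ...] = ()
    event_type_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_WEIGHTS)
    )
    size_range: tuple[int, int] = (1_000, 1_000_000)
    support_range: tuple[int, int] = (2, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")
        if self.background_per_sample < 0:
            raise ValueError("background_per_sample must be non-negative")
        for chrom, center, half_width, penetrance in self.hotspot_loci:
            self.genome.validate_position(chrom, center)
            if half_width < 0:
                raise ValueError("hotspot half_width must be non-negative")
            if not 0.0 <= penetrance <= 1.0:
                raise ValueError(f"penetrance {penetrance} outside [0, 1]")
        weights = dict(self.event_type_weights)
        unknown = set(weights) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"unknown event type(s) in weights: {sorted(unknown)}")
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("event weights must be non-negative and not all zero")
        for name in ("size_range", "support_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 ≤ min ≤ max")


@dataclass(frozen=True)
class SimulationResult:
    """Profiles, the alteration records behind them, and planted-locus truth.

    ``truth`` has one row per (locus, sample): locus_id, chrom, center,
    half_width, penetrance, sample_id, hit, pos (-1 when the sample missed
    the locus).
    """

    profiles: tuple[BreakpointProfile, ...]
    records: dict[str, list[AlterationRecord]]
    truth: pd.DataFrame


@dataclass(frozen=True)
class GermlinePair:
    """Matched cancer/pooled-normal simulation for germline subtraction.

    ``labels`` has one row per cancer record: sample_id, record_index,
    label ('somatic' or 'germline').
    """

    cancer_records: dict[str, list[AlterationRecord]]
    normal_records: list[AlterationRecord]
    labels: pd.DataFrame


def _uniform_positions(
    n: int, genome: GenomeAssembly, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    lengths = genome.lengths
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    scaled = rng.random(n) * offsets[-1]
    cidx = np.searchsorted(offsets[1:], scaled, side="right")
    pos = np.minimum((scaled - offsets[cidx]).astype(np.int64), lengths[cidx] - 1)
    return cidx, pos


def _make_record(
    sample_id: str,
    chrom: str,
    pos: int,
    event_type: str,
    genome: GenomeAssembly,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> AlterationRecord:
    """Build one alteration anchored at (chrom, pos) with a synthetic mate."""
    lo, hi = cfg.support_range
    discordant = int(rng.integers(lo, hi + 1))
    softclip = int(rng.integers(lo, hi + 1))
    mate: Optional[tuple[str, int]] = None
    if event_type in _MATED_INTRA:
        smin, smax = cfg.size_range
        size = int(rng.integers(smin, smax + 1))
        length = genome.length_of(chrom)
        direction = 1 if rng.random() < 0.5 else -1
        mate_pos = pos + direction * size
        if not 0 <= mate_pos < length:
            mate_pos = pos - direction * size
        mate_pos = min(max(mate_pos, 0), length - 1)
        mate = (chrom, mate_pos)
    elif event_type == "TRA_INTER" and len(genome) > 1:
        others = [i for i, name in enumerate(genome.names) if name != chrom]
        oc = others[int(rng.integers(0, len(others)))]
        oname, olen = genome.chromosomes[oc]
        mate = (oname, int(rng.integers(0, olen)))
    bp1 = Breakpoint(chrom=chrom, pos=pos, sample_id=sample_id, event_type=event_type, mate=mate)
    bp2 = None
    if mate is not None:
        bp2 = Breakpoint(
            chrom=mate[0], pos=mate[1], sample_id=sample_id, event_type=event_type,
            mate=(chrom, pos),
        )
    return AlterationRecord(
        sample_id=sample_id,
        event_type=event_type,
        bp1=bp1,
        bp2=bp2,
        discordant_pairs=discordant,
        softclip_reads=softclip,
    )


def simulate_profiles(cfg: SimulationConfig) -> SimulationResult:
    """Simulate a cohort of breakpoint profiles under ``cfg``.

    Each sample receives ``background_per_sample`` breakpoints uniform over
    the genome plus, per hotspot locus, one breakpoint within ±half_width
    with probability penetrance. Fixed seed → bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    event_names = list(cfg.event_type_weights)
    weights = np.array([cfg.event_type_weights[e] for e in event_names], dtype=float)
    weights = weights / weights.sum()

    profiles: list[BreakpointProfile] = []
    records: dict[str, list[AlterationRecord]] = {}
    truth_rows = []
    for i in range(cfg.n_samples):
        sample_id = f"sample_{i + 1:03d}"
        recs: list[AlterationRecord] = []
        cidx, pos = _uniform_positions(cfg.background_per_sample, cfg.genome, rng)
        etypes = rng.choice(len(event_names), size=cfg.background_per_sample, p=weights)
        for ci, p, ei in zip(cidx, pos, etypes):
            recs.append(
                _make_record(
                    sample_id, cfg.genome.names[ci], int(p), event_names[ei], cfg.genome, cfg, rng
                )
            )
        for locus_id, (chrom, center, half_width, penetrance) in enumerate(cfg.hotspot_loci):
            hit = bool(rng.random() < penetrance)
            hit_pos = -1
            if hit:
                length = cfg.genome.length_of(chrom)
                offset = int(rng.integers(-half_width, half_width + 1)) if half_width else 0
                hit_pos = min(max(center + offset, 0), length - 1)
                ei = int(rng.choice(len(event_names), p=weights))
                recs.append(
                    _make_record(
                        sample_id, chrom, hit_pos, event_names[ei], cfg.genome, cfg, rng
                    )
                )
            truth_rows.append(
                (locus_id, chrom, center, half_width, penetrance, sample_id, hit, hit_pos)
            )
        records[sample_id] = recs
        profiles.append(
            BreakpointProfile(
                sample_id=sample_id,
                breakpoints=tuple(r.bp1 for r in recs),
                cancer_type="simulated",
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "locus_id", "chrom", "center", "half_width", "penetrance",
            "sample_id", "hit", "pos",
        ],
    )
    return SimulationResult(profiles=tuple(profiles), records=records, truth=truth)


def simulate_germline_pair(
    cfg: SimulationConfig, shared_fraction: float, jitter: int = 50
) -> GermlinePair:
    """Simulate cancer profiles with a fraction of records shared with normals.

    ``round(shared_fraction * n)`` records of each cancer sample are
    duplicated into the pooled normal set with positions perturbed by at
    most ``jitter`` bases per breakpoint, and labelled 'germline'; the rest
    are 'somatic'. Subtracting the normals at a matching tolerance
    (≥ jitter) must therefore remove exactly the germline-labelled records.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    sim = simulate_profiles(cfg)
    rng = np.random.default_rng([cfg.seed, 7])  # separate stream from the cohort draw
    normals: list[AlterationRecord] = []
    label_rows = []
    for sample_id, recs in sim.records.items():
        n_germ = int(round(shared_fraction * len(recs)))
        germ_idx = set(
            rng.choice(len(recs), size=n_germ, replace=False).tolist()
        ) if n_germ else set()
        for j, rec in enumerate(recs):
            is_germ = j in germ_idx
            label_rows.append((sample_id, j, "germline" if is_germ else "somatic"))
            if not is_germ:
                continue
            shifted = []
            for bp in rec.breakpoints:
                delta = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                length = cfg.genome.length_of(bp.chrom)
                shifted.append(min(max(bp.pos + delta, 0), length - 1))
            bp1 = replace(rec.bp1, pos=shifted[0], sample_id="pooled_normal", mate=None)
            bp2 = None
            if rec.bp2 is not None:
                bp2 = replace(rec.bp2, pos=shifted[1], sample_id="pooled_normal", mate=None)
            normals.append(
                AlterationRecord(
                    sample_id="pooled_normal",
                    event_type=rec.event_type,
                    bp1=bp1,
                    bp2=bp2,
                    discordant_pairs=rec.discordant_pairs,
                    softclip_reads=rec.softclip_reads,
                )
            )
    labels = pd.DataFrame(label_rows, columns=["sample_id", "record_index", "label"])
    return GermlinePair(cancer_records=sim.records, normal_records=normals, labels=labels)
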