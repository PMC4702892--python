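"""Domain records: breakpoints, structural alterations, per-sample profiles.

A genomic alteration (GA) is a large structural event — deletion, insertion,
inversion, tandem duplication, intra-/inter-chromosomal translocation, or a
complex combination — anchored at one or two single-base breakpoints.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .genome import GenomeAssembly, GenomeError

__all__ = [
    "EVENT_TYPES",
    "Breakpoint",
    "AlterationRecord",
    "BreakpointProfile",
    "profile_from_records",
]

#: Closed set of structural-alteration event classes.
EVENT_TYPES: tuple[str, ...] = (
    "DEL",
    "INS",
    "INV",
    "TDUP",
    "TRA_INTRA",
    "TRA_INTER",
    "COMPLEX",
)

#: Event types whose two breakpoints lie on the same chromosome, so a size
#: (|pos2 - pos1|) is defined when both breakpoints are present.
INTRA_EVENT_TYPES = frozenset({"DEL", "INS", "INV", "TDUP", "TRA_INTRA", "COMPLEX"})


class RecordError(ValueError):
    """Invalid record content (bad event token, coordinate, or shape)."""


def _check_event_type(event_type: str) -> str:
    if event_type not in EVENT_TYPES:
        raise RecordError(
            f"unknown event type {event_type!r}; accepted tokens: {', '.join(EVENT_TYPES)}"
        )
    return event_type


@dataclass(frozen=True, slots=True)
class Breakpoint:
    """A single-nucleotide breakpoint locus.

    ``mate`` optionally records the partner locus of the alteration as a
    ``(chrom, pos)`` pair; it is annotation only and does not itself count as
    a breakpoint of this object.
    """

    chrom: str
    pos: int
    sample_id: str
    event_type: str
    mate: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        _check_event_type(self.event_type)
        if self.pos < 0:
            raise RecordError(f"negative breakpoint position {self.pos}")


@dataclass(frozen=True, slots=True)
class AlterationRecord:
    """One structural alteration with its breakpoint(s) and read support.

    ``size`` is |pos(bp2) - pos(bp1)| for intra-chromosomal events with both
    breakpoints present, and ``None`` (undefined) for inter-chromosomal
    translocations or single-breakpoint events; an undefined size is never
    compared against the size filter.
    """

    sample_id: str
    event_type: str
    bp1: Breakpoint
    bp2: Optional[Breakpoint] = None
    discordant_pairs: int = 0
    softclip_reads: int = 0
    size: Optional[int] = field(default=None)

    def __post_init__(self) -> None:
        _check_event_type(self.event_type)
        if self.discordant_pairs < 0 or self.softclip_reads < 0:
            raise RecordError("read-support counts must be non-negative")
        if (
            self.bp2 is not None
            and self.event_type in INTRA_EVENT_TYPES
            and self.bp1.chrom == self.bp2.chrom
        ):
            derived = abs(self.bp2.pos - self.bp1.pos)
            if self.size is None:
                object.__setattr__(self, "size", derived)
            elif self.size != derived:
                raise RecordError(
                    f"declared size {self.size} inconsistent with breakpoints "
                    f"({self.bp1.pos}, {self.bp2.pos})"
                )

    @property
    def breakpoints(self) -> tuple[Breakpoint, ...]:
        """All defined breakpoints of this alteration (bp1, and bp2 if present)."""
        return (self.bp1,) if self.bp2 is None else (self.bp1, self.bp2)

    def validate(self, genome: GenomeAssembly) -> None:
        for bp in self.breakpoints:
            genome.validate_position(bp.chrom, bp.pos)
            if bp.mate is not None:
                genome.validate_position(bp.mate[0], bp.mate[1])


@dataclass(frozen=True)
class BreakpointProfile:
    """All breakpoints of one sample; the unit the hotspot test counts over."""

    sample_id: str
    breakpoints: tuple[Breakpoint, ...]
    cancer_type: str = ""

    def __post_init__(self) -> None:
        bps = tuple(self.breakpoints)
        for bp in bps:
            if bp.sample_id != self.sample_id:
                raise RecordError(
                    f"breakpoint sample_id {bp.sample_id!r} differs from profile "
                    f"sample_id {self.sample_id!r}"
                )
        object.__setattr__(self, "breakpoints", bps)

    def __len__(self) -> int:
        return len(self.breakpoints)

    def validate(self, genome: GenomeAssembly) -> None:
        for bp in self.breakpoints:
            genome.validate_position(bp.chrom, bp.pos)


def profile_from_records(
    records: Sequence[AlterationRecord],
    sample_id: Optional[str] = None,
    cancer_type: str = "",
) -> BreakpointProfile:
    """Expand alteration records into a per-sample breakpoint profile.

    An intra-chromosomal alteration contributes two breakpoints (bp1, bp2),
    an insertion one, and an inter-chromosomal translocation one per
    chromosome side — each defined breakpoint becomes one profile entry.
    """
    if sample_id is None:
        ids = {r.sample_id for r in records}
        if len(ids) != 1:
            raise RecordError(
                "records carry multiple sample_ids; pass sample_id explicitly"
            )
        sample_id = next(iter(ids))
    bps: list[Breakpoint] = []
    for rec in records:
        for bp in rec.breakpoints:
            if bp.sample_id != sample_id:
                bp = replace(bp, sample_id=sample_id)
            bps.append(bp)
    return BreakpointProfile(sample_id=sample_id, breakpoints=tuple(bps), cancer_type=cancer_type)
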