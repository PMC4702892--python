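"""Reading and writing of on-disk formats.

Formats (all tab-separated text, 0-based half-open coordinates):

* chrom-sizes: standard two-column UCSC format (see :mod:`brehot.genome`).
* profile BED dialect: one alteration per line with columns
  ``chrom  start  end  event_type  discordant_pairs  softclip_reads  mate``
  where ``start`` is the breakpoint position, ``end = start + 1`` for point
  breakpoints, ``event_type`` is one of DEL, INS, INV, TDUP, TRA_INTRA,
  TRA_INTER, COMPLEX, and ``mate`` is the partner locus as ``chrom:pos`` or
  ``.``. Missing support columns parse as 0 (so unfiltered inputs are
  visibly rejected by the support filter rather than passing silently).
  Lines starting with ``#`` or ``track`` are ignored.
* blacklist: plain 3-column BED.
* results: TSV with a header, one row per bin/hotspot.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome import GenomeAssembly, GenomeError
from .records import (
    EVENT_TYPES,
    AlterationRecord,
    Breakpoint,
    BreakpointProfile,
    RecordError,
)

__all__ = [
    "read_profile",
    "write_profile",
    "read_blacklist",
    "write_results",
    "write_display_bed",
]

RESULT_COLUMNS = ("chrom", "start", "end", "score", "p", "q")


class ProfileParseError(ValueError):
    """Malformed profile/blacklist file; message names the offending line."""


def _parse_mate(token: str, lineno: int, path: Path) -> Optional[tuple[str, int]]:
    if token in (".", ""):
        return None
    chrom, sep, pos = token.rpartition(":")
    if not sep:
        raise ProfileParseError(
            f"{path}:{lineno}: mate locus {token!r} is not 'chrom:pos' or '.'"
        )
    try:
        return chrom, int(pos)
    except ValueError:
        raise ProfileParseError(
            f"{path}:{lineno}: mate position {pos!r} is not an integer"
        ) from None


def read_profile(
    path: str | Path,
    genome: GenomeAssembly,
    sample_id: Optional[str] = None,
    cancer_type: str = "",
) -> list[AlterationRecord]:
    """Read one sample's alterations from the profile BED dialect.

    ``sample_id`` defaults to the file name stem (one file per sample).
    Records are validated against ``genome``: unknown chromosomes,
    out-of-range positions and unknown event tokens raise.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    records: list[AlterationRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected ≥4 tab-separated columns "
                    f"(chrom, start, end, event_type), got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ProfileParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from None
            if end <= start:
                raise ProfileParseError(
                    f"{path}:{lineno}: empty/inverted interval [{start}, {end})"
                )
            event_type = fields[3]
            if event_type not in EVENT_TYPES:
                raise ProfileParseError(
                    f"{path}:{lineno}: unknown event type {event_type!r}; "
                    f"accepted tokens: {', '.join(EVENT_TYPES)}"
                )
            discordant = int(fields[4]) if len(fields) > 4 and fields[4] != "." else 0
            softclip = int(fields[5]) if len(fields) > 5 and fields[5] != "." else 0
            mate = _parse_mate(fields[6], lineno, path) if len(fields) > 6 else None

            try:
                genome.validate_position(chrom, start)
                bp2 = None
                if mate is not None:
                    genome.validate_position(mate[0], mate[1])
                    bp2 = Breakpoint(
                        chrom=mate[0],
                        pos=mate[1],
                        sample_id=sample_id,
                        event_type=event_type,
                        mate=(chrom, start),
                    )
                bp1 = Breakpoint(
                    chrom=chrom,
                    pos=start,
                    sample_id=sample_id,
                    event_type=event_type,
                    mate=mate,
                )
                records.append(
                    AlterationRecord(
                        sample_id=sample_id,
                        event_type=event_type,
                        bp1=bp1,
                        bp2=bp2,
                        discordant_pairs=discordant,
                        softclip_reads=softclip,
                    )
                )
            except (GenomeError, RecordError) as exc:
                raise ProfileParseError(f"{path}:{lineno}: {exc}") from None
    return records


def write_profile(records: Sequence[AlterationRecord], path: str | Path) -> None:
    """Write alterations in the profile BED dialect (inverse of :func:`read_profile`)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            mate = f"{rec.bp2.chrom}:{rec.bp2.pos}" if rec.bp2 is not None else "."
            fh.write(
                f"{rec.bp1.chrom}\t{rec.bp1.pos}\t{rec.bp1.pos + 1}\t"
                f"{rec.event_type}\t{rec.discordant_pairs}\t{rec.softclip_reads}\t{mate}\n"
            )


def read_blacklist(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a plain 3-column BED of intervals to exclude (half-open)."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected ≥3 columns (chrom, start, end)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ProfileParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if end <= start:
                raise ProfileParseError(
                    f"{path}:{lineno}: empty/inverted interval [{start}, {end})"
                )
            intervals.append((fields[0], start, end))
    return intervals


def write_results(bins: pd.DataFrame, path: str | Path) -> None:
    """Write scored bins/hotspots as a header-bearing TSV.

    Columns written: chrom, start, end, score, p, q. Accepts the DataFrames
    produced by :mod:`brehot.hotspots` (``p_value``/``q_value`` are renamed).
    """
    out = bins.rename(columns={"p_value": "p", "q_value": "q"})
    missing = [c for c in RESULT_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"results frame missing column(s): {', '.join(missing)}")
    out = out.loc[:, list(RESULT_COLUMNS)]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_display_bed(
    profile: BreakpointProfile,
    flank: int,
    genome: GenomeAssembly,
    path: str | Path,
) -> None:
    """Write each breakpoint as a flanked display interval.

    Each breakpoint becomes ``[pos - flank, pos + flank + 1)`` clipped to its
    chromosome — with the default 10 kb flank, a ~20 kb bar centred on the
    breakpoint, matching how profile tracks are conventionally rendered.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    with open(path, "w") as fh:
        for bp in profile.breakpoints:
            start, end = genome.clip(bp.chrom, bp.pos - flank, bp.pos + flank + 1)
            fh.write(f"{bp.chrom}\t{start}\t{end}\t{bp.event_type}\n")
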