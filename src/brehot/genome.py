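"""Genome assembly model: the coordinate universe for all intervals.

All coordinates throughout the package are 0-based, half-open (BED-native),
both on disk and in memory.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = ["GenomeAssembly", "read_chrom_sizes"]


class GenomeError(ValueError):
    """Invalid genome definition or coordinate outside the genome."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosomes with lengths in bases.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length)`` pairs in assembly order. Names must be
        unique and lengths strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        if not chroms:
            raise GenomeError("assembly must contain at least one chromosome")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GenomeError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for n, l in chroms:
            if l <= 0:
                raise GenomeError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_index", {n: i for i, (n, _) in enumerate(chroms)})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([l for _, l in self.chromosomes], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length_of(self, name: str) -> int:
        try:
            return self.chromosomes[self._index[name]][1]
        except KeyError:
            raise GenomeError(f"chromosome {name!r} not in assembly") from None

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise GenomeError(f"chromosome {name!r} not in assembly") from None

    def validate_position(self, chrom: str, pos: int) -> None:
        length = self.length_of(chrom)
        if not 0 <= pos < length:
            raise GenomeError(
                f"position {pos} outside chromosome {chrom!r} (length {length})"
            )

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Clip a half-open interval to ``[0, length(chrom))`` bounds."""
        length = self.length_of(chrom)
        return max(0, start), min(length, end)


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a UCSC-style two-column chrom-sizes file.

    Each non-empty line is ``name<whitespace>length``. File order is
    preserved; duplicate names and non-positive lengths are rejected.
    """
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GenomeError(f"{path}:{lineno}: expected 'name length', got {raw!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise GenomeError(
                    f"{path}:{lineno}: length {fields[1]!r} is not an integer"
                ) from None
            if length <= 0:
                raise GenomeError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            chroms.append((name, length))
    if not chroms:
        raise GenomeError(f"{path}: empty chrom-sizes file — assembly is unusable")
    names = [n for n, _ in chroms]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise GenomeError(f"{path}: duplicate chromosome name(s): {', '.join(dup)}")
    return GenomeAssembly(chroms)
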