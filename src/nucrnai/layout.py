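"""Genome coordinate system: chromosomes and a fixed-width bin grid.

Every track, ratio, and region in this package is expressed against a
:class:`GenomeLayout`.  Bins are 0-based, half-open, non-overlapping and
genome-ordered; a trailing remainder shorter than ``bin_size`` at a
chromosome end carries no bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["GenomeLayout", "LayoutError"]


class LayoutError(ValueError):
    """Raised for inconsistent coordinates or mismatched layouts."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes, their lengths, and a fixed bin width.

    Parameters
    ----------
    chromosomes:
        Chromosome names in genome order.
    lengths:
        Chromosome lengths in bp, parallel to ``chromosomes``.
    bin_size:
        Width of every bin in bp.
    """

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int

    # derived, filled in __post_init__
    _n_bins_per_chrom: tuple[int, ...] = field(init=False, repr=False, compare=False)
    _offsets: tuple[int, ...] = field(init=False, repr=False, compare=False)
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        chroms = tuple(str(c) for c in self.chromosomes)
        lengths = tuple(int(l) for l in self.lengths)
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "lengths", lengths)
        if len(chroms) != len(lengths):
            raise LayoutError("chromosomes and lengths differ in length")
        if len(set(chroms)) != len(chroms):
            raise LayoutError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise LayoutError(f"bin_size must be positive, got {self.bin_size}")
        if any(l <= 0 for l in lengths):
            raise LayoutError("chromosome lengths must be positive")
        nb = tuple(l // self.bin_size for l in lengths)
        offs = tuple(int(x) for x in np.concatenate([[0], np.cumsum(nb)[:-1]]))
        object.__setattr__(self, "_n_bins_per_chrom", nb)
        object.__setattr__(self, "_offsets", offs)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(chroms)})

    # ------------------------------------------------------------------ sizes
    @property
    def n_bins(self) -> int:
        """Total bin count: sum over chromosomes of floor(length / bin_size)."""
        return int(sum(self._n_bins_per_chrom))

    def n_bins_of(self, chrom: str) -> int:
        return self._n_bins_per_chrom[self.chrom_id(chrom)]

    def chrom_id(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise LayoutError(f"unknown chromosome {chrom!r}") from None

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.chrom_id(chrom)]

    def offset_of(self, chrom: str) -> int:
        """Global index of the chromosome's first bin."""
        return self._offsets[self.chrom_id(chrom)]

    def chrom_slice(self, chrom: str) -> slice:
        cid = self.chrom_id(chrom)
        return slice(self._offsets[cid], self._offsets[cid] + self._n_bins_per_chrom[cid])

    # ----------------------------------------------------------------- lookup
    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing ``pos``, or -1 for a position in the
        trailing partial-bin remainder of the chromosome."""
        cid = self.chrom_id(chrom)
        if pos < 0 or pos >= self.lengths[cid]:
            raise LayoutError(f"position {pos} outside {chrom} (length {self.lengths[cid]})")
        b = pos // self.bin_size
        if b >= self._n_bins_per_chrom[cid]:
            return -1
        return self._offsets[cid] + b

    def bin_location(self, i: int) -> tuple[str, int, int]:
        """(chrom, start, end) of global bin ``i``; 0-based half-open."""
        if i < 0 or i >= self.n_bins:
            raise LayoutError(f"bin index {i} out of range")
        cid = int(np.searchsorted(self._offsets, i, side="right")) - 1
        local = i - self._offsets[cid]
        start = local * self.bin_size
        return self.chromosomes[cid], start, start + self.bin_size

    def iter_bins(self) -> Iterator[tuple[str, int, int]]:
        for cid, chrom in enumerate(self.chromosomes):
            for b in range(self._n_bins_per_chrom[cid]):
                start = b * self.bin_size
                yield chrom, start, start + self.bin_size

    def global_indices(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bin_index`.

        ``chroms`` is an array of chromosome-id integers (see
        :meth:`chrom_id`); returns -1 for positions in trailing remainders.
        Positions outside chromosome bounds raise.
        """
        chroms = np.asarray(chroms, dtype=np.int64)
        positions = np.asarray(positions, dtype=np.int64)
        lens = np.asarray(self.lengths, dtype=np.int64)[chroms]
        if np.any((positions < 0) | (positions >= lens)):
            bad = int(np.argmax((positions < 0) | (positions >= lens)))
            raise LayoutError(
                f"position {positions[bad]} outside chromosome "
                f"{self.chromosomes[int(chroms[bad])]!r}"
            )
        local = positions // self.bin_size
        nb = np.asarray(self._n_bins_per_chrom, dtype=np.int64)[chroms]
        offs = np.asarray(self._offsets, dtype=np.int64)[chroms]
        out = offs + local
        out[local >= nb] = -1
        return out

    # -------------------------------------------------------------------- IO
    @classmethod
    def from_chrom_sizes(cls, path: str | Path, bin_size: int) -> "GenomeLayout":
        """Build a layout from a two-column tab-separated chrom.sizes file."""
        chroms: list[str] = []
        lengths: list[int] = []
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise LayoutError(f"{path}:{ln}: expected 'name<TAB>length'")
            chroms.append(parts[0])
            try:
                lengths.append(int(parts[1]))
            except ValueError:
                raise LayoutError(f"{path}:{ln}: bad length {parts[1]!r}") from None
        if not chroms:
            raise LayoutError(f"{path}: empty chrom.sizes file")
        return cls(tuple(chroms), tuple(lengths), bin_size)

    def write_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{l}\n" for c, l in zip(self.chromosomes, self.lengths))
        )

    def require_same(self, other: "GenomeLayout") -> None:
        if (
            self.chromosomes != other.chromosomes
            or self.lengths != other.lengths
            or self.bin_size != other.bin_size
        ):
            raise LayoutError("genome layouts do not match")
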