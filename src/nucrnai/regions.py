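"""Labeled genomic interval sets (locus classes, dependency calls, truth).

Intervals are 0-based half-open.  Within a set they are sorted and
non-overlapping; overlapping or book-ended input intervals are merged on
construction unless the set is stranded (stranded sets merge per strand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .layout import GenomeLayout, LayoutError

__all__ = ["Interval", "RegionSet", "BedError", "read_bed", "load_locus_sets"]


class BedError(ValueError):
    """Malformed BED input."""


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals, merging overlaps and book-ended neighbours.

    Strand groups are merged independently so stranded annotations survive.
    """
    out: list[Interval] = []
    for strand in (None, "+", "-"):
        group = sorted(
            (iv for iv in intervals if iv.strand == strand),
            key=lambda iv: (iv.chrom, iv.start, iv.end),
        )
        merged: list[Interval] = []
        for iv in group:
            if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
                prev = merged.pop()
                merged.append(
                    Interval(prev.chrom, prev.start, max(prev.end, iv.end), strand, prev.name)
                )
            else:
                merged.append(iv)
        out.extend(merged)
    return sorted(out, key=lambda iv: (iv.chrom, iv.start, iv.end))


class RegionSet:
    """A labeled collection of disjoint genomic intervals."""

    def __init__(self, label: str, intervals: Iterable[Interval] = ()):  # noqa: D107
        self.label = label
        self.intervals: list[Interval] = _merge(list(intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegionSet)
            and self.label == other.label
            and self.intervals == other.intervals
        )

    def __repr__(self) -> str:
        return f"RegionSet({self.label!r}, n={len(self)}, kb={self.total_kb:g})"

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def total_kb(self) -> float:
        return self.total_bp / 1000.0

    # ----------------------------------------------------------------- grids
    def snapped(self, layout: GenomeLayout) -> "RegionSet":
        """Snap off-grid boundaries outward to the bin grid (with a warning);
        clip interval ends to the binned extent of each chromosome."""
        bs = layout.bin_size
        out: list[Interval] = []
        warned = False
        for iv in self.intervals:
            limit = layout.n_bins_of(iv.chrom) * bs
            start = (iv.start // bs) * bs
            end = -(-iv.end // bs) * bs
            if (start, end) != (iv.start, min(iv.end, limit)) and not warned:
                if iv.start % bs or iv.end % bs:
                    warnings.warn(
                        f"{self.label}: off-grid interval boundaries snapped outward "
                        f"to the {bs}-bp grid",
                        stacklevel=2,
                    )
                    warned = True
            end = min(end, limit)
            if end > start:
                out.append(Interval(iv.chrom, start, end, iv.strand, iv.name))
        return RegionSet(self.label, out)

    def to_bin_mask(self, layout: GenomeLayout) -> np.ndarray:
        """Boolean mask over layout bins; a bin is in if it overlaps any
        interval."""
        mask = np.zeros(layout.n_bins, dtype=bool)
        bs = layout.bin_size
        for iv in self.intervals:
            cid = layout.chrom_id(iv.chrom)
            off = layout.offset_of(iv.chrom)
            nb = layout.n_bins_of(iv.chrom)
            b0 = max(iv.start // bs, 0)
            b1 = min(-(-iv.end // bs), nb)
            if b1 > b0:
                mask[off + b0 : off + b1] = True
        return mask

    @classmethod
    def from_bin_mask(
        cls, label: str, mask: np.ndarray, layout: GenomeLayout
    ) -> "RegionSet":
        """Merge runs of selected adjacent bins into intervals."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (layout.n_bins,):
            raise LayoutError("mask length does not match layout bin count")
        intervals: list[Interval] = []
        bs = layout.bin_size
        for chrom in layout.chromosomes:
            sl = layout.chrom_slice(chrom)
            sub = mask[sl]
            if not sub.any():
                continue
            padded = np.concatenate([[False], sub, [False]]).astype(np.int8)
            d = np.diff(padded)
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0]
            for s, e in zip(starts, ends):
                intervals.append(Interval(chrom, int(s) * bs, int(e) * bs))
        return cls(label, intervals)

    # -------------------------------------------------------------------- IO
    def write_bed(self, path: str | Path) -> None:
        """BED6; score column 0, strand '.' when unset."""
        with open(path, "w") as fh:
            for i, iv in enumerate(self.intervals):
                name = iv.name or f"{self.label}_{i}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand or '.'}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path, label: str | None = None) -> "RegionSet":
        return cls(label or Path(path).stem, read_bed(path))


def read_bed(path: str | Path) -> list[Interval]:
    """Parse BED3/BED6.  Raises :class:`BedError` with a line number."""
    intervals: list[Interval] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise BedError(f"{path}:{ln}: expected at least 3 tab-separated fields")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise BedError(f"{path}:{ln}: non-integer coordinates") from None
        if end <= start or start < 0:
            raise BedError(f"{path}:{ln}: invalid interval {start}-{end}")
        name = parts[3] if len(parts) > 3 and parts[3] != "." else None
        strand = None
        if len(parts) > 5 and parts[5] in ("+", "-"):
            strand = parts[5]
        intervals.append(Interval(chrom, start, end, strand, name))
    return intervals


def load_locus_sets(
    bed_files: Iterable[str | Path], layout: GenomeLayout | None = None
) -> dict[str, RegionSet]:
    """Load one labeled RegionSet per BED file (label = file stem).

    Overlapping input intervals are merged; with a layout, boundaries are
    snapped outward to the bin grid.
    """
    sets: dict[str, RegionSet] = {}
    for path in bed_files:
        rs = RegionSet.from_bed(path)
        if layout is not None:
            rs = rs.snapped(layout)
        sets[rs.label] = rs
    return sets
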