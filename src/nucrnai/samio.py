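"""Alignment file I/O: SAM via pysam and a 6-column BED read dialect.

Multi-mapper bookkeeping rides on the SAM ``NH`` tag (absent tag means a
unique alignment) and, in the BED dialect, on the score column (a score of
N >= 1 is interpreted as the read's total placement count).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .coverage import AlignedReadRecord, MalformedReadError
from .layout import GenomeLayout

__all__ = ["write_sam", "read_sam", "write_bed_reads", "read_bed_reads", "read_alignments"]


def _header(layout: GenomeLayout) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": c, "LN": l} for c, l in zip(layout.chromosomes, layout.lengths)
        ],
    }


def write_sam(
    path: str | Path, layout: GenomeLayout, placements: Iterable[AlignedReadRecord]
) -> int:
    """Write one SAM record per placement; NH carries the placement count.

    Placements after the first of a multi-mapping read (same ``name``) are
    marked secondary.  Returns the number of records written.
    """
    seen: set[str] = set()
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=_header(layout)) as out:
        for i, rec in enumerate(placements):
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.name or f"r{i:08d}"
            a.flag = 16 if rec.strand == "-" else 0
            if rec.name in seen:
                a.flag |= 0x100
            elif rec.name is not None:
                seen.add(rec.name)
            a.reference_id = layout.chrom_id(rec.chrom)
            a.reference_start = rec.start
            a.mapping_quality = 255
            a.cigartuples = [(0, rec.length)]
            a.set_tag("NH", rec.n_loci)
            out.write(a)
            n += 1
    return n


def read_sam(path: str | Path) -> Iterator[AlignedReadRecord]:
    """Yield one :class:`AlignedReadRecord` per mapped SAM/BAM record."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            nh = a.get_tag("NH") if a.has_tag("NH") else 1
            if nh < 1:
                raise MalformedReadError(f"read {a.query_name}: NH={nh}")
            yield AlignedReadRecord(
                chrom=a.reference_name,
                start=a.reference_start,
                length=a.query_length or a.infer_read_length() or 50,
                strand="-" if a.is_reverse else "+",
                n_loci=int(nh),
                name=a.query_name,
            )


def write_bed_reads(
    path: str | Path, placements: Iterable[AlignedReadRecord]
) -> int:
    """BED6 dialect: chrom, start, end, name, n_loci (score), strand."""
    n = 0
    with open(path, "w") as fh:
        for i, rec in enumerate(placements):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.start + rec.length}\t"
                f"{rec.name or f'r{i:08d}'}\t{rec.n_loci}\t{rec.strand}\n"
            )
            n += 1
    return n


def read_bed_reads(path: str | Path) -> Iterator[AlignedReadRecord]:
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise MalformedReadError(f"{path}:{ln}: expected 6 BED columns")
        try:
            start, end, nloci = int(parts[1]), int(parts[2]), int(float(parts[4]))
        except ValueError:
            raise MalformedReadError(f"{path}:{ln}: bad numeric field") from None
        if nloci < 1:
            raise MalformedReadError(f"{path}:{ln}: n_loci={nloci} < 1")
        yield AlignedReadRecord(
            chrom=parts[0],
            start=start,
            length=end - start,
            strand=parts[5] if parts[5] in ("+", "-") else "+",
            n_loci=nloci,
            name=parts[3] or None,
        )


def read_alignments(path: str | Path) -> Iterator[AlignedReadRecord]:
    """Dispatch on extension: .sam/.bam -> SAM reader, .bed -> BED dialect."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam", ".cram"):
        return read_sam(path)
    if suffix == ".bed":
        return read_bed_reads(path)
    raise ValueError(f"unrecognized alignment format: {path}")
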