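"""Weighted read binning and track normalization.

The quantification layer: aligned reads become per-bin weighted signal
(multi-mappers contribute 1/N at each of their N placements), tracks are
scaled to reads-per-million, optionally re-anchored to a background
region median, and smoothed with a truncated centered moving average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

from .layout import GenomeLayout, LayoutError
from .regions import RegionSet

__all__ = [
    "AlignedReadRecord",
    "Sample",
    "BinTrack",
    "SmoothedProfile",
    "MalformedReadError",
    "weight_reads",
    "bin_counts",
    "depth_normalize",
    "background_median_normalize",
    "moving_average",
    "stranded_coverage",
]

log = logging.getLogger(__name__)

RPM_SCALE = 1_000_000.0


class MalformedReadError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedReadRecord:
    """One placement of an aligned read.

    ``n_loci`` is the total number of placements of the read genome-wide;
    each placement therefore carries weight ``1 / n_loci`` so that a read's
    summed weight is 1 regardless of how many times it maps.
    """

    chrom: str
    start: int
    length: int = 50
    strand: str = "+"
    n_loci: int = 1
    name: str | None = None

    @property
    def weight(self) -> float:
        return 1.0 / self.n_loci


@dataclass(frozen=True)
class Sample:
    assay: str = "H3K9me3"
    genotype: str = "WT"
    replicate: int = 1
    treatment: str | None = None

    @property
    def name(self) -> str:
        bits = [self.assay, self.genotype, f"rep{self.replicate}"]
        if self.treatment:
            bits.append(self.treatment)
        return "_".join(bits)


@dataclass
class BinTrack:
    """Per-bin signal of one library on a :class:`GenomeLayout`.

    ``normalization_state`` is one of ``raw``, ``depth``,
    ``depth+background``.  ``raw_total`` is the total weighted read count of
    the raw track and survives normalization (it fixes the reads-per-million
    equivalent of one raw read, used as a default ratio pseudocount).
    """

    layout: GenomeLayout
    values: np.ndarray
    sample: Sample = field(default_factory=Sample)
    normalization_state: str = "raw"
    raw_total: float | None = None
    dropped_weight: float = 0.0
    dropped_reads: int = 0
    scale_log: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.layout.n_bins,):
            raise LayoutError(
                f"track has {self.values.size} values for {self.layout.n_bins} bins"
            )
        if np.any(self.values < 0):
            raise ValueError("bin values must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def with_values(self, values: np.ndarray, state: str, step: tuple[str, float]) -> "BinTrack":
        return replace(
            self,
            values=values,
            normalization_state=state,
            scale_log=self.scale_log + (step,),
        )

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.sample.name}"\n')
            for (chrom, start, end), v in zip(self.layout.iter_bins(), self.values):
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


@dataclass
class SmoothedProfile:
    """Centered moving-average profile at bin-midpoint resolution."""

    layout: GenomeLayout
    window: int
    values: np.ndarray


# --------------------------------------------------------------------- reads
def weight_reads(
    reads: Iterable[AlignedReadRecord],
) -> Iterator[tuple[AlignedReadRecord, float]]:
    """Attach the 1/N fractional weight to every placement.

    The emitted total weight equals the number of distinct reads, because a
    read mapping to N loci appears as N placements of weight 1/N.
    """
    for rec in reads:
        if rec.n_loci < 1:
            raise MalformedReadError(f"read {rec.name or rec}: n_loci={rec.n_loci} < 1")
        yield rec, 1.0 / rec.n_loci


def bin_counts(
    placements: Iterable[tuple[AlignedReadRecord, float] | AlignedReadRecord],
    layout: GenomeLayout,
    sample: Sample | None = None,
) -> BinTrack:
    """Sum placement weights into the bin containing each placement's 5' start.

    Accepts the output of :func:`weight_reads` (record, weight) or bare
    records (weighted on the fly).  Placements starting in a chromosome's
    trailing partial-bin remainder are dropped; their count and weight are
    logged and recorded on the returned track so mass can be audited:
    ``track.values.sum() + track.dropped_weight == distinct read count``.
    """
    chrom_ids: list[int] = []
    starts: list[int] = []
    weights: list[float] = []
    for item in placements:
        rec, w = item if isinstance(item, tuple) else (item, None)
        if w is None:
            if rec.n_loci < 1:
                raise MalformedReadError(f"read {rec.name or rec}: n_loci={rec.n_loci} < 1")
            w = 1.0 / rec.n_loci
        chrom_ids.append(layout.chrom_id(rec.chrom))  # raises for unknown chrom
        starts.append(rec.start)
        weights.append(w)

    values = np.zeros(layout.n_bins, dtype=np.float64)
    dropped_w = 0.0
    dropped_n = 0
    if chrom_ids:
        idx = layout.global_indices(np.array(chrom_ids), np.array(starts))
        w = np.asarray(weights)
        keep = idx >= 0
        dropped_n = int((~keep).sum())
        dropped_w = float(w[~keep].sum())
        np.add.at(values, idx[keep], w[keep])
    if dropped_n:
        log.info(
            "bin_counts: dropped %d placements (weight %.3f) in trailing partial bins",
            dropped_n,
            dropped_w,
        )
    return BinTrack(
        layout=layout,
        values=values,
        sample=sample or Sample(),
        normalization_state="raw",
        raw_total=float(values.sum()) + dropped_w,
        dropped_weight=dropped_w,
        dropped_reads=dropped_n,
    )


# ------------------------------------------------------------- normalization
def depth_normalize(track: BinTrack) -> BinTrack:
    """Scale to reads-per-million total weight.  Idempotent."""
    total = track.total
    if total <= 0:
        raise ValueError(f"cannot depth-normalize empty library {track.sample.name}")
    factor = RPM_SCALE / total
    state = track.normalization_state if track.normalization_state != "raw" else "depth"
    out = track.with_values(track.values * factor, state, ("depth", factor))
    if out.raw_total is None:
        out.raw_total = total
    return out


def background_median_normalize(
    track: BinTrack, background: RegionSet, reference: BinTrack
) -> BinTrack:
    """Rescale ``track`` so its median over background bins matches the
    reference's median over the same bins.

    Applied to heterochromatin-mark tracks only: when a mutant has lost the
    mark over much of the genome, plain depth scaling inflates its apparent
    background relative to WT, and re-anchoring on a mark-free background
    class removes that artifact.
    """
    if track.normalization_state == "raw" or reference.normalization_state == "raw":
        raise ValueError("background normalization expects depth-normalized tracks")
    track.layout.require_same(reference.layout)
    mask = background.to_bin_mask(track.layout)
    if not mask.any():
        raise ValueError("background region set selects no bins")
    med_t = float(np.median(track.values[mask]))
    med_r = float(np.median(reference.values[mask]))
    if med_t == 0:
        raise ValueError("background median of track is zero; cannot rescale")
    factor = med_r / med_t
    return track.with_values(
        track.values * factor, "depth+background", ("background-median", factor)
    )


# ------------------------------------------------------------------ smoothing
def moving_average(track: BinTrack, window: int) -> SmoothedProfile:
    """Centered moving average, truncated at chromosome edges.

    A bin's smoothed value is the mean over all bins of the same chromosome
    whose midpoints lie within ``window/2`` bp of its own midpoint
    (``2*|j-i|*bin_size <= window``); windows never cross chromosomes.
    """
    bs = track.layout.bin_size
    if window < bs:
        raise ValueError(f"window {window} < bin size {bs}")
    k = int(window // (2 * bs))
    out = np.empty_like(track.values)
    for chrom in track.layout.chromosomes:
        sl = track.layout.chrom_slice(chrom)
        v = track.values[sl]
        n = v.size
        if n == 0:
            continue
        c = np.concatenate([[0.0], np.cumsum(v)])
        i = np.arange(n)
        lo = np.maximum(i - k, 0)
        hi = np.minimum(i + k, n - 1)
        out[sl] = (c[hi + 1] - c[lo]) / (hi - lo + 1)
    return SmoothedProfile(track.layout, int(window), out)


# ------------------------------------------------------------------ stranded
def stranded_coverage(
    placements: Iterable[tuple[AlignedReadRecord, float] | AlignedReadRecord],
    annotation: RegionSet,
    layout: GenomeLayout,
    sample: Sample | None = None,
) -> tuple[BinTrack, BinTrack]:
    """Split weighted coverage into sense and antisense tracks.

    A read overlapping an annotated gene (by its 5' bin) is sense iff its
    strand matches the gene's strand.  Reads outside annotated genes fall
    back to the '+' convention (+ reads sense) and are counted in a logged
    flag total.  A bin annotated on both strands matches a read once per
    matching strand (warning logged once).
    """
    ann_plus = RegionSet("+", [iv for iv in annotation if iv.strand == "+"]).to_bin_mask(layout)
    ann_minus = RegionSet("-", [iv for iv in annotation if iv.strand == "-"]).to_bin_mask(layout)
    if np.any(ann_plus & ann_minus):
        log.warning("stranded_coverage: bins annotated on both strands; reads there count once per matching strand")

    sense = np.zeros(layout.n_bins)
    anti = np.zeros(layout.n_bins)
    flagged = 0
    for item in placements:
        rec, w = item if isinstance(item, tuple) else (item, item.weight)
        idx = layout.bin_index(rec.chrom, rec.start)
        if idx < 0:
            continue
        in_plus, in_minus = ann_plus[idx], ann_minus[idx]
        if not in_plus and not in_minus:
            flagged += 1
            (sense if rec.strand == "+" else anti)[idx] += w
        else:
            if in_plus:
                (sense if rec.strand == "+" else anti)[idx] += w
            if in_minus:
                (sense if rec.strand == "-" else anti)[idx] += w
    if flagged:
        log.info("stranded_coverage: %d reads outside annotated genes assigned by + convention", flagged)
    base = sample or Sample(assay="pre-mRNA")
    return (
        BinTrack(layout, sense, replace(base, treatment="sense"), raw_total=float(sense.sum())),
        BinTrack(layout, anti, replace(base, treatment="antisense"), raw_total=float(anti.sum())),
    )
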