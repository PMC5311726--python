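"""Figure rendering: locus coverage, genome scatter with boundary curves,
kb-weighted Venn, region-class boxplots, and stranded coverage."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .coverage import BinTrack, SmoothedProfile
from .differential import ChangedBins, DependencySet, venn_overlap
from .regions import Interval, RegionSet
from .regionstats import GroupStats

__all__ = [
    "coverage_plot",
    "scatter_plot",
    "venn_plot",
    "boxplot",
    "stranded_plot",
]


def _locus_values(track: BinTrack, region: Interval) -> tuple[np.ndarray, np.ndarray]:
    layout = track.layout
    bs = layout.bin_size
    b0 = max(region.start // bs, 0)
    b1 = min(-(-region.end // bs), layout.n_bins_of(region.chrom))
    off = layout.offset_of(region.chrom)
    x = (np.arange(b0, b1) + 0.5) * bs
    return x, track.values[off + b0 : off + b1]


def coverage_plot(
    tracks: Sequence[BinTrack],
    region: Interval,
    path: str | Path,
    highlight: Interval | None = None,
) -> Path:
    """Overlay per-bin coverage of several samples over one locus; an
    optional highlight interval (e.g. a dsRNA trigger region) is shaded."""
    if not tracks:
        raise ValueError("no tracks supplied")
    fig, ax = plt.subplots(figsize=(8, 3))
    for track in tracks:
        x, y = _locus_values(track, region)
        ax.plot(x + 1, y, label=track.sample.name, lw=1)  # display 1-based
    if highlight is not None:
        ax.axvspan(highlight.start + 1, highlight.end, color="gold", alpha=0.3)
    ax.set_xlabel(f"{region.chrom} position (bp)")
    ax.set_ylabel("signal per bin")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def smoothed_plot(profiles: Sequence[SmoothedProfile], chrom: str, path: str | Path,
                  labels: Sequence[str] | None = None) -> Path:
    fig, ax = plt.subplots(figsize=(8, 3))
    for i, prof in enumerate(profiles):
        sl = prof.layout.chrom_slice(chrom)
        x = (np.arange(sl.stop - sl.start) + 0.5) * prof.layout.bin_size
        ax.plot(x, prof.values[sl], lw=1, label=labels[i] if labels else None)
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_ylabel("smoothed signal")
    if labels:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def scatter_plot(
    result: ChangedBins,
    path: str | Path,
    highlights: dict[str, RegionSet] | None = None,
    max_points: int = 200_000,
) -> Path:
    """log-log scatter of per-bin abundance vs ratio with the significance
    boundary curves; optional region classes are highlighted in color."""
    keep = result.abundance > 0
    ab = result.abundance[keep]
    dl = result.delta[keep]
    if ab.size > max_points:
        idx = np.linspace(0, ab.size - 1, max_points).astype(int)
        ab, dl = ab[idx], dl[idx]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(ab, dl, s=2, c="0.6", linewidths=0, rasterized=True)
    if highlights:
        for label, rs in highlights.items():
            mask = rs.to_bin_mask(result.layout) & keep
            ax.scatter(
                result.abundance[mask], result.delta[mask], s=4, linewidths=0, label=label
            )
        ax.legend(fontsize=6)
    n_grid = np.unique(np.geomspace(1, max(result.abundance.max() * 2, 2), 80).astype(int))
    bnd = result.curve.boundary(n_grid)
    for branch in ("up", "lo"):
        ok = ~np.isnan(bnd[f"ratio_{branch}"])
        ax.plot(bnd[f"abundance_{branch}"][ok], bnd[f"ratio_{branch}"][ok], "k:", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.axhline(1.0, color="k", lw=0.5)
    ax.set_xlabel("mean abundance (rpm)")
    ax.set_ylabel("ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def venn_plot(sets: Sequence[DependencySet], path: str | Path) -> Path:
    """Two- or three-circle Venn annotated with kb per cell."""
    cells = venn_overlap(sets)
    centers2 = [(-0.5, 0.0), (0.5, 0.0)]
    centers3 = [(-0.5, -0.3), (0.5, -0.3), (0.0, 0.55)]
    centers = centers2 if len(sets) == 2 else centers3
    fig, ax = plt.subplots(figsize=(5, 5))
    for (cx, cy), s in zip(centers, sets):
        ax.add_patch(plt.Circle((cx, cy), 1.0, fill=False, lw=1.5))
        ax.annotate(s.label, (cx, cy + 1.05), ha="center", fontsize=8)
    # cell label anchors: singles at outer thirds, pairs between, triple center
    pos = {}
    labels = [s.label for s in sets]
    for key, kb in cells.items():
        members = key.split("&")
        xs = [centers[labels.index(m)][0] for m in members]
        ys = [centers[labels.index(m)][1] for m in members]
        shrink = 1.0 if len(members) == 1 else len(members) * 0.45
        pos[key] = (np.mean(xs) * (2 - shrink), np.mean(ys) * (2 - shrink))
        ax.annotate(f"{kb:g} kb", pos[key], ha="center", fontsize=7)
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2, 2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def boxplot(stats_list: Sequence[GroupStats], path: str | Path, title: str = "") -> Path:
    """Boxplot from precomputed group statistics (Tukey whiskers)."""
    if not stats_list:
        raise ValueError("no group statistics supplied")
    boxes = [
        {
            "label": gs.label,
            "med": gs.median,
            "q1": gs.q1,
            "q3": gs.q3,
            "whislo": gs.whisker_lo,
            "whishi": gs.whisker_hi,
            "fliers": [],
        }
        for gs in stats_list
    ]
    fig, ax = plt.subplots(figsize=(1.2 * len(boxes) + 1.5, 4))
    ax.bxp(boxes, showfliers=False)
    ax.axhline(1.0, color="k", lw=0.5, ls="--")
    ax.set_yscale("log")
    ax.set_ylabel("ratio")
    if title:
        ax.set_title(title, fontsize=9)
    ax.tick_params(axis="x", labelsize=7, rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def stranded_plot(
    sense: BinTrack, antisense: BinTrack, region: Interval, path: str | Path
) -> Path:
    """Sense coverage above the y = 0 line, antisense below."""
    fig, ax = plt.subplots(figsize=(8, 3))
    x, ys = _locus_values(sense, region)
    _, ya = _locus_values(antisense, region)
    ax.fill_between(x + 1, 0, ys, step="mid", color="tab:blue", label="sense")
    ax.fill_between(x + 1, 0, -ya, step="mid", color="tab:red", label="antisense")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel(f"{region.chrom} position (bp)")
    ax.set_ylabel("signal per bin")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
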