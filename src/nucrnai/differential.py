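"""Mutant/WT ratio tracks, fold-change significance with FDR boundary
curves, dependency-region calling, and kb-resolved set overlaps.

Per-bin significance uses a conditional binomial test: given the pooled
count n of a bin in two libraries, the count in library A is
Binomial(n, depth_A / (depth_A + depth_B)) under the null of equal relative
abundance.  Two-sided p-values double the smaller tail (capped at 1), which
is exact at the low counts where fold-change boundaries flare out.
Multiple testing is controlled with Benjamini-Hochberg over bins with a
nonzero pooled count; a bin is called changed only when it also clears a
hard fold cutoff, and the returned boundary curve is the exact frontier of
that joint rule, so plotting and calling can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import BinTrack, RPM_SCALE, Sample
from .layout import GenomeLayout
from .regions import RegionSet

__all__ = [
    "RatioTrack",
    "SignificanceConfig",
    "SignificanceCurve",
    "ChangedBins",
    "DependencyCriteria",
    "DependencySet",
    "compute_ratio",
    "bin_test",
    "call_changed_bins",
    "call_dependent_regions",
    "venn_overlap",
]


# ------------------------------------------------------------------- ratios
@dataclass
class RatioTrack:
    """Per-bin mutant/WT (or treatment/control) ratio values.

    ``pseudocount`` is recorded in the same units as the input tracks
    (reads-per-million for depth-normalized tracks).
    """

    layout: GenomeLayout
    values: np.ndarray
    pseudocount: float
    numerator: Sample
    denominator: Sample

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def default_pseudocount(numerator: BinTrack, denominator: BinTrack) -> float:
    """Reads-per-million equivalent of one raw read in the smaller library.

    Falls back to 0 when raw totals are unknown (tracks built directly from
    arrays rather than from reads).
    """
    totals = [t.raw_total for t in (numerator, denominator) if t.raw_total]
    if not totals:
        return 0.0
    return RPM_SCALE / min(totals)


def compute_ratio(
    numerator: BinTrack, denominator: BinTrack, pseudocount: float | None = None
) -> RatioTrack:
    """Per-bin (numerator + c) / (denominator + c).

    Tracks must share a layout and a normalization state.  With c > 0 every
    ratio is finite and positive; with c = 0 swapping the tracks maps every
    value to its reciprocal.
    """
    numerator.layout.require_same(denominator.layout)
    if numerator.normalization_state != denominator.normalization_state:
        raise ValueError(
            "normalization states differ: "
            f"{numerator.normalization_state} vs {denominator.normalization_state}"
        )
    c = default_pseudocount(numerator, denominator) if pseudocount is None else float(pseudocount)
    if c < 0:
        raise ValueError("pseudocount must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (numerator.values + c) / (denominator.values + c)
    return RatioTrack(numerator.layout, values, c, numerator.sample, denominator.sample)


# ----------------------------------------------------------------- bin test
def bin_test(count_a, count_b, depth_a: float, depth_b: float):
    """Two-sided conditional binomial p-value per bin (vectorized).

    H0: the bin's true relative abundance is equal in both libraries, i.e.
    count_a ~ Binomial(count_a + count_b, depth_a / (depth_a + depth_b)).
    p = min(1, 2 * min(lower tail, upper tail)); empty bins (n = 0) give
    p = 1 by convention.
    """
    a = np.asarray(count_a, dtype=np.int64)
    b = np.asarray(count_b, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("depths must be positive")
    n = a + b
    p0 = depth_a / (depth_a + depth_b)
    lower = stats.binom.cdf(a, n, p0)
    upper = stats.binom.sf(a - 1, n, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p = np.where(n == 0, 1.0, p)
    return p if p.ndim else float(p)


# ------------------------------------------------------------- significance
@dataclass(frozen=True)
class SignificanceConfig:
    fold: float = 2.0
    alpha: float = 0.05
    test: str = "conditional-binomial"
    correction: str = "benjamini-hochberg"
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if not self.fold > 1:
            raise ValueError("fold threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SignificanceCurve:
    """Boundary of the changed region in the (abundance, ratio) plane.

    ``p_cut`` is the realized raw-p rejection threshold of the BH step, so a
    bin is outside the curve iff its raw p <= p_cut and its ratio clears the
    fold cutoff — identical to the calling rule.
    """

    fold: float
    alpha: float
    p_cut: float
    depth_a: float
    depth_b: float
    pseudocount: float

    def _norm(self, a, b):
        na = np.asarray(a) / self.depth_a * RPM_SCALE
        nb = np.asarray(b) / self.depth_b * RPM_SCALE
        return na, nb

    def is_changed(self, count_a, count_b):
        """True where (count_a, count_b) lies outside the boundary."""
        a = np.asarray(count_a, dtype=np.int64)
        b = np.asarray(count_b, dtype=np.int64)
        p = np.asarray(bin_test(a, b, self.depth_a, self.depth_b))
        na, nb = self._norm(a, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (na + self.pseudocount) / (nb + self.pseudocount)
            big = np.abs(np.log2(delta)) >= np.log2(self.fold)
        out = (a + b > 0) & (p <= self.p_cut) & np.nan_to_num(big, nan=False)
        return out if out.ndim else bool(out)

    def boundary(self, n_values: np.ndarray):
        """Boundary points for plotting.

        For each pooled count n, the smallest A (upper branch) and largest A
        (lower branch) that would be called; returns a dict of arrays with
        mean normalized abundance and the boundary ratio of each branch
        (NaN where no count is callable at that n).
        """
        res = {
            "n": np.asarray(n_values, dtype=np.int64),
            "abundance_up": [], "ratio_up": [],
            "abundance_lo": [], "ratio_lo": [],
        }
        for n in res["n"]:
            a_grid = np.arange(n + 1)
            called = np.asarray(self.is_changed(a_grid, n - a_grid))
            up = a_grid[called & (a_grid / self.depth_a >= (n - a_grid) / self.depth_b)]
            lo = a_grid[called & (a_grid / self.depth_a < (n - a_grid) / self.depth_b)]
            for branch, sel, pick in (("up", up, np.min), ("lo", lo, np.max)):
                if sel.size:
                    a = int(pick(sel))
                    na, nb = self._norm(a, n - a)
                    res[f"abundance_{branch}"].append((na + nb) / 2)
                    res[f"ratio_{branch}"].append(
                        (na + self.pseudocount) / (nb + self.pseudocount)
                    )
                else:
                    res[f"abundance_{branch}"].append(np.nan)
                    res[f"ratio_{branch}"].append(np.nan)
        return {k: np.asarray(v) for k, v in res.items()}


@dataclass
class ChangedBins:
    """Result of :func:`call_changed_bins`."""

    layout: GenomeLayout
    changed: np.ndarray
    delta: np.ndarray
    abundance: np.ndarray
    pvalues: np.ndarray
    padj: np.ndarray
    curve: SignificanceCurve
    config: SignificanceConfig

    @property
    def n_changed(self) -> int:
        return int(self.changed.sum())


def _bh(p: np.ndarray, mask: np.ndarray, alpha: float):
    """BH over ``p[mask]``; returns (reject, padj) over all bins (padj = 1
    outside the mask) and the realized raw-p cutoff."""
    reject = np.zeros(p.size, dtype=bool)
    padj = np.ones(p.size)
    m = int(mask.sum())
    if m:
        rej, adj, _, _ = multipletests(p[mask], alpha=alpha, method="fdr_bh")
        reject[mask] = rej
        padj[mask] = adj
    p_cut = float(p[reject].max()) if reject.any() else (alpha / m if m else 0.0)
    return reject, padj, p_cut


def call_changed_bins(
    track_a: BinTrack,
    track_b: BinTrack,
    config: SignificanceConfig = SignificanceConfig(),
    depths: tuple[float, float] | None = None,
) -> ChangedBins:
    """Call bins changed between two libraries.

    A bin is changed iff |log2 ratio| >= log2(fold) and its BH-adjusted
    conditional-binomial p-value is below alpha (adjustment over bins with a
    nonzero pooled count).  Tracks should carry raw weighted counts; they
    are rounded to the nearest integer for testing (1/N weighting makes
    counts non-integral; the rounding error is at most half a read).
    ``depths`` overrides the library depths inferred from track totals, for
    inputs that are depth-matched by construction.
    """
    track_a.layout.require_same(track_b.layout)
    a = np.rint(track_a.values).astype(np.int64)
    b = np.rint(track_b.values).astype(np.int64)
    depth_a, depth_b = depths if depths is not None else (track_a.total, track_b.total)
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("library depths must be positive")

    p = bin_test(a, b, depth_a, depth_b)
    nonzero = (a + b) > 0
    reject, padj, p_cut = _bh(p, nonzero, config.alpha)

    c = (
        RPM_SCALE / min(depth_a, depth_b)
        if config.pseudocount is None
        else config.pseudocount
    )
    na = a / depth_a * RPM_SCALE
    nb = b / depth_b * RPM_SCALE
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (na + c) / (nb + c)
        big = np.abs(np.log2(delta)) >= np.log2(config.fold)
    changed = nonzero & reject & np.nan_to_num(big, nan=False)
    curve = SignificanceCurve(config.fold, config.alpha, p_cut, depth_a, depth_b, c)
    return ChangedBins(
        layout=track_a.layout,
        changed=changed,
        delta=delta,
        abundance=(na + nb) / 2,
        pvalues=p,
        padj=padj,
        curve=curve,
        config=config,
    )


# -------------------------------------------------------------- dependency
@dataclass(frozen=True)
class DependencyCriteria:
    """A bin qualifies only if every replicate pair clears both cuts."""

    max_delta: float = 0.5
    alpha: float = 0.05
    replicates_required: int = 2
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.max_delta:
            raise ValueError("max_delta must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.replicates_required < 1:
            raise ValueError("replicates_required must be >= 1")


@dataclass
class DependencySet:
    """Merged regions whose signal depends on the tested factor."""

    label: str
    layout: GenomeLayout
    mask: np.ndarray
    regions: RegionSet = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.regions = RegionSet.from_bin_mask(self.label, self.mask, self.layout)

    @property
    def total_kb(self) -> float:
        return float(self.mask.sum()) * self.layout.bin_size / 1000.0


def call_dependent_regions(
    replicate_pairs: Sequence[tuple[BinTrack, BinTrack]],
    criteria: DependencyCriteria = DependencyCriteria(),
    label: str = "dependent",
    depths: Sequence[tuple[float, float]] | None = None,
) -> DependencySet:
    """Identify regions where the mutant/WT ratio is at most ``max_delta``
    with BH-adjusted significance below ``alpha`` in every replicate pair.

    ``replicate_pairs`` holds (mutant, WT) raw-count track pairs; at least
    ``criteria.replicates_required`` are needed.  Qualifying adjacent bins
    merge into regions; ``total_kb`` counts member bins.
    """
    if len(replicate_pairs) < criteria.replicates_required:
        raise ValueError(
            f"need >= {criteria.replicates_required} replicate pairs, "
            f"got {len(replicate_pairs)}"
        )
    layout = replicate_pairs[0][0].layout
    qualify = np.ones(layout.n_bins, dtype=bool)
    for i, (mut, wt) in enumerate(replicate_pairs):
        mut.layout.require_same(layout)
        wt.layout.require_same(layout)
        m = np.rint(mut.values).astype(np.int64)
        w = np.rint(wt.values).astype(np.int64)
        dm, dw = depths[i] if depths is not None else (mut.total, wt.total)
        p = bin_test(m, w, dm, dw)
        nonzero = (m + w) > 0
        reject, _, _ = _bh(p, nonzero, criteria.alpha)
        c = criteria.pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (m / dm * RPM_SCALE + c) / (w / dw * RPM_SCALE + c)
        ok = reject & ~np.isnan(delta) & (delta <= criteria.max_delta)
        qualify &= ok
    return DependencySet(label, layout, qualify)


# -------------------------------------------------------------------- venn
def venn_overlap(sets: Sequence[DependencySet]) -> dict[str, float]:
    """kb in every intersection cell of 2-3 dependency sets.

    Keys are '&'-joined member labels (e.g. ``"A&B"`` = in A and B but not
    in any other supplied set); cells sum to the union's kb.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_overlap takes 2 or 3 sets")
    layout = sets[0].layout
    for s in sets[1:]:
        s.layout.require_same(layout)
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be distinct")
    masks = np.stack([s.mask for s in sets])
    kb_per_bin = layout.bin_size / 1000.0
    cells: dict[str, float] = {}
    for combo in range(1, 2 ** len(sets)):
        members = [i for i in range(len(sets)) if combo >> i & 1]
        cell = np.ones(layout.n_bins, dtype=bool)
        for i in range(len(sets)):
            cell &= masks[i] if i in members else ~masks[i]
        cells["&".join(labels[i] for i in members)] = float(cell.sum()) * kb_per_bin
    return cells
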