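"""Percentile-based region classes and group-level ratio statistics.

Defines the signal / background classes from a WT track (top-percentile
bins and a low-percentile background band) and summarizes ratio tracks over
labeled region sets with boxplot statistics and Welch t tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .coverage import BinTrack
from .differential import RatioTrack
from .regions import RegionSet

__all__ = [
    "RegionClassConfig",
    "GroupStats",
    "percentile_regions",
    "group_ratio_stats",
    "welch_test",
]


@dataclass(frozen=True)
class RegionClassConfig:
    """Percentile rules for the signal(+) and background(-) classes.

    Nearest-rank percentiles on per-bin WT values.  The top class holds the
    floor(n * top_percentile / 100) largest bins, extended to include ties
    at the cutoff value; the background band holds bins whose value is
    strictly above the lower-band threshold and at most the upper-band
    threshold, minus any bin already in the top class.  ``min_coverage``
    optionally drops near-empty bins from ranking and from both classes.
    """

    top_percentile: float = 5.0
    background_band: tuple[float, float] = (5.0, 25.0)
    min_coverage: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.top_percentile < 100:
            raise ValueError("top_percentile must be in (0, 100)")
        lo, hi = self.background_band
        if not 0 <= lo < hi <= 100:
            raise ValueError("background band must satisfy 0 <= lower < upper <= 100")


def percentile_regions(
    wt_track: BinTrack, config: RegionClassConfig = RegionClassConfig()
) -> tuple[RegionSet, RegionSet]:
    """Split a WT track into signal(+) and background(-) region classes.

    Returns (positive, negative) RegionSets with adjacent selected bins
    merged.  The classes are disjoint by construction.
    """
    if wt_track.normalization_state == "raw":
        raise ValueError("percentile classification expects a normalized track")
    values = wt_track.values
    eligible = np.ones(values.size, dtype=bool)
    if config.min_coverage is not None:
        eligible = values >= config.min_coverage
    n = int(eligible.sum())
    if n < 100:
        raise ValueError(f"need >= 100 eligible bins, have {n}")
    v = np.sort(values[eligible])
    if v[0] == v[-1]:
        raise ValueError("all bin values equal; percentiles undefined for classification")

    k_top = math.floor(n * config.top_percentile / 100)
    if k_top < 1:
        raise ValueError("top percentile selects no bins")
    v_top = v[n - k_top]  # k_top-th largest
    top_mask = eligible & (values >= v_top)

    lo_pct, hi_pct = config.background_band
    i_lo = math.floor(n * lo_pct / 100)
    i_hi = math.floor(n * hi_pct / 100)
    v_lo = v[i_lo - 1] if i_lo >= 1 else -np.inf
    v_hi = v[i_hi - 1] if i_hi >= 1 else -np.inf
    band_mask = eligible & (values > v_lo) & (values <= v_hi) & ~top_mask

    assay = wt_track.sample.assay
    pos = RegionSet.from_bin_mask(f"{assay}(+)", top_mask, wt_track.layout)
    neg = RegionSet.from_bin_mask(f"{assay}(-)", band_mask, wt_track.layout)
    return pos, neg


@dataclass
class GroupStats:
    """Boxplot summary of per-bin ratio values over one region class.

    Whiskers follow the Tukey 1.5 x IQR convention (display only; medians
    and p-values never depend on it).
    """

    label: str
    n_bins: int
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    welch_t: float | None = None
    welch_df: float | None = None
    welch_p: float | None = None
    reference_label: str | None = None


def group_ratio_stats(
    ratio: RatioTrack,
    regions: RegionSet,
    reference: RegionSet | None = None,
) -> GroupStats:
    """Median/quartile statistics of a ratio track restricted to a region
    class, with an optional Welch t test against a reference class."""
    mask = regions.to_bin_mask(ratio.layout)
    vals = ratio.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"region set {regions.label!r} selects no bins")
    q1, med, q3 = (float(x) for x in np.percentile(vals, [25, 50, 75]))
    iqr = q3 - q1
    in_lo = vals[vals >= q1 - 1.5 * iqr]
    in_hi = vals[vals <= q3 + 1.5 * iqr]
    gs = GroupStats(
        label=regions.label,
        n_bins=int(vals.size),
        median=med,
        q1=q1,
        q3=q3,
        whisker_lo=float(in_lo.min()) if in_lo.size else q1,
        whisker_hi=float(in_hi.max()) if in_hi.size else q3,
    )
    if reference is not None:
        ref_vals = ratio.values[reference.to_bin_mask(ratio.layout)]
        ref_vals = ref_vals[np.isfinite(ref_vals)]
        t, df, p = welch_test(vals, ref_vals)
        gs.welch_t, gs.welch_df, gs.welch_p = t, df, p
        gs.reference_label = reference.label
    return gs


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Welch two-sample t test.

    Returns (t, Welch-Satterthwaite df, p).  Requires n >= 2 per group and
    a nonzero pooled variance.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs n >= 2 (got {na}, {nb})")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("zero variance in both groups; t undefined")
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)
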