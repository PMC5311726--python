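import collections

import numpy as np
import pytest

from nucrnai import (
    AlignedReadRecord,
    Sample,
    background_median_normalize,
    bin_counts,
    compute_ratio,
    depth_normalize,
    moving_average,
    simulate_bin_counts,
    stranded_coverage,
    weight_reads,
    generate_layout,
    SimulationConfig,
)
from nucrnai.coverage import MalformedReadError
from nucrnai.layout import LayoutError
from nucrnai.regions import Interval, RegionSet

from conftest import make_track


# ------------------------------------------------------------- weight_reads
def test_unique_read_weight_is_one():
    [(rec, w)] = list(weight_reads([AlignedReadRecord("chrI", 0)]))
    assert w == 1.0


def test_four_way_read_weight_quarter_each():
    reads = [AlignedReadRecord("chrI", i * 100, n_loci=4, name="m") for i in range(4)]
    weights = [w for _, w in weight_reads(reads)]
    assert weights == [0.25] * 4


def test_total_weight_equals_distinct_reads():
    # oracle: 1000 unique reads + 100 four-way reads = 1100 distinct
    reads = [AlignedReadRecord("chrI", i % 9000, name=f"u{i}") for i in range(1000)]
    for j in range(100):
        reads += [
            AlignedReadRecord("chrI", (j * 37) % 9000, n_loci=4, name=f"m{j}")
            for _ in range(4)
        ]
    assert len(reads) == 1400
    total = sum(w for _, w in weight_reads(reads))
    assert total == pytest.approx(1100.0)


def test_zero_n_loci_rejected():
    with pytest.raises(MalformedReadError):
        list(weight_reads([AlignedReadRecord("chrI", 0, n_loci=0)]))


# --------------------------------------------------------------- bin_counts
def test_read_at_1500_lands_in_bin_one(layout):
    track = bin_counts(weight_reads([AlignedReadRecord("chrI", 1500)]), layout)
    assert track.values[1] == 1.0
    assert track.values.sum() == 1.0


def test_empty_stream_gives_zero_track(layout):
    track = bin_counts([], layout)
    assert not track.values.any()
    assert track.raw_total == 0.0


def test_bin_counts_matches_brute_force_tally(layout, rng):
    reads = []
    for i in range(10_000):
        chrom = "chrI" if rng.random() < 0.7 else "chrII"
        pos = int(rng.integers(0, layout.length_of(chrom)))
        n_loci = int(rng.choice([1, 1, 1, 2, 5]))
        reads.append(AlignedReadRecord(chrom, pos, n_loci=n_loci, name=f"r{i}"))
    track = bin_counts(weight_reads(reads), layout)
    # independent oracle: dictionary tally by (chrom, pos // bin)
    tally = collections.defaultdict(float)
    dropped = 0.0
    for r in reads:
        b = r.start // 1000
        if b < layout.n_bins_of(r.chrom):
            tally[(r.chrom, b)] += 1.0 / r.n_loci
        else:
            dropped += 1.0 / r.n_loci
    for (chrom, b), w in tally.items():
        assert track.values[layout.offset_of(chrom) + b] == pytest.approx(w)
    assert track.dropped_weight == pytest.approx(dropped)
    assert track.values.sum() + track.dropped_weight == pytest.approx(len(reads) / 1.0 - sum(
        (1 - 1 / r.n_loci) for r in reads))


def test_unknown_chromosome_error_names_record(layout):
    with pytest.raises(LayoutError, match="chrMT"):
        bin_counts(weight_reads([AlignedReadRecord("chrMT", 0)]), layout)


def test_read_order_never_changes_track(layout, rng):
    reads = [
        AlignedReadRecord("chrI", int(rng.integers(0, 10_000)), name=f"r{i}")
        for i in range(500)
    ]
    t1 = bin_counts(weight_reads(reads), layout)
    shuffled = list(reads)
    rng.shuffle(shuffled)
    t2 = bin_counts(weight_reads(shuffled), layout)
    assert np.array_equal(t1.values, t2.values)


# ---------------------------------------------------------- depth_normalize
def test_depth_normalize_halves_two_million(mb_layout):
    track = make_track(mb_layout, np.full(1000, 2000.0))  # total 2e6
    norm = depth_normalize(track)
    assert np.allclose(norm.values, 1000.0)


def test_depth_normalize_identity_at_one_million(mb_layout):
    track = make_track(mb_layout, np.full(1000, 1000.0))
    assert np.allclose(depth_normalize(track).values, track.values)


def test_depth_normalize_total_exactly_one_million(mb_layout, rng):
    track = make_track(mb_layout, rng.exponential(7.0, 1000))
    assert depth_normalize(track).total == pytest.approx(1_000_000.0)


def test_depth_normalize_idempotent(mb_layout, rng):
    track = make_track(mb_layout, rng.poisson(20, 1000).astype(float))
    once = depth_normalize(track)
    twice = depth_normalize(once)
    assert np.allclose(once.values, twice.values)


def test_depth_normalize_empty_library_errors(mb_layout):
    with pytest.raises(ValueError):
        depth_normalize(make_track(mb_layout, np.zeros(1000)))


# ----------------------------------------------- background_median_normalize
@pytest.fixture
def background(mb_layout):
    return RegionSet("bg", [Interval("chrI", 0, 200_000)])


def test_background_normalize_self_is_identity(mb_layout, rng, background):
    ref = make_track(mb_layout, rng.poisson(50, 1000) + 1.0, state="depth")
    out = background_median_normalize(ref, background, ref)
    assert np.allclose(out.values, ref.values)
    assert out.scale_log[-1][1] == pytest.approx(1.0)


def test_background_normalize_halves_doubled_track(mb_layout, rng, background):
    ref = make_track(mb_layout, rng.poisson(50, 1000) + 1.0, state="depth")
    doubled = make_track(mb_layout, ref.values * 2.0, state="depth")
    out = background_median_normalize(doubled, background, ref)
    assert np.allclose(out.values, ref.values)


def test_background_normalize_zero_median_errors(mb_layout, background):
    ref = make_track(mb_layout, np.ones(1000), state="depth")
    zeros = make_track(mb_layout, np.zeros(1000) + 1e-12, state="depth")
    zeros.values[:500] = 0  # background median 0
    with pytest.raises(ValueError):
        background_median_normalize(zeros, background, ref)


def test_background_normalize_recovers_planted_depletion():
    # mutant with global 1.6x depth shift and 0.2 domain depletion: the
    # group median over domain bins recovers 0.2 +/- 0.02 (10,000 bins)
    cfg = SimulationConfig(
        seed=3,
        chromosome_length=20_000_000,
        n_domains=100,
        domain_length=100_000,
        background_mean=25.0,
        domain_enrichment=12.0,
        dispersion=10.0,
        depletion_factors={"WT": 1.0, "mut": 0.2},
        n_grts_like=0,
        n_grh_like=0,
        library_depth_scalers={"H3K9me3_mut_rep1": 1.6},
    )
    genome, truth = generate_layout(cfg)
    wt = depth_normalize(simulate_bin_counts(cfg, genome, truth, Sample("H3K9me3", "WT", 1)))
    mut = depth_normalize(simulate_bin_counts(cfg, genome, truth, Sample("H3K9me3", "mut", 1)))
    dom = truth.domains.to_bin_mask(genome)
    assert dom.sum() == 10_000
    bg = RegionSet.from_bin_mask("bg", ~dom, genome)
    mut_bg = background_median_normalize(mut, bg, wt)
    ref = wt.with_values(wt.values, "depth+background", ("background-median", 1.0))
    delta = compute_ratio(mut_bg, ref, 0.0)
    assert float(np.median(delta.values[dom])) == pytest.approx(0.2, abs=0.02)


# ------------------------------------------------------------ moving_average
def test_moving_average_constant_is_constant(mb_layout):
    track = make_track(mb_layout, np.full(1000, 3.5))
    assert np.allclose(moving_average(track, 50_000).values, 3.5)


def test_moving_average_single_bin_plateau(mb_layout):
    values = np.zeros(1000)
    values[500] = 9.0
    track = make_track(mb_layout, values)
    sm = moving_average(track, 3000).values
    assert np.allclose(sm[499:502], 3.0)
    assert sm[498] == 0.0 and sm[502] == 0.0


def test_moving_average_matches_brute_force(layout, rng):
    track = make_track(layout, rng.random(15))
    window = 5000
    sm = moving_average(track, window).values
    # oracle: explicit midpoint scan per chromosome
    for chrom in layout.chromosomes:
        sl = layout.chrom_slice(chrom)
        v = track.values[sl]
        centers = (np.arange(v.size) + 0.5) * 1000
        for i, c in enumerate(centers):
            sel = np.abs(centers - c) <= window / 2
            assert sm[sl][i] == pytest.approx(v[sel].mean(), abs=1e-12)


def test_moving_average_never_crosses_chromosomes(layout):
    values = np.zeros(15)
    values[9] = 10.0  # last chrI bin
    sm = moving_average(make_track(layout, values), 5000).values
    assert not sm[10:].any()  # chrII untouched


def test_moving_average_window_below_bin_size_errors(mb_layout):
    with pytest.raises(ValueError):
        moving_average(make_track(mb_layout, np.zeros(1000)), 500)


def test_moving_average_is_linear(mb_layout, rng):
    x = make_track(mb_layout, rng.random(1000))
    y = make_track(mb_layout, rng.random(1000))
    combo = make_track(mb_layout, 2.0 * x.values + 3.0 * y.values)
    lhs = moving_average(combo, 7000).values
    rhs = 2.0 * moving_average(x, 7000).values + 3.0 * moving_average(y, 7000).values
    assert np.allclose(lhs, rhs)


# --------------------------------------------------------- stranded_coverage
@pytest.fixture
def genes():
    return RegionSet(
        "genes",
        [
            Interval("chrI", 0, 3000, "+", "gplus"),
            Interval("chrI", 5000, 8000, "-", "gminus"),
        ],
    )


def test_plus_read_in_plus_gene_is_sense(layout, genes):
    sense, anti = stranded_coverage([AlignedReadRecord("chrI", 100, strand="+")], genes, layout)
    assert sense.values[0] == 1.0 and anti.values.sum() == 0.0


def test_plus_read_in_minus_gene_is_antisense(layout, genes):
    sense, anti = stranded_coverage([AlignedReadRecord("chrI", 5100, strand="+")], genes, layout)
    assert anti.values[5] == 1.0 and sense.values.sum() == 0.0


def test_read_outside_genes_uses_plus_convention(layout, genes):
    sense, anti = stranded_coverage(
        [
            AlignedReadRecord("chrI", 4100, strand="+"),
            AlignedReadRecord("chrI", 4200, strand="-"),
        ],
        genes,
        layout,
    )
    assert sense.values[4] == 1.0 and anti.values[4] == 1.0
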