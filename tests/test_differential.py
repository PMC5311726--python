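import math

import numpy as np
import pytest

from nucrnai import (
    DependencyCriteria,
    DependencySet,
    GenomeLayout,
    SignificanceConfig,
    bin_test,
    call_changed_bins,
    call_dependent_regions,
    compute_ratio,
    venn_overlap,
)

from conftest import make_track


# ------------------------------------------------------------ compute_ratio
def test_identical_tracks_ratio_one(mb_layout, rng):
    t = make_track(mb_layout, rng.poisson(30, 1000) + 1.0, state="depth")
    for c in (0.0, 0.5, 2.0):
        assert np.allclose(compute_ratio(t, t, c).values, 1.0)


def test_ratio_plain_division(mb_layout):
    num = make_track(mb_layout, np.full(1000, 30.0), state="depth")
    den = make_track(mb_layout, np.full(1000, 100.0), state="depth")
    assert np.allclose(compute_ratio(num, den, 0.0).values, 0.3)


def test_ratio_pseudocount_protects_zero():
    # oracle: (0 + 1) / (100 + 1)
    layout = GenomeLayout(("chrI",), (1000,), 1000)
    num = make_track(layout, [0.0], state="depth")
    den = make_track(layout, [100.0], state="depth")
    assert compute_ratio(num, den, 1.0).values[0] == pytest.approx(1.0 / 101.0)


def test_ratio_swap_is_reciprocal_without_pseudocount(mb_layout, rng):
    a = make_track(mb_layout, rng.poisson(30, 1000) + 1.0, state="depth")
    b = make_track(mb_layout, rng.poisson(30, 1000) + 1.0, state="depth")
    fw = compute_ratio(a, b, 0.0).values
    bw = compute_ratio(b, a, 0.0).values
    assert np.allclose(fw, 1.0 / bw)


def test_ratio_rejects_state_mismatch(mb_layout):
    raw = make_track(mb_layout, np.ones(1000))
    depth = make_track(mb_layout, np.ones(1000), state="depth")
    with pytest.raises(ValueError):
        compute_ratio(raw, depth)


def test_ratio_rejects_layout_mismatch(mb_layout, layout):
    a = make_track(mb_layout, np.ones(1000), state="depth")
    b = make_track(layout, np.ones(15), state="depth")
    with pytest.raises(Exception):
        compute_ratio(a, b)


# ----------------------------------------------------------------- bin_test
def test_bin_test_equal_counts_equal_depths_p_one():
    assert bin_test(7, 7, 1e6, 1e6) == 1.0


def test_bin_test_extreme_split_exact_value():
    # oracle: 2 * (1/2)**10
    assert bin_test(0, 10, 5e6, 5e6) == pytest.approx(0.001953125)
    assert bin_test(10, 0, 5e6, 5e6) == pytest.approx(0.001953125)


def test_bin_test_empty_bin_p_one():
    assert bin_test(0, 0, 1e6, 1e6) == 1.0


def test_bin_test_matches_enumeration_oracle_small_counts():
    def oracle(a, b, da, db):
        n = a + b
        if n == 0:
            return 1.0
        p0 = da / (da + db)
        pmf = [math.comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)]
        return min(1.0, 2.0 * min(sum(pmf[: a + 1]), sum(pmf[a:])))

    for da, db in [(1e6, 1e6), (1e6, 3e6)]:
        for n in range(0, 31):
            for a in range(n + 1):
                assert bin_test(a, n - a, da, db) == pytest.approx(
                    oracle(a, n - a, da, db), rel=1e-9
                ), (a, n - a, da, db)


def test_bin_test_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bin_test(-1, 2, 1.0, 1.0)
    with pytest.raises(ValueError):
        bin_test(1, 2, 0.0, 1.0)


# --------------------------------------------------------- call_changed_bins
def test_null_self_comparison_no_calls(mb_layout, rng):
    t = make_track(mb_layout, rng.poisson(40, 1000).astype(float))
    assert call_changed_bins(t, t).n_changed == 0


def test_low_count_large_ratio_not_called(mb_layout):
    # delta 0.45-ish from counts (2 vs 4): exact test cannot reach
    # significance, verified against the binomial oracle p = 0.6875
    values_a = np.full(1000, 50.0)
    values_b = np.full(1000, 50.0)
    values_a[0], values_b[0] = 2.0, 4.0
    res = call_changed_bins(
        make_track(mb_layout, values_a), make_track(mb_layout, values_b), depths=(1.0, 1.0)
    )
    assert res.pvalues[0] == pytest.approx(2 * sum(
        math.comb(6, k) * 0.5**6 for k in range(3)), rel=1e-6)
    assert not res.changed[0]


def test_curve_and_calls_never_disagree(mb_layout, rng):
    a = make_track(mb_layout, rng.poisson(30, 1000).astype(float) * rng.choice([1, 1, 1, 4], 1000))
    b = make_track(mb_layout, rng.poisson(30, 1000).astype(float))
    res = call_changed_bins(a, b)
    ai = np.rint(a.values).astype(int)
    bi = np.rint(b.values).astype(int)
    assert np.array_equal(res.changed, res.curve.is_changed(ai, bi))


def test_symmetry_under_swap(mb_layout, rng):
    a = make_track(mb_layout, (rng.poisson(30, 1000) * rng.choice([1, 1, 3], 1000)).astype(float))
    b = make_track(mb_layout, rng.poisson(30, 1000).astype(float))
    fw = call_changed_bins(a, b)
    bw = call_changed_bins(b, a)
    assert np.array_equal(fw.changed, bw.changed)
    nz = (np.rint(a.values) + np.rint(b.values)) > 0
    assert np.allclose(fw.pvalues[nz], bw.pvalues[nz])


def test_monotonic_in_fold_and_alpha(mb_layout, rng):
    a = make_track(mb_layout, (rng.poisson(25, 1000) * rng.choice([1, 1, 2, 5], 1000)).astype(float))
    b = make_track(mb_layout, rng.poisson(25, 1000).astype(float))
    base = call_changed_bins(a, b, SignificanceConfig(fold=2.0, alpha=0.05))
    stricter_fold = call_changed_bins(a, b, SignificanceConfig(fold=3.0, alpha=0.05))
    stricter_alpha = call_changed_bins(a, b, SignificanceConfig(fold=2.0, alpha=0.01))
    assert not np.any(stricter_fold.changed & ~base.changed)
    assert not np.any(stricter_alpha.changed & ~base.changed)


@pytest.mark.parametrize("alpha", [0.01, 0.05, 0.1])
def test_null_fdp_controlled(alpha):
    layout = GenomeLayout(("chrI",), (10_000_000,), 1000)
    fdps = []
    for seed in range(10):
        r = np.random.default_rng(seed)
        a = make_track(layout, r.poisson(50, 10_000).astype(float))
        b = make_track(layout, r.poisson(50, 10_000).astype(float))
        res = call_changed_bins(a, b, SignificanceConfig(fold=2.0, alpha=alpha))
        fdps.append(1.0 if res.n_changed else 0.0)
    assert np.mean(fdps) <= alpha + 0.1  # Monte-Carlo slack


# ---------------------------------------------------- call_dependent_regions
def _grid_tracks(ratios, wt_per_bin=10_000.0):
    layout = GenomeLayout(("chrI",), (len(ratios) * 1000,), 1000)
    mut = make_track(layout, np.rint(wt_per_bin * np.asarray(ratios)))
    wt = make_track(layout, np.full(len(ratios), wt_per_bin))
    return layout, mut, wt


def test_dependency_cutoff_is_half():
    # ratios 0.01..1.00: with overwhelming significance everywhere the
    # filter must keep exactly the bins with delta <= 0.50
    ratios = np.arange(1, 101) / 100.0
    _, mut, wt = _grid_tracks(ratios)
    dep = call_dependent_regions(
        [(mut, wt), (mut, wt)], DependencyCriteria(), depths=[(1.0, 1.0)] * 2
    )
    retained = ratios[dep.mask]
    assert retained.max() == pytest.approx(0.50)
    assert np.array_equal(dep.mask, ratios <= 0.50 + 1e-12)


def test_single_replicate_qualification_excluded():
    ratios = np.full(50, 0.2)
    layout, mut, wt = _grid_tracks(ratios)
    null_mut = make_track(layout, wt.values.copy())
    dep = call_dependent_regions(
        [(mut, wt), (null_mut, wt)], DependencyCriteria(), depths=[(1.0, 1.0)] * 2
    )
    assert dep.total_kb == 0.0


def test_more_replicates_shrink_the_set(rng):
    layout = GenomeLayout(("chrI",), (2_000_000,), 1000)
    pairs = []
    for seed in range(3):
        r = np.random.default_rng(seed)
        mut = make_track(layout, r.poisson(np.where(np.arange(2000) < 300, 12, 50)).astype(float))
        wt = make_track(layout, r.poisson(50, 2000).astype(float))
        pairs.append((mut, wt))
    two = call_dependent_regions(pairs[:2], DependencyCriteria(replicates_required=2))
    three = call_dependent_regions(pairs, DependencyCriteria(replicates_required=2))
    single = call_dependent_regions(pairs[:1], DependencyCriteria(replicates_required=1))
    assert not np.any(three.mask & ~two.mask)
    assert not np.any(two.mask & ~single.mask)


def test_too_few_replicates_error(mb_layout):
    t = make_track(mb_layout, np.ones(1000))
    with pytest.raises(ValueError):
        call_dependent_regions([(t, t)], DependencyCriteria(replicates_required=2))


def test_total_kb_counts_member_bins():
    ratios = np.array([0.1] * 5 + [1.0] * 5)
    _, mut, wt = _grid_tracks(ratios)
    dep = call_dependent_regions(
        [(mut, wt)], DependencyCriteria(replicates_required=1), depths=[(1.0, 1.0)]
    )
    assert dep.total_kb == 5.0
    assert dep.regions.total_kb == 5.0


# -------------------------------------------------------------- venn_overlap
def _dep(label, layout, mask):
    return DependencySet(label, layout, mask)


def test_disjoint_sets_no_intersection(mb_layout):
    m1 = np.zeros(1000, bool)
    m2 = np.zeros(1000, bool)
    m1[:100] = True
    m2[200:350] = True
    cells = venn_overlap([_dep("A", mb_layout, m1), _dep("B", mb_layout, m2)])
    assert cells["A&B"] == 0.0
    assert cells["A"] == 100.0 and cells["B"] == 150.0


def test_identical_sets_full_intersection(mb_layout):
    m = np.zeros(1000, bool)
    m[::7] = True
    cells = venn_overlap([_dep("A", mb_layout, m), _dep("B", mb_layout, m.copy())])
    assert cells["A&B"] == _dep("A", mb_layout, m).total_kb
    assert cells["A"] == 0.0 and cells["B"] == 0.0


def test_venn_matches_brute_force_tally(mb_layout, rng):
    masks = [rng.random(1000) < p for p in (0.2, 0.3, 0.15)]
    sets = [_dep(l, mb_layout, m) for l, m in zip("ABC", masks)]
    cells = venn_overlap(sets)
    # oracle: per-bin membership loop
    expected = {}
    for i in range(1000):
        key = "&".join(l for l, m in zip("ABC", masks) if m[i])
        if key:
            expected[key] = expected.get(key, 0.0) + 1.0
    for key, kb in cells.items():
        assert kb == expected.get(key, 0.0)
    assert sum(cells.values()) == pytest.approx(
        float((masks[0] | masks[1] | masks[2]).sum())
    )
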