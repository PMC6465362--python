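import numpy as np
import pytest
from scipy import stats as sps

from pmdscape.intervals import IntervalSet, overlap_stats
from pmdscape.io import GenomeLayout
from pmdscape.stats import (border_null_distribution, boundary_profile,
                            density_by_frequency, frequency_fraction_curve,
                            frequency_track, genome_fraction, shuffle_pmds)

from conftest import brute_force_coverage


def layout_1k():
    return GenomeLayout(chrom_sizes={"chr1": 1_000})


def layout_toy(L=300_000, excl=None):
    return GenomeLayout(chrom_sizes={"chr1": L},
                        excluded=IntervalSet(excl or []))


# -------------------------------------------------------- genome_fraction

def test_genome_fraction_worked_example():
    pmds = IntervalSet([("chr1", 0, 100), ("chr1", 200, 400)])
    assert genome_fraction(pmds, layout_1k()) == pytest.approx(0.30)


def test_genome_fraction_edges():
    assert genome_fraction(IntervalSet(), layout_1k()) == 0.0
    assert genome_fraction(IntervalSet([("chr1", 0, 1_000)]), layout_1k()) == 1.0


def test_genome_fraction_excludes_excluded_regions():
    layout = layout_toy(L=1_000, excl=[("chr1", 0, 200)])
    pmds = IntervalSet([("chr1", 100, 300)])  # 100 bp overlap the excluded block
    assert genome_fraction(pmds, layout) == pytest.approx(100 / 800)


def test_genome_fraction_random_sets_match_per_bp(rng):
    L = 5_000
    layout = layout_toy(L=L)
    for _ in range(100):
        n = rng.integers(1, 10)
        rows = []
        for _ in range(n):
            s = int(rng.integers(0, L - 10))
            rows.append(("chr1", s, int(min(L, s + rng.integers(1, 500)))))
        iset = IntervalSet(rows)
        cov = brute_force_coverage([(s, e) for _, s, e in rows], L)
        assert genome_fraction(iset, layout) == pytest.approx((cov > 0).mean())


# ------------------------------------------------------- frequency track

def test_frequency_track_worked_example():
    # identical PMD spanning tiles 3..5 (tile 100): [320, 580)
    layout = layout_toy(L=1_000)
    pmds = IntervalSet([("chr1", 320, 580)])
    track = frequency_track([pmds, pmds.copy()], layout, tile_bp=100, mode="coverage")
    assert track.df.freq.tolist() == [0, 0, 0, 2, 2, 2, 0, 0, 0, 0]
    border = frequency_track([pmds, pmds.copy()], layout, tile_bp=100, mode="border")
    assert border.df.freq.tolist() == [0, 0, 0, 2, 0, 2, 0, 0, 0, 0]


def test_frequency_track_union_intersection_match_interval_arithmetic(rng, mini_cohort):
    layout = mini_cohort.layout
    sets = list(mini_cohort.truth.pmds_by_sample.values())
    track = frequency_track(sets, layout, tile_bp=10_000)
    curve = frequency_fraction_curve(track)
    union = sets[0]
    inter = sets[0]
    for s in sets[1:]:
        union = union.union(s)
        inter = inter.intersection(s)
    # tile granularity: fractions agree to within one tile per interval edge
    union_frac = union.subtract(layout.excluded).total_length() / layout.non_excluded_length()
    n_edges = sum(len(s) for s in sets) * 2
    tol = n_edges * 10_000 / layout.non_excluded_length()
    assert curve[1] == pytest.approx(union_frac, abs=tol)
    inter_frac = inter.subtract(layout.excluded).total_length() / layout.non_excluded_length()
    assert curve[len(sets)] == pytest.approx(inter_frac, abs=tol)


def test_frequency_curve_monotone_and_per_bp(rng):
    L = 10_000
    layout = layout_toy(L=L)
    sets = []
    for k in range(4):
        rows = []
        for _ in range(5):
            s = int(rng.integers(0, L - 500))
            rows.append(("chr1", s, s + int(rng.integers(100, 500))))
        sets.append(IntervalSet(rows).merged())
    track = frequency_track(sets, layout, tile_bp=1)  # 1-bp tiles = per-bp
    curve = frequency_fraction_curve(track)
    assert all(curve[f] >= curve[f + 1] for f in range(4))
    cov = np.zeros(L, dtype=int)
    for s in sets:
        c = brute_force_coverage([(r.start, r.end) for r in s.df.itertuples()], L)
        cov += (c > 0).astype(int)
    for f in range(5):
        assert curve[f] == pytest.approx((cov >= f).mean())


def test_frequency_curve_rejects_border_mode():
    layout = layout_toy(L=1_000)
    track = frequency_track([IntervalSet([("chr1", 0, 100)])], layout,
                            tile_bp=100, mode="border")
    with pytest.raises(ValueError, match="coverage"):
        frequency_fraction_curve(track)


def test_single_sample_curve_is_step():
    layout = layout_toy(L=1_000)
    track = frequency_track([IntervalSet([("chr1", 0, 500)])], layout, tile_bp=100)
    curve = frequency_fraction_curve(track)
    assert curve[0] == 1.0 and curve[1] == 0.5


def test_frequency_conservation(mini_cohort):
    layout = mini_cohort.layout
    track = frequency_track(list(mini_cohort.truth.pmds_by_sample.values()),
                            layout, tile_bp=30_000)
    assert track.df.eff_bp.sum() == layout.non_excluded_length()


# -------------------------------------------------------------- shuffles

def test_shuffle_preserves_length_multiset(rng):
    layout = layout_toy(L=500_000, excl=[("chr1", 200_000, 210_000)])
    rows = [("chr1", 0, 10_000), ("chr1", 50_000, 75_000), ("chr1", 400_000, 460_000)]
    pmds = IntervalSet(rows)
    for seed in range(20):
        sh = shuffle_pmds(pmds, layout, seed=seed)
        assert sorted((sh.df.end - sh.df.start)) == sorted(e - s for _, s, e in rows)
        assert sh.is_nonoverlapping()
        assert sh.intersection(layout.excluded).total_length() == 0


def test_shuffle_single_interval_uniform_start():
    """KS test of the placed start against Uniform(0, L - len)."""
    L, ln = 100_000, 10_000
    layout = layout_toy(L=L)
    pmds = IntervalSet([("chr1", 0, ln)])
    starts = [shuffle_pmds(pmds, layout, seed=s).df.start.iloc[0] for s in range(2_000)]
    stat = sps.kstest(np.array(starts) / (L - ln), "uniform")
    assert stat.pvalue > 0.01


def test_shuffle_infeasible_occupancy_raises():
    layout = layout_toy(L=1_000)
    # 99.9% occupancy: placement of both intervals is (almost surely) impossible
    pmds = IntervalSet([("chr1", 0, 500), ("chr1", 500, 999)])
    with pytest.raises(ValueError, match="chr1"):
        shuffle_pmds(pmds, layout, seed=0, max_attempts=50, max_restarts=2)


def test_shuffle_null_mean_matches_analytic(mini_cohort):
    """Coverage-mode null per-tile frequency mean ~= sum of per-sample
    per-chromosome coverage fractions (within 3 s.e. over 200 shuffles)."""
    layout = mini_cohort.layout
    sets = list(mini_cohort.truth.pmds_by_sample.values())
    tile_bp = 30_000
    null = border_null_distribution(sets, layout, tile_bp=tile_bp,
                                    n_shuffles=200, seed=5, mode="coverage")
    # analytic: tile covered by sample s with prob ~ coverage fraction
    # (slightly larger because any >=1 bp overlap counts; use bp-occupancy
    # expectation with edge correction len/(len+tile) per interval)
    L = layout.chrom_sizes["chr1"]
    expect = 0.0
    for s in sets:
        lens = (s.df.end - s.df.start).to_numpy()
        # P(tile hit) = sum over intervals of (len + tile - 1) / L approx
        expect += np.minimum((lens + tile_bp - 1), L).sum() / L
    se = null.null_tile_sd / np.sqrt(null.n_shuffles)
    assert null.null_tile_mean == pytest.approx(expect, abs=3 * se + 0.05 * expect)


def test_border_null_requires_two_shuffles(mini_cohort):
    with pytest.raises(ValueError, match="2 shuffles"):
        border_null_distribution(list(mini_cohort.truth.pmds_by_sample.values()),
                                 mini_cohort.layout, n_shuffles=1, seed=0)


def test_identical_cohort_bimodal_observed():
    layout = layout_toy(L=300_000)
    pmds = IntervalSet([("chr1", 100_000, 200_000)])
    cohort = [pmds.copy() for _ in range(6)]
    null = border_null_distribution(cohort, layout, tile_bp=10_000,
                                    n_shuffles=5, seed=1, mode="coverage")
    observed = null.observed_hist
    assert observed[0] > 0 and observed[6] > 0
    assert sum(observed[f] for f in range(1, 6)) == 0


def test_observed_mode_zero_null_mode_positive(mini_cohort):
    layout = mini_cohort.layout
    sets = list(mini_cohort.truth.pmds_by_sample.values())
    null = border_null_distribution(sets, layout, tile_bp=30_000,
                                    n_shuffles=20, seed=3, mode="coverage")
    assert null.observed_mode == 0
    assert null.null_mode > 0


# ----------------------------------------------------------- overlap stats

def test_interval_set_overlap_random_vs_per_bp(rng):
    L = 5_000
    for _ in range(10):
        rows_a = [("chr1", int(s), int(s) + int(rng.integers(1, 400)))
                  for s in rng.integers(0, L - 400, 8)]
        rows_b = [("chr1", int(s), int(s) + int(rng.integers(1, 400)))
                  for s in rng.integers(0, L - 400, 8)]
        a, b = IntervalSet(rows_a), IntervalSet(rows_b)
        cov_a = brute_force_coverage([(s, e) for _, s, e in rows_a], L) > 0
        cov_b = brute_force_coverage([(s, e) for _, s, e in rows_b], L) > 0
        st = overlap_stats(a, b)
        inter = (cov_a & cov_b).sum()
        union = (cov_a | cov_b).sum()
        assert st["jaccard"] == pytest.approx(inter / union)


# -------------------------------------------------------- boundary profile

def test_boundary_profile_constant_signal():
    pmds = IntervalSet([("chr1", 100_000, 200_000)])
    signal = {"chr1": np.full(300, 7.0)}  # 1-kb bins
    profile, used, excluded = boundary_profile(signal, 1_000, pmds,
                                               flank_bp=20_000, n_bins=20)
    np.testing.assert_allclose(profile, 7.0)
    assert used == 2 and excluded == 0


def test_boundary_profile_step_signal_crosses_half():
    """Signal = 1 inside planted PMDs -> sigmoid crossing 0.5 at the edge."""
    pmds = IntervalSet([("chr1", 100_000, 200_000)])
    sig = np.zeros(300)
    sig[100:200] = 1.0
    profile, used, _ = boundary_profile({"chr1": sig}, 1_000, pmds,
                                        flank_bp=20_000, n_bins=40)
    assert used == 2
    # orientation outside -> inside: first half ~0, second half ~1
    assert profile[:19].mean() < 0.1
    assert profile[21:].mean() > 0.9


def test_boundary_profile_short_pmds_excluded():
    pmds = IntervalSet([("chr1", 100_000, 105_000)])
    profile, used, excluded = boundary_profile({"chr1": np.ones(300)}, 1_000,
                                               pmds, flank_bp=20_000, n_bins=10)
    assert used == 0 and excluded == 1


# ---------------------------------------------------- density by frequency

def test_density_uniform_points_flat(rng):
    layout = layout_toy(L=1_000_000)
    sets = [IntervalSet([("chr1", 0, 500_000)]),
            IntervalSet([("chr1", 250_000, 750_000)])]
    track = frequency_track(sets, layout, tile_bp=10_000)
    n_feat = 4_000
    starts = rng.integers(0, 1_000_000 - 10, n_feat)
    feats = IntervalSet([("chr1", int(s), int(s) + 5) for s in starts])
    table = density_by_frequency(feats, track)
    assert table["count"].sum() == n_feat
    dens = table.dropna(subset=["density_per_mb"])
    expected = n_feat / 1.0  # per Mb over a 1-Mb genome
    for _, row in dens.iterrows():
        if row.mb < 0.05:
            continue
        se = np.sqrt(expected / row.mb)  # Poisson
        assert row.density_per_mb == pytest.approx(expected, abs=3 * se)


def test_density_empty_class_missing():
    layout = layout_toy(L=100_000)
    sets = [IntervalSet([("chr1", 0, 100_000)])]  # whole genome at freq 1
    track = frequency_track(sets, layout, tile_bp=10_000)
    feats = IntervalSet([("chr1", 10, 20)])
    table = density_by_frequency(feats, track)
    assert np.isnan(table.loc[table.freq == 0, "density_per_mb"]).all()
    assert table.loc[table.freq == 1, "count"].iloc[0] == 1
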