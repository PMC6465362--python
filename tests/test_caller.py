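import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln
from scipy.stats import norm

from pmdscape.caller import (PmdCallConfig, aggregate_pmds_sd, bb_loglik, call_pmds,
                             fit_alpha, pmds_present, segment, window_alpha)
from pmdscape.hmm import forward_backward
from pmdscape.intervals import IntervalSet, overlap_stats
from pmdscape.io import GenomeLayout, SampleMethylome
from pmdscape.simulate import SimConfig, generate_cohort


# ------------------------------------------------------------ oracles

def bb_loglik_oracle(m, t, alpha, mhat):
    """Independent scalar-loop beta-binomial log-likelihood."""
    beta = alpha * (1 - mhat) / mhat
    return sum(float(betaln(mi + alpha, ti - mi + beta) - betaln(alpha, beta))
               for mi, ti in zip(m, t))


def golden_alpha_oracle(m, t, mhat, lo=-6.0, hi=6.0, tol=1e-9):
    """Plain scalar golden-section maximization, written independently."""
    invphi = (np.sqrt(5) - 1) / 2
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1 = bb_loglik_oracle(m, t, np.exp(x1), mhat)
    f2 = bb_loglik_oracle(m, t, np.exp(x2), mhat)
    while hi - lo > tol:
        if f1 < f2:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + invphi * (hi - lo)
            f2 = bb_loglik_oracle(m, t, np.exp(x2), mhat)
        else:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - invphi * (hi - lo)
            f1 = bb_loglik_oracle(m, t, np.exp(x1), mhat)
    return np.exp((lo + hi) / 2)


def brute_force_posteriors(log_em, p_stay, init):
    """Exhaustive enumeration of all 2^n state paths."""
    n = log_em.shape[0]
    post = np.zeros((n, 2))
    total = 0.0
    for path in itertools.product([0, 1], repeat=n):
        logp = np.log(init[path[0]]) + log_em[0, path[0]]
        for t in range(1, n):
            logp += np.log(p_stay if path[t] == path[t - 1] else 1 - p_stay)
            logp += log_em[t, path[t]]
        p = np.exp(logp)
        total += p
        for t in range(n):
            post[t, path[t]] += p
    return post / total


def make_single_pmd_sample(seed, L=10_000_000, pmd=(4_000_000, 6_000_000),
                           spacing=150, cov=10.0, pmd_mean=0.55, bg_mean=0.85,
                           pmd_conc=6.0, bg_conc=0.8):
    """Hand-built methylome with one planted PMD (independent of the generator)."""
    rng = np.random.default_rng(seed)
    pos = np.unique(np.cumsum(rng.exponential(spacing, int(L / spacing * 1.1)).astype(int) + 2))
    pos = pos[pos < L]
    inside = (pos >= pmd[0]) & (pos < pmd[1])
    mean = np.where(inside, pmd_mean, bg_mean)
    conc = np.where(inside, pmd_conc, bg_conc)
    p = rng.beta(mean * conc, (1 - mean) * conc)
    t = rng.negative_binomial(5, 5 / (5 + cov), len(pos))
    m = rng.binomial(t, p)
    meth = SampleMethylome(f"s{seed}", pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "m": m, "t": t}))
    return meth, GenomeLayout(chrom_sizes={"chr1": L})


# ------------------------------------------------------------- alpha ML

def test_alpha_matches_golden_oracle_random_windows(rng):
    for _ in range(50):
        n = 101
        mean = rng.uniform(0.15, 0.9)
        conc = np.exp(rng.uniform(-1.5, 2.0))  # interior optima with curvature
        p = rng.beta(mean * conc, (1 - mean) * conc, n)
        t = rng.integers(5, 50, n).astype(float)
        m = rng.binomial(t.astype(int), p).astype(float)
        mhat = np.clip(m.sum() / t.sum(), 1e-6, 1 - 1e-6)
        got = fit_alpha(m[None, :], t[None, :], np.array([mhat]), tol=1e-9)[0]
        want = golden_alpha_oracle(m, t, mhat)
        assert np.log(got) == pytest.approx(np.log(want), abs=1e-6)


def test_alpha_polarized_window_below_one():
    # every CpG fully methylated at coverage 10 -> maximally polarized
    t = np.full(101, 10.0)
    m = t.copy()
    mhat = 1 - 1e-6
    got = fit_alpha(m[None, :], t[None, :], np.array([mhat]), tol=1e-9)[0]
    assert got < 1.0
    assert golden_alpha_oracle(m, t, mhat) < 1.0


def test_alpha_intermediate_window_above_one(rng):
    t = np.full(101, 50.0)
    m = rng.binomial(50, 0.5, 101).astype(float)
    mhat = m.sum() / t.sum()
    got = fit_alpha(m[None, :], t[None, :], np.array([mhat]), tol=1e-9)[0]
    assert got > 1.0
    assert golden_alpha_oracle(m, t, mhat) > 1.0


def test_symmetric_mean_gives_symmetric_beta():
    # constraint beta = alpha * (1 - mhat) / mhat: equal shapes at mhat = 0.5
    m = np.array([1.0, 2.0, 3.0])
    t = np.array([4.0, 4.0, 4.0])
    ll_a = bb_loglik(m, t, 2.0, 0.5)
    ll_b = bb_loglik(t - m, t, 2.0, 0.5)  # mirrored counts, same likelihood
    assert ll_a == pytest.approx(ll_b, rel=1e-12)


@pytest.mark.parametrize("true_alpha", [0.3, 1.0, 3.0])
def test_alpha_recovery_within_15_percent(true_alpha, rng):
    m_true = 0.7
    beta = true_alpha * (1 - m_true) / m_true
    est = []
    for _ in range(200):
        p = rng.beta(true_alpha, beta, 101)
        t = rng.integers(8, 40, 101).astype(float)
        m = rng.binomial(t.astype(int), p).astype(float)
        mhat = np.clip(m.sum() / t.sum(), 1e-6, 1 - 1e-6)
        est.append(fit_alpha(m[None, :], t[None, :], np.array([mhat]))[0])
    assert abs(np.median(est) - true_alpha) / true_alpha < 0.15


# ----------------------------------------------------------------- HMM

def test_forward_backward_matches_enumeration(rng):
    for n in (3, 7, 12):
        log_em = rng.normal(0, 2, size=(n, 2))
        init = np.array([0.4, 0.6])
        post, _ = forward_backward(log_em, p_stay=0.8, init=init)
        want = brute_force_posteriors(log_em, 0.8, init)
        assert np.abs(post - want).max() < 1e-9


def test_forward_backward_rows_sum_to_one(rng):
    log_em = rng.normal(0, 3, size=(500, 2))
    post, _ = forward_backward(log_em, p_stay=0.995)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)


# ------------------------------------------------------------- windowing

def test_window_alpha_requires_enough_cpgs():
    df = pd.DataFrame({"chrom": "chr1", "pos": np.arange(0, 500, 10),
                       "m": 5, "t": 10})
    meth = SampleMethylome("s", df)
    layout = GenomeLayout(chrom_sizes={"chr1": 1_000})
    with pytest.raises(ValueError, match="eligible CpGs"):
        window_alpha(meth, layout, PmdCallConfig())


def test_windows_do_not_span_excluded_regions():
    rng = np.random.default_rng(0)
    pos = np.arange(0, 300_000, 100)
    t = np.full(len(pos), 10)
    m = rng.binomial(10, 0.9, len(pos))
    meth = SampleMethylome("s", pd.DataFrame({"chrom": "chr1", "pos": pos, "m": m, "t": t}))
    layout = GenomeLayout(chrom_sizes={"chr1": 300_000},
                          excluded=IntervalSet([("chr1", 150_000, 160_000)]))
    track = window_alpha(meth, layout, PmdCallConfig())
    # no window anchor inside the excluded region, and blocks split around it
    assert not ((track.df.pos >= 150_000) & (track.df.pos < 160_000)).any()
    assert track.df.block.nunique() == 2


def test_presence_decision_order_invariant(mini_cohort):
    s = mini_cohort.samples[0]
    cfg = PmdCallConfig()
    track = window_alpha(s, mini_cohort.layout, cfg)
    dec1 = pmds_present(track, cfg)
    shuffled = track.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
    track.df = shuffled
    dec2 = pmds_present(track, cfg)
    assert dec1.present == dec2.present
    np.testing.assert_allclose(dec1.means, dec2.means, atol=1e-6)


def test_pmds_present_requires_min_windows():
    cfg = PmdCallConfig()
    from pmdscape.caller import AlphaTrack
    df = pd.DataFrame({"chrom": "chr1", "pos": range(10), "n_cpgs": 101,
                       "mhat": 0.8, "alpha": 0.5, "log_alpha": -0.7, "block": 0})
    with pytest.raises(ValueError, match="windows"):
        pmds_present(AlphaTrack(df, cfg), cfg)


# ----------------------------------------------------------- segmentation

def test_single_planted_pmd_boundaries():
    meth, layout = make_single_pmd_sample(seed=9)
    pmds = call_pmds(meth, layout, PmdCallConfig())
    assert len(pmds) == 1
    row = pmds.df.iloc[0]
    tol = 10 * 150 * 2  # step x mean spacing x 2
    assert abs(row.start - 4_000_000) < tol
    assert abs(row.end - 6_000_000) < tol


def test_fully_methylated_sample_empty_call():
    rng = np.random.default_rng(3)
    pos = np.arange(0, 2_000_000, 150)
    t = rng.integers(5, 30, len(pos))
    meth = SampleMethylome("s", pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "m": t, "t": t}))
    layout = GenomeLayout(chrom_sizes={"chr1": 2_000_000})
    pmds = call_pmds(meth, layout, PmdCallConfig())
    assert len(pmds) == 0


def test_zero_contrast_cohort_empty_calls():
    cfg = SimConfig(chrom_sizes={"chr1": 6_000_000}, n_samples=2, seed=4,
                    pmd_mean_range=(0.85, 0.85), pmd_concentration=0.8)
    coh = generate_cohort(cfg)
    for s in coh.samples:
        assert len(call_pmds(s, coh.layout, PmdCallConfig())) == 0


def test_no_pmds_planted_not_present():
    cfg = SimConfig(chrom_sizes={"chr1": 6_000_000}, n_samples=1, seed=3,
                    propensity_ceiling=0.0)
    coh = generate_cohort(cfg)
    pmds, _track, dec = call_pmds(coh.samples[0], coh.layout, PmdCallConfig(),
                                  return_diagnostics=True)
    assert not dec.present
    assert len(pmds) == 0


def test_called_pmds_disjoint_in_bounds_avoid_excluded(mini_cohort, mini_calls):
    layout = mini_cohort.layout
    for pmds in mini_calls.values():
        assert pmds.is_nonoverlapping()
        assert pmds.intersection(layout.excluded).total_length() == 0
        for r in pmds.df.itertuples():
            assert 0 <= r.start < r.end <= layout.chrom_sizes[r.chrom]


def test_cohort_jaccard_against_planted(mini_cohort, mini_calls):
    for sid, pmds in mini_calls.items():
        truth = mini_cohort.truth.pmds_by_sample[sid]
        if truth.total_length() / 6e6 < 0.05:
            continue  # tiny plantings are legitimately hard; scored in acceptance
        assert overlap_stats(pmds, truth)["jaccard"] >= 0.90


def test_monotone_contrast_improves_recovery():
    jac = []
    for pmd_hi in (0.80, 0.65, 0.50):  # decreasing depth = increasing contrast
        cfg = SimConfig(chrom_sizes={"chr1": 6_000_000}, n_samples=1, seed=21,
                        pmd_mean_range=(pmd_hi - 1e-6, pmd_hi),
                        activity_range=(1.2, 1.2))
        coh = generate_cohort(cfg)
        s = coh.samples[0]
        pmds = call_pmds(s, coh.layout, PmdCallConfig())
        jac.append(overlap_stats(pmds, coh.truth.pmds_by_sample[s.sample_id])["jaccard"])
    assert jac[0] <= jac[1] + 0.02 and jac[1] <= jac[2] + 0.02
    assert jac[2] >= 0.9


# --------------------------------------------------------- aggregate caller

def test_aggregate_requires_three_samples(mini_cohort):
    with pytest.raises(ValueError, match="3 samples"):
        aggregate_pmds_sd(mini_cohort.samples[:2], mini_cohort.layout)


def test_aggregate_identical_samples_empty():
    rng = np.random.default_rng(0)
    pos = np.arange(0, 3_000_000, 150)
    t = np.full(len(pos), 10)
    m = rng.binomial(10, 0.85, len(pos))
    layout = GenomeLayout(chrom_sizes={"chr1": 3_000_000})
    samples = [SampleMethylome(f"s{i}", pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "m": m, "t": t})) for i in range(4)]
    assert len(aggregate_pmds_sd(samples, layout)) == 0


def test_aggregate_contains_per_sample_calls(mini_cohort, mini_calls):
    agg = aggregate_pmds_sd(mini_cohort.samples, mini_cohort.layout)
    for pmds in mini_calls.values():
        if pmds.total_length() == 0:
            continue
        st = overlap_stats(pmds, agg)
        assert st["frac_a_in_b"] >= 0.95


def test_aggregate_coverage_invariance(mini_cohort):
    """Doubling coverage leaves bin s.d. (of fractions) within MC noise."""
    import copy
    doubled = []
    for s in mini_cohort.samples:
        df = s.data.copy()
        df["m"] = df.m * 2
        df["t"] = df.t * 2
        doubled.append(SampleMethylome(s.sample_id, df, dict(s.metadata)))
    a = aggregate_pmds_sd(mini_cohort.samples, mini_cohort.layout)
    b = aggregate_pmds_sd(doubled, mini_cohort.layout)
    assert overlap_stats(a, b)["jaccard"] > 0.95
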