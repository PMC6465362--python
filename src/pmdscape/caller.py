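"""PMD segmentation from windowed beta-binomial polarization scores.

Per window of (by default) 101 eligible CpGs, the pooled mean ``m`` is fixed
and a beta-binomial ``BB(M | T, alpha, alpha*(1-m)/m)`` is fitted by maximum
likelihood in ``log(alpha)``.  ``alpha < 1`` indicates a polarized window
(counts piled at 0 and T: the hypermethylated background of a methylome with
hypomethylated islands); ``alpha >= 1`` indicates intermediate, dispersed
methylation, the PMD signature.  A two-component Gaussian mixture on
``log(alpha)`` decides whether a sample contains PMDs at all and supplies
emission parameters for a two-state HMM whose posterior decoding yields PMD
intervals.

An aggregate cross-sample caller classifies 100-kb bins by the
between-sample standard deviation of bin methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln
from sklearn.mixture import GaussianMixture

from .hmm import forward_backward
from .intervals import IntervalSet
from .io import GenomeLayout, SampleMethylome

logger = logging.getLogger(__name__)


@dataclass
class PmdCallConfig:
    window_cpgs: int = 101        # CpGs per window (odd)
    step_cpgs: int = 10           # window step in CpGs
    min_coverage: int = 5         # per-CpG coverage for eligibility
    persistence: float = 0.9995   # HMM self-transition per CpG step
    min_length: int = 10_000      # bp; shorter PMDs dropped
    min_cpgs: int = 101           # eligible CpGs; sparser PMDs dropped
    mode: str = "all"             # 'all' | 'solo_wcgw'
    refine_boundaries: bool = True  # CpG-level changepoint polish of HMM edges
    posterior_threshold: float = 0.5
    log_alpha_bounds: tuple[float, float] = (-6.0, 6.0)
    alpha_tol: float = 1e-6       # golden-section tolerance in log(alpha)
    min_windows: int = 200        # required by pmds_present
    min_component_separation_sd: float = 2.0
    min_component_gap: float = 0.1

    def __post_init__(self):
        if self.window_cpgs < 11 or self.window_cpgs % 2 == 0:
            raise ValueError("window_cpgs must be odd and >= 11")
        if not 0.5 < self.persistence < 1.0:
            raise ValueError("persistence must lie in (0.5, 1)")
        if self.mode not in ("all", "solo_wcgw"):
            raise ValueError("mode must be 'all' or 'solo_wcgw'")


@dataclass
class AlphaTrack:
    """Windowed polarization scores.  One row per evaluated window.

    ``df`` columns: chrom, pos (anchor = central CpG), n_cpgs, mhat, alpha,
    log_alpha, block (windows sharing a block are contiguous and may be
    chained by the HMM; blocks never span chromosomes or excluded regions).
    """

    df: pd.DataFrame
    config: PmdCallConfig
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MixtureDecision:
    present: bool
    reason: str
    means: np.ndarray | None = None       # ascending in log alpha
    sds: np.ndarray | None = None
    weights: np.ndarray | None = None
    bic1: float = float("nan")
    bic2: float = float("nan")
    histogram: pd.DataFrame | None = None


# ---------------------------------------------------------------- alpha ML

def bb_loglik(m: np.ndarray, t: np.ndarray, alpha, mhat) -> np.ndarray:
    """Mean-constrained beta-binomial log-likelihood (binomial coefficients,
    constant in alpha, omitted).

    ``m``/``t`` may be (n,) for one window or (w, n) for a batch; ``alpha``
    and ``mhat`` scalar or (w,).
    """
    alpha = np.asarray(alpha, dtype=float)
    mhat = np.asarray(mhat, dtype=float)
    beta = alpha * (1.0 - mhat) / mhat
    if m.ndim == 2 and alpha.ndim == 1:
        alpha = alpha[:, None]
        beta = beta[:, None]
    ll = betaln(m + alpha, t - m + beta) - betaln(alpha, beta)
    return ll.sum(axis=-1)


_INV_PHI = (np.sqrt(5.0) - 1.0) / 2.0


def fit_alpha(mw: np.ndarray, tw: np.ndarray, mhat: np.ndarray,
              bounds: tuple[float, float] = (-6.0, 6.0), tol: float = 1e-6,
              ) -> np.ndarray:
    """Vectorized golden-section ML of log(alpha) over a batch of windows.

    ``mw``/``tw``: (w, n) count matrices; ``mhat``: (w,) pooled means held
    fixed.  Returns the ML alpha per window.
    """
    mw = np.atleast_2d(np.asarray(mw, dtype=float))
    tw = np.atleast_2d(np.asarray(tw, dtype=float))
    mhat = np.atleast_1d(np.asarray(mhat, dtype=float))
    w = mw.shape[0]
    lo = np.full(w, float(bounds[0]))
    hi = np.full(w, float(bounds[1]))
    x1 = hi - _INV_PHI * (hi - lo)
    x2 = lo + _INV_PHI * (hi - lo)
    f1 = bb_loglik(mw, tw, np.exp(x1), mhat)
    f2 = bb_loglik(mw, tw, np.exp(x2), mhat)
    span = float(bounds[1] - bounds[0])
    n_iter = max(1, int(np.ceil(np.log(tol / span) / np.log(_INV_PHI))) + 1)
    for _ in range(n_iter):
        right = f1 < f2  # maximum lies in [x1, hi]
        lo = np.where(right, x1, lo)
        hi = np.where(right, hi, x2)
        x_keep = np.where(right, x2, x1)
        f_keep = np.where(right, f2, f1)
        x_new = np.where(right, lo + _INV_PHI * (hi - lo), hi - _INV_PHI * (hi - lo))
        f_new = bb_loglik(mw, tw, np.exp(x_new), mhat)
        x1 = np.where(right, x_keep, x_new)
        f1 = np.where(right, f_keep, f_new)
        x2 = np.where(right, x_new, x_keep)
        f2 = np.where(right, f_new, f_keep)
    return np.exp((lo + hi) / 2.0)


# ------------------------------------------------------------- windowing

def _eligible(methylome: SampleMethylome, config: PmdCallConfig,
              layout: GenomeLayout | None = None) -> pd.DataFrame:
    df = methylome.data
    mask = (df.t >= config.min_coverage).to_numpy()
    if config.mode == "solo_wcgw":
        if "is_solo_wcgw" not in df.columns:
            raise ValueError("solo_wcgw mode requires solo-WCGW annotation")
        mask &= df.is_solo_wcgw.to_numpy()
    if layout is not None and len(layout.excluded):
        mask &= ~layout.excluded.contains_points(df.chrom.to_numpy(), df.pos.to_numpy())
    return df[mask]


def window_alpha(methylome: SampleMethylome, layout: GenomeLayout,
                 config: PmdCallConfig | None = None) -> AlphaTrack:
    """Score sliding CpG windows with the polarization statistic alpha."""
    config = config or PmdCallConfig()
    elig = _eligible(methylome, config, layout)
    w = config.window_cpgs
    rows = []
    n_skipped = 0
    block_id = 0
    any_block = False
    for chrom, sub in elig.groupby("chrom", sort=True):
        pos = sub.pos.to_numpy()
        m = sub.m.to_numpy(dtype=float)
        t = sub.t.to_numpy(dtype=float)
        # cut into blocks wherever an excluded interval falls between CpGs
        exc_s, exc_e = layout.excluded._merged().get(chrom, (np.array([]), np.array([])))
        if len(exc_s):
            seg = np.searchsorted(exc_s, pos, side="right")
        else:
            seg = np.zeros(len(pos), dtype=int)
        for _, idx in pd.Series(np.arange(len(pos))).groupby(seg):
            i = idx.to_numpy()
            if len(i) < w:
                continue
            any_block = True
            bm, bt, bp = m[i], t[i], pos[i]
            starts = np.arange(0, len(i) - w + 1, config.step_cpgs)
            win_idx = starts[:, None] + np.arange(w)[None, :]
            mw = bm[win_idx]
            tw = bt[win_idx]
            st = tw.sum(axis=1)
            ok = st > 0
            n_skipped += int((~ok).sum())
            if not ok.any():
                continue
            mw, tw, starts, st = mw[ok], tw[ok], starts[ok], st[ok]
            mhat = np.clip(mw.sum(axis=1) / st, 1e-6, 1.0 - 1e-6)
            alpha = fit_alpha(mw, tw, mhat, config.log_alpha_bounds, config.alpha_tol)
            anchors = bp[starts + w // 2]
            rows.append(pd.DataFrame({
                "chrom": chrom, "pos": anchors, "n_cpgs": w, "mhat": mhat,
                "alpha": alpha, "log_alpha": np.log(alpha), "block": block_id}))
            block_id += 1
    if not any_block:
        raise ValueError(f"fewer than {w} eligible CpGs on every chromosome")
    df = (pd.concat(rows, ignore_index=True) if rows
          else pd.DataFrame(columns=["chrom", "pos", "n_cpgs", "mhat", "alpha",
                                     "log_alpha", "block"]))
    return AlphaTrack(df, config, n_skipped)


# ---------------------------------------------------------- presence test

def pmds_present(track: AlphaTrack, config: PmdCallConfig | None = None) -> MixtureDecision:
    """1- vs 2-component Gaussian mixture on log(alpha) decides PMD presence."""
    config = config or track.config
    x = track.df.log_alpha.to_numpy()
    if len(x) < config.min_windows:
        raise ValueError(f"need >= {config.min_windows} windows, got {len(x)}")
    hist_counts, hist_edges = np.histogram(x, bins=50)
    hist = pd.DataFrame({"left": hist_edges[:-1], "right": hist_edges[1:],
                         "count": hist_counts})
    if np.std(x) < 1e-8:
        return MixtureDecision(False, "degenerate alpha distribution", histogram=hist)
    X = x.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=0).fit(X)
    bic1 = g1.bic(X)
    # EM on a heavy-tailed background readily converges to a degenerate
    # split of the background itself, hiding a minority PMD component.  Fit
    # from the default inits and from a flank-anchored init, test the
    # presence criteria on each candidate, and accept any candidate that
    # passes all of them (tie-break: better BIC first).
    var = max(float(np.var(x)), 1e-6)
    candidates = [GaussianMixture(2, random_state=0, n_init=5).fit(X)]
    try:
        candidates.append(GaussianMixture(
            2, random_state=0,
            means_init=np.array([[np.quantile(x, 0.25)], [np.quantile(x, 0.995)]]),
            weights_init=np.array([0.95, 0.05]),
            precisions_init=np.array([[[4.0 / var]], [[4.0 / var]]]),
        ).fit(X))
    except ValueError:  # pragma: no cover - pathological inputs
        pass
    candidates.sort(key=lambda g: g.bic(X))

    def _verdict(g2) -> MixtureDecision:
        bic2 = g2.bic(X)
        order = np.argsort(g2.means_.ravel())
        means = g2.means_.ravel()[order]
        sds = np.sqrt(g2.covariances_.ravel()[order])
        weights = g2.weights_.ravel()[order]
        common = dict(means=means, sds=sds, weights=weights, bic1=bic1, bic2=bic2,
                      histogram=hist)
        if bic2 >= bic1:
            return MixtureDecision(False, "BIC favors one component", **common)
        gap = means[1] - means[0]
        # balanced pooling: weighting by component mass lets the dominant,
        # skewed background inflate the yardstick and mask a clean minority
        pooled_sd = float(np.sqrt((sds ** 2).mean()))
        if gap < config.min_component_gap:
            return MixtureDecision(False, "component means nearly coincide", **common)
        if gap < config.min_component_separation_sd * pooled_sd:
            return MixtureDecision(False, "components insufficiently separated", **common)
        if means[1] <= 0.0:
            return MixtureDecision(False, "high component not in alpha > 1 regime", **common)
        return MixtureDecision(True, "two separated components", **common)

    verdicts = [_verdict(g) for g in candidates]
    passing = [v for v in verdicts if v.present]
    if passing:
        # the best-separated fit gives the cleanest emission model downstream
        def sep(v):
            return (v.means[1] - v.means[0]) / np.sqrt((v.sds ** 2).mean())
        return max(passing, key=sep)
    return verdicts[0]


# ------------------------------------------------------------- segmentation

def _gaussian_log_emissions(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return (-0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :]) - 0.5 * np.log(2 * np.pi))


def segment(track: AlphaTrack, decision: MixtureDecision,
            layout: GenomeLayout, config: PmdCallConfig | None = None,
            methylome: SampleMethylome | None = None,
            n_baum_welch: int = 5) -> IntervalSet:
    """HMM posterior decoding of the alpha track into PMD intervals.

    The mixture parameters seed the Gaussian emissions; a few Baum-Welch
    iterations re-estimate them under the chain, letting spatial persistence
    disambiguate the overlap region that an iid mixture fit mis-assigns.
    """
    config = config or track.config
    if not decision.present:
        return IntervalSet()
    means = decision.means.astype(float).copy()
    sds = np.maximum(decision.sds.astype(float), 1e-3)
    weights = decision.weights
    p_stay = config.persistence ** config.step_cpgs
    # a cleanly separated mixture is already a good emission model; only
    # refine when the components overlap enough for iid EM to mis-assign
    sep0 = (means[1] - means[0]) / np.sqrt((sds ** 2).mean())
    if sep0 >= 2.5:
        n_baum_welch = 0
    blocks = [(chrom, sub.pos.to_numpy(), sub.log_alpha.to_numpy())
              for (chrom, _b), sub in track.df.groupby(["chrom", "block"], sort=True)]

    for _ in range(max(0, n_baum_welch)):
        s0 = np.zeros(2)
        s1 = np.zeros(2)
        s2 = np.zeros(2)
        for _chrom, _anchors, x in blocks:
            post, _ = forward_backward(_gaussian_log_emissions(x, means, sds),
                                       p_stay, init=weights)
            s0 += post.sum(axis=0)
            s1 += post.T @ x
            s2 += post.T @ (x ** 2)
        if (s0 < 10).any():
            break  # a state starved; keep previous parameters
        new_means = s1 / s0
        new_sds = np.sqrt(np.maximum(s2 / s0 - new_means ** 2, 1e-6))
        if new_means[1] - new_means[0] < config.min_component_gap:
            break  # refitting collapsed the states; keep previous parameters
        if np.abs(new_means - means).max() < 1e-6 and np.abs(new_sds - sds).max() < 1e-6:
            means, sds = new_means, new_sds
            break
        means, sds = new_means, np.maximum(new_sds, 1e-3)

    rows = []
    for chrom, anchors, x in blocks:
        post, _ = forward_backward(_gaussian_log_emissions(x, means, sds),
                                   p_stay, init=weights)
        pmd = post[:, 1] > config.posterior_threshold  # state 1 = high alpha
        if not pmd.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], pmd.astype(int), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            rows.append((chrom, int(anchors[a]), int(anchors[b - 1]) + 1))
    if not rows:
        return IntervalSet()
    pmds = IntervalSet(rows, validate=False).merged()
    if config.refine_boundaries and methylome is not None:
        pmds = _refine_boundaries(pmds, methylome, config)
    pmds = pmds.subtract(layout.excluded).clip(layout.chrom_sizes)
    return _filter_pmds(pmds, config, methylome)


def _refine_boundaries(pmds: IntervalSet, methylome: SampleMethylome,
                       config: PmdCallConfig) -> IntervalSet:
    """Polish each PMD edge with a CpG-level binomial changepoint.

    Window-level alpha scores blur a boundary over the window span and bias
    it inward; re-locating each edge as the maximum-likelihood split of the
    local counts (flank-estimated means held fixed) removes that bias.
    """
    elig = _eligible(methylome, config)
    w = config.window_cpgs
    out_rows = []
    for chrom, sub in pmds.df.groupby("chrom", sort=True):
        c = elig[elig.chrom == chrom]
        pos = c.pos.to_numpy()
        if len(pos) < 3 * w:
            out_rows.extend((chrom, r.start, r.end) for r in sub.itertuples())
            continue
        cm = np.concatenate([[0], np.cumsum(c.m.to_numpy(dtype=float))])
        ct = np.concatenate([[0], np.cumsum(c.t.to_numpy(dtype=float))])

        def pooled(i, j) -> float:
            tt = ct[j] - ct[i]
            return float((cm[j] - cm[i]) / tt) if tt > 0 else float("nan")

        half = w // 2 + config.step_cpgs

        def refine(bp: int, inside_right: bool, lo_bp: int, hi_bp: int) -> int:
            k0 = int(np.searchsorted(pos, bp))
            lo = max(int(np.searchsorted(pos, lo_bp)), k0 - half)
            hi = min(int(np.searchsorted(pos, hi_bp)), k0 + half)
            if hi - lo < 4:
                return bp
            if inside_right:   # start boundary: background left, PMD right
                m_out = pooled(max(0, lo - w), lo)
                m_in = pooled(hi, min(len(pos), hi + w))
            else:              # end boundary: PMD left, background right
                m_in = pooled(max(0, lo - w), lo)
                m_out = pooled(hi, min(len(pos), hi + w))
            if not np.isfinite(m_in) or not np.isfinite(m_out) or abs(m_in - m_out) < 0.05:
                return bp
            m_left, m_right = (m_out, m_in) if inside_right else (m_in, m_out)
            eps = 1e-6
            la, lb = np.log(m_left + eps), np.log1p(-m_left + eps)
            ra, rb = np.log(m_right + eps), np.log1p(-m_right + eps)
            ks = np.arange(lo, hi + 1)
            ml, tl = cm[ks] - cm[lo], ct[ks] - ct[lo]
            mr, tr = cm[hi] - cm[ks], ct[hi] - ct[ks]
            ll = ml * la + (tl - ml) * lb + mr * ra + (tr - mr) * rb
            return int(pos[ks[int(np.argmax(ll))]])

        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        chrom_lo = int(pos[0])
        chrom_hi = int(pos[-1]) + 1
        for i in range(len(starts)):
            mid = (starts[i] + ends[i]) // 2
            prev_hi = ends[i - 1] if i > 0 else chrom_lo
            next_lo = starts[i + 1] if i + 1 < len(starts) else chrom_hi
            ns = refine(int(starts[i]), True, max(prev_hi, chrom_lo), mid)
            ne = refine(int(ends[i]), False, mid, min(next_lo, chrom_hi))
            if ne > ns:
                out_rows.append((chrom, ns, ne + 1))
    return IntervalSet(out_rows, validate=False).merged()


def _filter_pmds(pmds: IntervalSet, config: PmdCallConfig,
                 methylome: SampleMethylome | None) -> IntervalSet:
    df = pmds.df
    keep = (df.end - df.start) >= config.min_length
    scores = np.zeros(len(df))
    if methylome is not None and len(methylome):
        elig = _eligible(methylome, config)
        n_in = np.zeros(len(df), dtype=int)
        for chrom, sub in elig.groupby("chrom"):
            sel = df.chrom == chrom
            if not sel.any():
                continue
            pos = sub.pos.to_numpy()
            i0 = np.searchsorted(pos, df.start[sel].to_numpy(), side="left")
            i1 = np.searchsorted(pos, df.end[sel].to_numpy(), side="left")
            n_in[sel.to_numpy()] = i1 - i0
            cm = np.concatenate([[0], np.cumsum(sub.m.to_numpy())])
            ct = np.concatenate([[0], np.cumsum(sub.t.to_numpy())])
            with np.errstate(invalid="ignore", divide="ignore"):
                sc = (cm[i1] - cm[i0]) / (ct[i1] - ct[i0])
            scores[sel.to_numpy()] = np.nan_to_num(sc)
        keep &= n_in >= config.min_cpgs
    out = df[keep].copy()
    out["score"] = scores[keep.to_numpy()] if len(out) else []
    out["name"] = [f"pmd{i:05d}" for i in range(len(out))]
    return IntervalSet(out, validate=False)


def call_pmds(methylome: SampleMethylome, layout: GenomeLayout,
              config: PmdCallConfig | None = None,
              return_diagnostics: bool = False):
    """window_alpha -> pmds_present -> segment, honoring the CpG mode."""
    config = config or PmdCallConfig()
    track = window_alpha(methylome, layout, config)
    if len(track) < config.min_windows:
        decision = MixtureDecision(False, "too few windows")
    else:
        decision = pmds_present(track, config)
    pmds = segment(track, decision, layout, config, methylome)
    if return_diagnostics:
        return pmds, track, decision
    return pmds


# ------------------------------------------------------- aggregate caller

def aggregate_pmds_sd(samples: list[SampleMethylome], layout: GenomeLayout,
                      bin_bp: int = 100_000, min_cpgs: int = 10) -> IntervalSet:
    """Aggregate PMD track from the cross-sample s.d. of bin methylation.

    Per 100-kb bin the weighted methylation of each sample is computed
    (CGI/shore/promoter CpGs excluded); bins with fewer than ``min_cpgs``
    eligible covered CpGs in any sample are masked.  A two-component
    mixture on the s.d. classifies high-s.d. bins as PMD-like; adjacent
    PMD-like bins are merged.
    """
    if len(samples) < 3:
        raise ValueError("aggregate calling needs >= 3 samples")
    frames = []
    for s in samples:
        df = s.data
        excl = np.zeros(len(df), dtype=bool)
        for col in ("in_cgi", "in_shore", "in_promoter"):
            if col in df.columns:
                excl |= df[col].to_numpy()
        sub = df[~excl & (df.t > 0)]
        frames.append(sub)
    rows = []
    for chrom, size in layout.chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_bp))
        meth = np.full((len(samples), n_bins), np.nan)
        counts = np.zeros((len(samples), n_bins), dtype=int)
        for si, sub in enumerate(frames):
            c = sub[sub.chrom == chrom]
            if not len(c):
                continue
            b = (c.pos.to_numpy() // bin_bp).astype(int)
            sm = np.bincount(b, weights=c.m.to_numpy(), minlength=n_bins)
            st = np.bincount(b, weights=c.t.to_numpy(), minlength=n_bins)
            counts[si] = np.bincount(b, minlength=n_bins)
            with np.errstate(invalid="ignore", divide="ignore"):
                meth[si] = np.where(st > 0, sm / st, np.nan)
        ok = (counts >= min_cpgs).all(axis=0)
        sd = np.where(ok, np.nanstd(meth, axis=0, ddof=1), np.nan)
        starts = np.arange(n_bins) * bin_bp
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                  "end": np.minimum(starts + bin_bp, size),
                                  "sd": sd}))
    bins = pd.concat(rows, ignore_index=True)
    valid = bins.dropna(subset=["sd"])
    x = valid.sd.to_numpy()
    if len(x) < 4 or np.std(x) < 1e-9:
        return IntervalSet()
    X = x.reshape(-1, 1)
    g2 = GaussianMixture(2, random_state=0, n_init=5).fit(X)
    order = np.argsort(g2.means_.ravel())
    if g2.means_.ravel()[order][1] - g2.means_.ravel()[order][0] < 1e-4:
        return IntervalSet()
    post = g2.predict_proba(X)[:, order[1]]
    high = post > 0.5
    # boundary bins straddle PMD edges and dilute the cross-sample s.d.;
    # absorb neighbors of high bins whose s.d. still leans above the low
    # component until stable
    mu_lo = float(g2.means_.ravel()[order][0])
    sd_lo = float(np.sqrt(g2.covariances_.ravel()[order][0]))
    leaning = x > mu_lo + sd_lo
    chroms = valid.chrom.to_numpy()
    same_prev = np.zeros(len(valid), dtype=bool)
    same_prev[1:] = chroms[1:] == chroms[:-1]
    while True:
        adjacency = np.zeros(len(valid), dtype=bool)
        adjacency[:-1] = high[1:] & same_prev[1:]
        adjacency[1:] |= high[:-1] & same_prev[1:]
        new = high | (~high & leaning & adjacency)
        if (new == high).all():
            break
        high = new
    sel = valid[high]
    return IntervalSet([(r.chrom, r.start, r.end) for r in sel.itertuples()],
                       validate=False).merged()
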