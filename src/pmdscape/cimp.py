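"""CGI-level methylation, B-CIMP quantification and beta regression.

B-CIMP is the per-sample fraction of (non-missing) CGIs whose weighted
methylation exceeds 0.30 (strictly).  The association between B-CIMP and the
fraction of CGIs inside PMDs is modeled with a logit-link beta regression:
``y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)`` with
``mu_i = logistic(b0 + b1 * x_i)``, fitted by maximum likelihood in
``(b0, b1, log phi)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .intervals import IntervalSet
from .io import GenomeLayout, SampleMethylome

logger = logging.getLogger(__name__)


@dataclass
class CgiMatrix:
    """CGI x sample weighted methylation plus per-(CGI, sample) PMD status."""

    values: pd.DataFrame      # index = CGI id, columns = sample ids; NaN = missing
    in_pmd: pd.DataFrame      # same shape, boolean
    cgi_coords: pd.DataFrame  # cgi_id, chrom, start, end


@dataclass
class CimpFit:
    intercept: float
    slope: float
    phi: float
    slope_se: float
    wald_z: float
    wald_p: float
    pseudo_r2: float
    loglik: float
    n: int
    threshold: float = 0.30
    converged: bool = True


# --------------------------------------------------- element stratification

def element_methylation_distribution(samples: list[SampleMethylome],
                                     layout: GenomeLayout,
                                     pmds_per_sample: dict[str, IntervalSet],
                                     min_coverage: int = 5,
                                     quantiles=(0.25, 0.5, 0.75)) -> pd.DataFrame:
    """Quantiles of per-CpG methylation per element class x PMD status.

    Element precedence for CpGs in several classes: CGI > shore > promoter >
    other.  Classes with no CpGs are reported with count 0 and NaN quantiles.
    """
    recs = {}
    for cls in ("cgi", "shore", "promoter", "other"):
        for status in ("in_pmd", "out_pmd"):
            recs[(cls, status)] = []
    for s in samples:
        df = s.data
        covered = df.t >= min_coverage
        sub = df[covered]
        frac = sub.m.to_numpy() / sub.t.to_numpy()
        pmds = pmds_per_sample[s.sample_id]
        in_pmd = pmds.contains_points(sub.chrom.to_numpy(), sub.pos.to_numpy())
        cls = np.select(
            [sub.in_cgi.to_numpy(), sub.in_shore.to_numpy(), sub.in_promoter.to_numpy()],
            ["cgi", "shore", "promoter"], default="other")
        for c in ("cgi", "shore", "promoter", "other"):
            m = cls == c
            recs[(c, "in_pmd")].append(frac[m & in_pmd])
            recs[(c, "out_pmd")].append(frac[m & ~in_pmd])
    rows = []
    for (cls, status), parts in recs.items():
        v = np.concatenate(parts) if parts else np.array([])
        row = {"element": cls, "pmd_status": status, "n_cpgs": len(v)}
        for q in quantiles:
            row[f"q{int(q * 100)}"] = float(np.quantile(v, q)) if len(v) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------- CGI matrix

def cgi_matrix(samples: list[SampleMethylome], layout: GenomeLayout,
               pmds_per_sample: dict[str, IntervalSet],
               overlap_rule: str = "half", min_cpgs: int = 3) -> CgiMatrix:
    """Weighted methylation per CGI per sample (all CGI CpGs, no exclusion).

    A CGI with fewer than ``min_cpgs`` covered CpGs in a sample is missing.
    ``overlap_rule``: 'half' (>= 50% of CGI length inside a PMD) or
    'midpoint' (CGI midpoint inside a PMD).
    """
    cgi_df = layout.cgis.df
    if not len(cgi_df):
        raise ValueError("layout has no CGIs")
    ids = list(cgi_df.name)
    values = {}
    in_pmd = {}
    for s in samples:
        df = s.data[s.data.t > 0]
        vals = np.full(len(cgi_df), np.nan)
        for chrom, sub in df.groupby("chrom"):
            rows = cgi_df.chrom == chrom
            if not rows.any():
                continue
            pos = sub.pos.to_numpy()
            i0 = np.searchsorted(pos, cgi_df.start[rows].to_numpy())
            i1 = np.searchsorted(pos, cgi_df.end[rows].to_numpy())
            cm = np.concatenate([[0], np.cumsum(sub.m.to_numpy())])
            ct = np.concatenate([[0], np.cumsum(sub.t.to_numpy())])
            n = i1 - i0
            with np.errstate(invalid="ignore", divide="ignore"):
                v = (cm[i1] - cm[i0]) / (ct[i1] - ct[i0])
            v = np.where(n >= min_cpgs, v, np.nan)
            vals[rows.to_numpy()] = v
        values[s.sample_id] = vals
        pmds = pmds_per_sample[s.sample_id]
        if overlap_rule == "half":
            ov = layout.cgis.overlap_lengths(pmds)
            flag = ov >= 0.5 * (cgi_df.end - cgi_df.start).to_numpy()
        elif overlap_rule == "midpoint":
            mids = ((cgi_df.start + cgi_df.end) // 2).to_numpy()
            flag = pmds.contains_points(cgi_df.chrom.to_numpy(), mids)
        else:
            raise ValueError("overlap_rule must be 'half' or 'midpoint'")
        in_pmd[s.sample_id] = flag
    coords = cgi_df[["name", "chrom", "start", "end"]].rename(columns={"name": "cgi_id"})
    return CgiMatrix(values=pd.DataFrame(values, index=ids),
                     in_pmd=pd.DataFrame(in_pmd, index=ids),
                     cgi_coords=coords.reset_index(drop=True))


def hypermethylated_fraction(values, threshold: float = 0.30) -> float:
    """Fraction of non-missing values strictly above the threshold."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("all values missing")
    return float((v > threshold).mean())


def cimp_inputs(matrix: CgiMatrix, threshold: float = 0.30) -> pd.DataFrame:
    """Per-sample (b_cimp, frac_cgi_in_pmd) over non-missing CGIs."""
    rows = []
    for sample in matrix.values.columns:
        v = matrix.values[sample]
        ok = v.notna()
        if not ok.any():
            raise ValueError(f"sample {sample}: all CGIs missing")
        b_cimp = float((v[ok] > threshold).mean())
        frac_in = float(matrix.in_pmd.loc[ok.to_numpy(), sample].mean())
        rows.append({"sample_id": sample, "b_cimp": b_cimp,
                     "frac_cgi_in_pmd": frac_in, "n_cgis": int(ok.sum())})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- beta regression

def _beta_reg_negloglik(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    b0, b1, logphi = params
    phi = np.exp(logphi)
    eta = b0 + b1 * x
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
          + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    return -float(ll.sum())


def compress_boundary(y: np.ndarray) -> np.ndarray:
    """Smithson-Verkuilen transform applied only to exact 0/1 values."""
    y = np.asarray(y, dtype=float).copy()
    n = len(y)
    at_edge = (y <= 0.0) | (y >= 1.0)
    y[at_edge] = (y[at_edge] * (n - 1) + 0.5) / n
    return y


def fit_beta_regression(y, x, threshold: float = 0.30) -> CimpFit:
    """ML beta regression of proportions ``y`` on covariate ``x``.

    Pseudo-R^2 is the squared Pearson correlation between the linear
    predictor and logit(y); the slope p-value is a Wald z-test using the
    observed-information standard error.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x):
        raise ValueError("x and y lengths differ")
    if len(y) < 5:
        raise ValueError("need n >= 5 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate x")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("responses must lie in [0, 1]")
    y = compress_boundary(y)

    ly = special.logit(y)
    X = np.column_stack([np.ones_like(x), x])
    b_init, *_ = np.linalg.lstsq(X, ly, rcond=None)
    mu0 = special.expit(X @ b_init)
    # method-of-moments start for phi: var(y|mu) = mu(1-mu)/(1+phi)
    s2 = max(float(np.var(y - mu0)), 1e-6)
    phi0 = float(np.clip(np.mean(mu0 * (1.0 - mu0)) / s2 - 1.0, 1.0, 1e4))
    start = np.array([b_init[0], b_init[1], np.log(phi0)])

    res = optimize.minimize(_beta_reg_negloglik, start, args=(x, y), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000})
    res2 = optimize.minimize(_beta_reg_negloglik, res.x, args=(x, y), method="BFGS",
                             options={"gtol": 1e-8, "maxiter": 500})
    best = res2 if res2.fun <= res.fun else res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"beta regression failed to converge: {best}")
    b0, b1, logphi = best.x

    hess = _numerical_hessian(lambda p: _beta_reg_negloglik(p, x, y), best.x)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        raise RuntimeError("singular Hessian in beta regression") from None
    if not np.isfinite(se) or se == 0:
        raise RuntimeError("could not compute slope standard error")
    z = b1 / se
    p = 2.0 * stats.norm.sf(abs(z))
    eta = b0 + b1 * x
    r2 = float(np.corrcoef(eta, special.logit(y))[0, 1] ** 2)
    return CimpFit(intercept=float(b0), slope=float(b1), phi=float(np.exp(logphi)),
                   slope_se=se, wald_z=float(z), wald_p=float(p), pseudo_r2=r2,
                   loglik=-float(best.fun), n=len(y), threshold=threshold)


def _numerical_hessian(f, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x0)
    h = eps * np.maximum(1.0, np.abs(x0))
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            pp = x0.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = x0.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = x0.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = x0.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            hess[i, j] = hess[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * h[i] * h[j])
    return hess


# ----------------------------------------------------- variation by frequency

def cgi_variation_by_frequency(matrix: CgiMatrix, min_cgis: int = 3) -> pd.DataFrame:
    """Cross-sample s.d. of CGI methylation grouped by the CGI's PMD
    frequency (number of samples in which the CGI is inside a PMD)."""
    sd = matrix.values.std(axis=1, ddof=1)
    freq = matrix.in_pmd.sum(axis=1)
    n_samples = matrix.in_pmd.shape[1]
    rows = []
    for f in range(n_samples + 1):
        sel = sd[freq == f].dropna()
        rows.append({"freq": f, "n_cgis": len(sel),
                     "median_sd": float(sel.median()) if len(sel) >= min_cgis else np.nan,
                     "mean_sd": float(sel.mean()) if len(sel) >= min_cgis else np.nan})
    return pd.DataFrame(rows)
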