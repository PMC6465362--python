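"""Gene-level PMD frequency and gene-set exclusion testing."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet
from .io import GenomeLayout


@dataclass
class ExclusionTestResult:
    p_value: float
    n_universe: int      # N: all genes
    n_set: int           # K: genes in the tested set
    n_outside: int       # n: genes with PMD frequency 0
    n_set_outside: int   # k: tested-set genes with frequency 0


def gene_pmd_frequency(layout: GenomeLayout,
                       cohort_pmds: dict[str, IntervalSet],
                       overlap_rule: str = "half") -> pd.DataFrame:
    """Number of samples in which each gene counts as 'inside a PMD'.

    ``overlap_rule``: 'half' (>= 50% of the gene body inside a PMD) or
    'tss' (the gene start lies inside a PMD).
    """
    gdf = layout.genes.df
    unknown = set(gdf.chrom) - set(layout.chrom_sizes)
    if unknown:
        raise ValueError(f"genes on unknown chromosomes: {sorted(unknown)}")
    freq = np.zeros(len(gdf), dtype=int)
    for pmds in cohort_pmds.values():
        if overlap_rule == "half":
            ov = layout.genes.overlap_lengths(pmds)
            freq += (ov >= 0.5 * (gdf.end - gdf.start).to_numpy()).astype(int)
        elif overlap_rule == "tss":
            freq += pmds.contains_points(gdf.chrom.to_numpy(),
                                         gdf.start.to_numpy()).astype(int)
        else:
            raise ValueError("overlap_rule must be 'half' or 'tss'")
    out = gdf[["name", "chrom", "start", "end"]].rename(columns={"name": "gene_id"}).copy()
    out["freq"] = freq
    for set_name, members in layout.gene_sets.items():
        out[f"set_{set_name}"] = out.gene_id.isin(members)
    return out.reset_index(drop=True)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact log-factorials."""
    k_max = min(K, n)
    k_min = max(0, n - (N - K))
    if k <= k_min:
        return 1.0
    denom = _log_comb(N, n)
    total = 0.0
    for i in range(max(k, k_min), k_max + 1):
        total += math.exp(_log_comb(K, i) + _log_comb(N - K, n - i) - denom)
    return min(total, 1.0)


def exclusion_test(table: pd.DataFrame, set_name: str) -> ExclusionTestResult:
    """Hypergeometric test for over-representation of a gene set among genes
    outside PMDs (PMD frequency 0)."""
    col = f"set_{set_name}" if f"set_{set_name}" in table.columns else set_name
    if col not in table.columns:
        raise KeyError(f"gene set {set_name!r} not in table")
    members = table[col].astype(bool)
    N = len(table)
    K = int(members.sum())
    if K == 0:
        raise ValueError(f"gene set {set_name!r} is empty")
    outside = table.freq == 0
    n = int(outside.sum())
    k = int((members & outside).sum())
    return ExclusionTestResult(hypergeom_upper_tail(N, K, n, k), N, K, n, k)


def frequency_distribution_by_set(table: pd.DataFrame) -> pd.DataFrame:
    """Absolute and relative PMD-frequency histograms per gene set (plus the
    complement of all annotated sets as 'non_set')."""
    n_max = int(table.freq.max()) if len(table) else 0
    set_cols = [c for c in table.columns if c.startswith("set_")]
    groups = {c.removeprefix("set_"): table[c].astype(bool) for c in set_cols}
    any_set = np.zeros(len(table), dtype=bool)
    for m in groups.values():
        any_set |= m.to_numpy()
    groups["non_set"] = pd.Series(~any_set, index=table.index)
    rows = []
    for name, mask in groups.items():
        sub = table[mask]
        counts = sub.freq.value_counts().reindex(range(n_max + 1), fill_value=0)
        total = counts.sum()
        for f in range(n_max + 1):
            rows.append({"set": name, "freq": f, "count": int(counts[f]),
                         "relative": counts[f] / total if total else np.nan})
    return pd.DataFrame(rows)
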