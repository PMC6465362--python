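"""Cohort-level PMD statistics: coverage fractions, frequency tracks,
shuffle nulls, overlap metrics, boundary metaprofiles, and feature-density
summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet, overlap_stats
from .io import GenomeLayout

logger = logging.getLogger(__name__)

interval_set_overlap = overlap_stats  # bp-level jaccard + containment fractions


@dataclass
class FrequencyTrack:
    """Per-tile PMD frequency (number of samples hitting the tile).

    ``df`` columns: chrom, start, end, eff_bp (non-excluded bp in the tile),
    freq.  Tiles are a fixed grid over each chromosome; the last tile is
    truncated when the tile size does not divide the chromosome length.
    """

    tile_bp: int
    mode: str               # 'coverage' | 'border'
    n_samples: int
    df: pd.DataFrame


@dataclass
class ShuffleNull:
    n_shuffles: int
    seed: int
    tile_bp: int
    observed_hist: pd.Series       # frequency -> tile count
    null_hist: pd.Series           # frequency -> mean tile count per shuffle
    null_tile_mean: float
    null_tile_sd: float
    observed_mode: int
    null_mode: int
    frac_zero_tiles: float


def genome_fraction(pmds: IntervalSet, layout: GenomeLayout) -> float:
    """Fraction of the non-excluded genome covered by the PMD set."""
    covered = pmds.subtract(layout.excluded).clip(layout.chrom_sizes).total_length()
    return covered / layout.non_excluded_length()


def _tile_grid(layout: GenomeLayout, tile_bp: int) -> pd.DataFrame:
    rows = []
    for chrom, size in layout.chrom_sizes.items():
        starts = np.arange(0, size, tile_bp)
        ends = np.minimum(starts + tile_bp, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    grid = pd.concat(rows, ignore_index=True)
    tiles = IntervalSet(grid, validate=False)
    excl_overlap = tiles.overlap_lengths(layout.excluded)
    out = tiles.df[["chrom", "start", "end"]].copy()
    out["eff_bp"] = (out.end - out.start).to_numpy() - excl_overlap
    return out


def frequency_track(cohort_pmds: list[IntervalSet] | dict[str, IntervalSet],
                    layout: GenomeLayout, tile_bp: int = 30_000,
                    mode: str = "coverage", min_overlap_bp: int = 1,
                    min_overlap_frac: float | None = None) -> FrequencyTrack:
    """Per-tile count of samples overlapping (coverage mode) or having a PMD
    endpoint inside (border mode) the tile."""
    if isinstance(cohort_pmds, dict):
        cohort_pmds = list(cohort_pmds.values())
    if len(cohort_pmds) < 1:
        raise ValueError("need at least one sample")
    if mode not in ("coverage", "border"):
        raise ValueError("mode must be 'coverage' or 'border'")
    grid = _tile_grid(layout, tile_bp)
    freq = np.zeros(len(grid), dtype=int)
    key = {(c, s): i for i, (c, s) in enumerate(zip(grid.chrom, grid.start))}
    for pmds in cohort_pmds:
        hit = np.zeros(len(grid), dtype=bool)
        for chrom in pmds.chroms:
            if chrom not in layout.chrom_sizes:
                continue
            size = layout.chrom_sizes[chrom]
            s, e = pmds._merged()[chrom]
            if mode == "coverage":
                for a, b in zip(s, e):
                    t0, t1 = a // tile_bp, (b - 1) // tile_bp
                    for t in range(t0, t1 + 1):
                        tile_start = t * tile_bp
                        if tile_start >= size:
                            break
                        ov = min(b, min(tile_start + tile_bp, size)) - max(a, tile_start)
                        need = (min_overlap_frac * (min(tile_start + tile_bp, size) - tile_start)
                                if min_overlap_frac is not None else min_overlap_bp)
                        if ov >= need:
                            hit[key[(chrom, tile_start)]] = True
            else:
                for b in np.concatenate([s, e]):
                    b = min(int(b), size - 1)
                    tile_start = (b // tile_bp) * tile_bp
                    hit[key[(chrom, tile_start)]] = True
        freq += hit
    out = grid.copy()
    out["freq"] = freq
    return FrequencyTrack(tile_bp, mode, len(cohort_pmds), out)


def frequency_fraction_curve(track: FrequencyTrack) -> pd.Series:
    """Genome fraction (of non-excluded bp) in tiles with frequency >= f."""
    if track.mode != "coverage":
        raise ValueError("frequency_fraction_curve requires a coverage-mode track")
    df = track.df
    total = df.eff_bp.sum()
    out = {}
    for f in range(0, track.n_samples + 1):
        out[f] = float(df.loc[df.freq >= f, "eff_bp"].sum() / total)
    return pd.Series(out, name="genome_fraction")


def shuffle_pmds(pmds: IntervalSet, layout: GenomeLayout, seed: int,
                 max_attempts: int = 2000, max_restarts: int = 50) -> IntervalSet:
    """Re-place each chromosome's intervals uniformly at random, without
    overlap and avoiding excluded regions; lengths are preserved exactly."""
    rng = np.random.default_rng(seed)
    rows = []
    exc = layout.excluded
    for chrom in pmds.chroms:
        size = layout.chrom_sizes[chrom]
        s, e = pmds.chrom_arrays(chrom)
        lengths = (e - s).astype(int)
        total = lengths.sum()
        avail = layout.non_excluded_length(chrom)
        if total >= avail:
            raise ValueError(f"{chrom}: PMD bp ({total}) exceeds available bp ({avail})")
        exc_s, exc_e = exc._merged().get(chrom, (np.array([]), np.array([])))
        for _restart in range(max_restarts):
            order = rng.permutation(len(lengths))
            placed_s: list[int] = []
            placed_e: list[int] = []
            failed = False
            for ln in lengths[order]:
                ln = int(ln)
                done = False
                for _ in range(max_attempts):
                    a = int(rng.integers(0, size - ln + 1))
                    b = a + ln
                    if _overlaps_any(a, b, exc_s, exc_e):
                        continue
                    if any(b > ps and a < pe for ps, pe in zip(placed_s, placed_e)):
                        continue
                    placed_s.append(a)
                    placed_e.append(b)
                    done = True
                    break
                if not done:
                    failed = True
                    break
            if not failed:
                rows.extend((chrom, a, b) for a, b in zip(placed_s, placed_e))
                break
        else:
            occ = total / size
            raise ValueError(f"{chrom}: shuffle placement infeasible "
                             f"(occupancy {occ:.2f}) after {max_restarts} restarts")
    return IntervalSet(rows, validate=False)


def _overlaps_any(a: int, b: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    if len(starts) == 0:
        return False
    i = np.searchsorted(ends, a, side="right")
    return i < len(starts) and starts[i] < b


def border_null_distribution(cohort_pmds: list[IntervalSet] | dict[str, IntervalSet],
                             layout: GenomeLayout, tile_bp: int = 30_000,
                             n_shuffles: int = 20, seed: int = 0,
                             mode: str = "border") -> ShuffleNull:
    """Observed per-tile frequency histogram vs a shuffle null."""
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    if isinstance(cohort_pmds, dict):
        cohort_pmds = list(cohort_pmds.values())
    n = len(cohort_pmds)
    observed = frequency_track(cohort_pmds, layout, tile_bp, mode=mode)
    obs_counts = observed.df.freq.value_counts().reindex(range(n + 1), fill_value=0)
    null_counts = np.zeros(n + 1, dtype=float)
    null_freqs = []
    for k in range(n_shuffles):
        shuffled = [shuffle_pmds(p, layout, seed=seed * 100_003 + 17 * k + j)
                    for j, p in enumerate(cohort_pmds)]
        tr = frequency_track(shuffled, layout, tile_bp, mode=mode)
        null_counts += tr.df.freq.value_counts().reindex(range(n + 1), fill_value=0).to_numpy()
        null_freqs.append(tr.df.freq.to_numpy())
    null_counts /= n_shuffles
    all_null = np.concatenate(null_freqs)
    obs = observed.df.freq.to_numpy()
    return ShuffleNull(
        n_shuffles=n_shuffles, seed=seed, tile_bp=tile_bp,
        observed_hist=obs_counts, null_hist=pd.Series(null_counts, index=range(n + 1)),
        null_tile_mean=float(all_null.mean()), null_tile_sd=float(all_null.std(ddof=1)),
        observed_mode=int(obs_counts.idxmax()),
        null_mode=int(np.argmax(null_counts)),
        frac_zero_tiles=float((obs == 0).mean()),
    )


def boundary_profile(signal: dict[str, np.ndarray], signal_bin_bp: int,
                     pmds: IntervalSet, flank_bp: int, n_bins: int,
                     ) -> tuple[np.ndarray, int, int]:
    """Average a binned signal over aligned PMD boundaries.

    ``signal`` maps chromosome -> per-bin values (bin size ``signal_bin_bp``).
    Boundaries are oriented outside -> inside left-to-right (end boundaries
    mirrored).  PMDs shorter than ``flank_bp`` are excluded.

    Returns (profile of length n_bins, n boundaries used, n PMDs excluded).
    """
    step = 2 * flank_bp / n_bins
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    used = 0
    excluded = 0
    for r in pmds.df.itertuples(index=False):
        if r.end - r.start < flank_bp:
            excluded += 1
            continue
        vals = signal.get(r.chrom)
        if vals is None:
            continue
        for boundary, orient in ((r.start, 1), (r.end, -1)):
            centers = boundary + orient * (np.arange(n_bins) + 0.5) * step - orient * flank_bp
            idx = (centers // signal_bin_bp).astype(int)
            ok = (idx >= 0) & (idx < len(vals))
            v = np.full(n_bins, np.nan)
            v[ok] = vals[idx[ok]]
            good = ~np.isnan(v)
            acc[good] += v[good]
            cnt[good] += 1
            used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(cnt > 0, acc / cnt, np.nan)
    return profile, used, excluded


def density_by_frequency(features: IntervalSet, track: FrequencyTrack) -> pd.DataFrame:
    """Feature density (count per Mb) per PMD-frequency class.

    Features are assigned to tiles by their midpoint.  Frequency classes
    with no genomic territory are reported as missing, not zero.
    """
    df = track.df
    n = track.n_samples
    mb = df.groupby("freq").eff_bp.sum().reindex(range(n + 1), fill_value=0) / 1e6
    counts = pd.Series(0, index=range(n + 1), dtype=int)
    tile_lookup = {}
    for chrom, sub in df.groupby("chrom"):
        tile_lookup[chrom] = sub.freq.to_numpy()
    for r in features.df.itertuples(index=False):
        freqs = tile_lookup.get(r.chrom)
        if freqs is None:
            continue
        mid = (r.start + r.end) // 2
        t = mid // track.tile_bp
        if t < len(freqs):
            counts[freqs[t]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(mb > 0, counts / mb, np.nan)
    return pd.DataFrame({"freq": range(n + 1), "count": counts.to_numpy(),
                         "mb": mb.to_numpy(), "density_per_mb": density})
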