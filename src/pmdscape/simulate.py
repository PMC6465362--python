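"""Seeded synthetic WGBS-like cohorts with planted PMDs and ground truth.

Generative architecture
-----------------------
A shared layout of *PMD-permissive domains* is placed per chromosome, each
with an activation propensity.  Every sample activates each domain
independently (Bernoulli of propensity x a per-sample activity factor), so
domain boundaries are shared across samples while occupancy is
hypervariable.  Activated domain edges are jittered; a configurable fraction
of the genome lies in no permissive domain and therefore never hosts a PMD.

Per-CpG truth: background CpGs draw their methylation from a polarized Beta
(high mean, low concentration); CpGs inside a sample's planted PMDs draw
from an intermediate-mean Beta with that sample's PMD depth.  CGIs are
hypomethylated outside PMDs (with a minority constitutively methylated) and,
inside PMDs, gain intermediate methylation with a configurable probability.
Solo-WCGW CpGs get a negative methylation offset inside PMDs.  Counts are
beta-binomial: coverage is negative-binomial, methylated reads binomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .intervals import IntervalSet
from .io import (GenomeLayout, SampleMethylome, annotate_cpgs,
                 default_promoters, default_shores)

DEFAULT_CHROM_SIZES = {"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000}


@dataclass
class SimConfig:
    """All knobs of the generator.  Probabilities live in [0, 1], lengths in bp."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    n_samples: int = 30
    seed: int = 0

    # CpG landscape
    cpg_spacing: float = 150.0            # mean inter-CpG distance (bp)
    cgi_density_multiplier: float = 5.0   # CpG density boost inside CGIs

    # PMD-permissive domain architecture
    domain_size_mean: float = 400_000.0   # lognormal scale (median) of domain sizes
    domain_size_sigma: float = 0.45
    never_pmd_fraction: float = 0.25      # genome fraction in no permissive domain
    propensity_floor: float = 0.15
    propensity_ceiling: float = 0.98
    propensity_shape: tuple[float, float] = (0.6, 1.6)  # Beta shape of propensities
    activity_range: tuple[float, float] = (0.35, 1.9)   # per-sample activation multiplier
    boundary_jitter: float = 50_000.0     # Uniform(0, jitter) edge extension/truncation

    # methylation levels (Beta means and concentrations nu; Beta(mean*nu, (1-mean)*nu)).
    # The non-PMD background concentration is deliberately < 1/background_mean
    # so background windows are polarized (fitted alpha < 1), matching the
    # near-binary methylation landscape outside PMDs.
    pmd_mean_range: tuple[float, float] = (0.40, 0.75)
    pmd_concentration: float = 6.0
    background_mean: float = 0.85
    background_concentration: float = 0.8
    # Background/shore CpGs have a fixed latent level per CpG (drawn once per
    # layout from the U-shaped background Beta) and are redrawn per sample
    # tightly around it: outside PMDs the methylation state of a CpG is a
    # stable property, and cross-sample variation concentrates inside PMDs.
    replicate_concentration: float = 60.0

    # CGIs
    cgi_per_mb: float = 8.0
    cgi_size_mean: float = 1_000.0
    cgi_size_sigma: float = 0.3
    cgi_gain_prob: float = 0.92           # P(hypo CGI gains methylation | inside PMD)
    cgi_constitutive_prob: float = 0.27   # P(CGI constitutively methylated outside PMDs)
    cgi_hypo_mean: float = 0.03
    cgi_gain_min_mean: float = 0.45       # gained CGI level = max(PMD depth, this)
    cgi_concentration: float = 60.0       # concentration of per-CGI level draws
    cgi_cpg_concentration: float = 50.0   # per-CpG spread around the CGI level
    cgi_in_pmd_min_overlap: float = 0.5   # CGI counts as inside a PMD at >=50% length

    # shores / promoters (non-CGI promoter CpGs)
    shore_mean: float = 0.45
    shore_concentration: float = 4.0
    promoter_hypo_mean: float = 0.05

    # solo-WCGW
    wcgw_prob: float = 0.35               # P(CpG has W-C-G-W context)
    solo_distance: float = 35.0           # "solo" iff nearest CpG neighbor > 35 bp
    solo_offset: float = -0.08            # methylation offset inside PMDs

    # coverage: negative binomial with mean and shape r (var = mean + mean^2/r)
    coverage_mean: float = 10.0
    coverage_shape: float = 5.0

    # genes
    genes_per_mb: float = 8.0
    gene_size_mean: float = 30_000.0
    gene_size_sigma: float = 0.6
    tsg_fraction: float = 0.10            # fraction of genes labeled TSG
    tsg_outside_prob: float = 0.90        # P(TSG planted outside permissive domains)

    # misc
    excluded_fraction: float = 0.02       # centromere-like block per chromosome
    n_tissues: int = 1
    tissue_specific_fraction: float = 0.5  # fraction of domains tissue-private (n_tissues=2)
    covariate_effect: float = 0.04        # background shift in covariate-responsive regions

    def validate(self) -> None:
        probs = [self.cgi_gain_prob, self.cgi_constitutive_prob, self.wcgw_prob,
                 self.tsg_fraction, self.tsg_outside_prob, self.never_pmd_fraction,
                 self.propensity_floor, self.propensity_ceiling,
                 self.tissue_specific_fraction, self.excluded_fraction]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        lengths = [*self.chrom_sizes.values(), self.cpg_spacing, self.domain_size_mean,
                   self.cgi_size_mean, self.gene_size_mean, self.coverage_mean]
        if any(l <= 0 for l in lengths):
            raise ValueError("lengths and means must be > 0")
        means = [self.background_mean, self.cgi_hypo_mean, self.shore_mean,
                 self.promoter_hypo_mean, *self.pmd_mean_range]
        if any(not 0.0 < m < 1.0 for m in means):
            raise ValueError("methylation means must lie in (0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_tissues not in (1, 2):
            raise ValueError("n_tissues must be 1 or 2")

    @property
    def zero_contrast(self) -> bool:
        """True when PMDs are configured to be indistinguishable from background."""
        lo, hi = self.pmd_mean_range
        return (abs(lo - self.background_mean) < 1e-9
                and abs(hi - self.background_mean) < 1e-6
                and self.pmd_concentration == self.background_concentration)


@dataclass
class GroundTruth:
    """Everything the generator knows and the analysis should recover."""

    domains: IntervalSet                      # permissive domains (name=id, score=propensity)
    propensities: np.ndarray
    domain_tissue: np.ndarray                 # 0 = shared, 1/2 = tissue-private
    cgi_base_state: pd.Series                 # per CGI id: 'hypo' | 'constitutive'
    gene_table: pd.DataFrame                  # gene_id, chrom, start, end, is_tsg, planted_outside
    pmds_by_sample: dict[str, IntervalSet] = field(default_factory=dict)
    pmd_mean_by_sample: dict[str, float] = field(default_factory=dict)
    sample_tissue: dict[str, int] = field(default_factory=dict)
    cgi_state_by_sample: dict[str, pd.Series] = field(default_factory=dict)  # 'hypo'|'gained'|'constitutive'

    def planted_frequency(self, tile_bp: int, chrom_sizes: Mapping[str, int]) -> pd.DataFrame:
        """Per-tile count of samples whose planted PMDs overlap the tile."""
        rows = []
        for chrom, size in chrom_sizes.items():
            n_tiles = math.ceil(size / tile_bp)
            counts = np.zeros(n_tiles, dtype=int)
            for pmds in self.pmds_by_sample.values():
                hit = np.zeros(n_tiles, dtype=bool)
                s, e = pmds.chrom_arrays(chrom)
                for a, b in zip(s, e):
                    hit[a // tile_bp: (b - 1) // tile_bp + 1] = True
                counts += hit
            starts = np.arange(n_tiles) * tile_bp
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                      "end": np.minimum(starts + tile_bp, size),
                                      "freq": counts}))
        return pd.concat(rows, ignore_index=True)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


def _place_nonoverlapping(rng, region_start, region_end, lengths, obstacles, attempts=200):
    """Uniformly place given lengths in [region_start, region_end) without overlap."""
    placed = list(obstacles)
    out = []
    for ln in lengths:
        ok = False
        for _ in range(attempts):
            if region_end - region_start - ln <= 0:
                break
            s = int(rng.integers(region_start, region_end - ln))
            e = s + ln
            if all(e <= a or s >= b for a, b in placed):
                placed.append((s, e))
                out.append((s, e))
                ok = True
                break
        if not ok:
            out.append(None)
    return out


def generate_layout(config: SimConfig) -> tuple[GenomeLayout, GroundTruth]:
    """Build the shared genome layout and the ground-truth skeleton."""
    config.validate()
    rng = _rng(config.seed, 1)

    excluded_rows, domain_rows, cgi_rows, gene_rows = [], [], [], []
    cpg_frames = []
    f = config.never_pmd_fraction
    jitter_budget = 2.0 * config.boundary_jitter  # gap bp eaten by edge jitter (union over samples)

    for chrom, size in config.chrom_sizes.items():
        # centromere-like excluded block in the middle
        exc_len = int(size * config.excluded_fraction)
        exc_start = (size - exc_len) // 2
        arms = [(0, exc_start), (exc_start + exc_len, size)] if exc_len > 0 else [(0, size)]
        if exc_len > 0:
            excluded_rows.append((chrom, exc_start, exc_start + exc_len, "centromere"))

        # --- permissive domains: sequential placement with jitter-padded gaps.
        # The structural "extra" gap beyond the jitter budget is sized so the
        # genome fraction in no permissive domain comes out near the config
        # target once the excluded block and tile discretization are counted.
        mean_len = config.domain_size_mean * math.exp(config.domain_size_sigma ** 2 / 2)
        # small calibration compensates boundary-tile discretization losses
        f_eff = f - config.excluded_fraction + 0.005
        if f >= 1.0 or f_eff <= 0.005:
            mean_extra = None  # no structural gaps possible / no domains wanted
            if f >= 1.0:
                continue_placement = False
            else:
                continue_placement = True
                mean_extra = 0.01 * mean_len
        else:
            continue_placement = True
            mean_extra = f_eff * (mean_len + jitter_budget) / (1.0 - f_eff)
        if continue_placement:
            # Gamma(4) gap draws: same mean as an exponential but half the
            # spread, keeping the realized never-PMD fraction near target
            for arm_start, arm_end in arms:
                cursor = arm_start + int(rng.gamma(2.0, mean_extra / 4)
                                         + jitter_budget / 2)
                while True:
                    length = int(rng.lognormal(math.log(config.domain_size_mean),
                                               config.domain_size_sigma))
                    length = max(length, 50_000)
                    tail = arm_end - cursor - int(jitter_budget / 2)
                    if length > tail:
                        # shrink the final domain into the remaining arm space
                        # instead of wasting the tail as never-PMD territory
                        if tail >= max(100_000, int(jitter_budget)):
                            domain_rows.append((chrom, cursor, cursor + tail))
                        break
                    domain_rows.append((chrom, cursor, cursor + length))
                    cursor += length + int(jitter_budget + rng.gamma(4.0, mean_extra / 4))

    n_domains = len(domain_rows)
    if n_domains == 0 and f < 1.0 and config.propensity_ceiling > 0:
        sizes = {c: s for c, s in config.chrom_sizes.items()}
        raise ValueError(f"could not place any permissive domain; chromosome sizes {sizes} "
                         f"are too small for domain_size_mean={config.domain_size_mean:g}")

    lo, hi = config.propensity_floor, config.propensity_ceiling
    if hi <= 0:
        domain_rows = []
        n_domains = 0
        propensities = np.zeros(0)
    else:
        a, b = config.propensity_shape
        propensities = lo + (hi - lo) * rng.beta(a, b, size=n_domains)

    domain_tissue = np.zeros(n_domains, dtype=int)
    if config.n_tissues == 2 and n_domains:
        u = rng.random(n_domains)
        priv = u < config.tissue_specific_fraction
        half = rng.random(n_domains) < 0.5
        domain_tissue[priv & half] = 1
        domain_tissue[priv & ~half] = 2

    domains = IntervalSet([(c, s, e, f"domain{k:05d}", float(propensities[k]))
                           for k, (c, s, e) in enumerate(domain_rows)], validate=False)
    excluded = IntervalSet([(c, s, e, n) for c, s, e, n in excluded_rows])

    # --- CGIs: uniform placement avoiding excluded regions and each other
    for chrom, size in config.chrom_sizes.items():
        n_cgis = int(round(config.cgi_per_mb * size / 1e6))
        lens = np.maximum(200, rng.lognormal(math.log(config.cgi_size_mean),
                                             config.cgi_size_sigma, n_cgis).astype(int))
        obstacles = [(s, e) for c, s, e, _n in excluded_rows if c == chrom]
        for placed in _place_nonoverlapping(rng, 0, size, lens, obstacles):
            if placed is not None:
                cgi_rows.append((chrom, placed[0], placed[1]))
    cgi_rows.sort()
    cgis = IntervalSet([(c, s, e, f"cgi{k:05d}") for k, (c, s, e) in enumerate(cgi_rows)],
                       validate=False)

    # --- genes; TSGs preferentially planted outside permissive domains.
    # Gap cores are eroded by the boundary jitter so jittered PMD edges
    # cannot reach genes planted "outside".
    gap_regions = {}
    erode = int(config.boundary_jitter)
    for chrom, size in config.chrom_sizes.items():
        whole = IntervalSet([(chrom, 0, size)])
        gaps = whole.subtract(domains).subtract(excluded)
        s, e = gaps.chrom_arrays(chrom)
        s, e = s + erode, e - erode
        keep = s < e
        gap_regions[chrom] = (s[keep], e[keep])
    gk = 0
    for chrom, size in config.chrom_sizes.items():
        n_genes = int(round(config.genes_per_mb * size / 1e6))
        lens = np.maximum(2_000, rng.lognormal(math.log(config.gene_size_mean),
                                               config.gene_size_sigma, n_genes).astype(int))
        is_tsg = rng.random(n_genes) < config.tsg_fraction
        gs, ge = gap_regions[chrom]
        gap_lens = ge - gs
        for ln, tsg in zip(lens, is_tsg):
            outside = False
            placed = None
            if tsg and rng.random() < config.tsg_outside_prob:
                fit = np.where(gap_lens >= ln + 2)[0]
                if len(fit):
                    gi = int(rng.choice(fit))
                    start = int(rng.integers(gs[gi], ge[gi] - ln))
                    placed = (start, start + ln)
                    outside = True
            if placed is None:
                start = int(rng.integers(0, size - ln)) if size > ln else 0
                placed = (start, min(start + ln, size))
            gene_rows.append((chrom, placed[0], placed[1], f"gene{gk:05d}", bool(tsg), outside))
            gk += 1

    gene_table = pd.DataFrame(gene_rows,
                              columns=["chrom", "start", "end", "gene_id", "is_tsg",
                                       "planted_outside"])
    genes = IntervalSet([(r.chrom, r.start, r.end, r.gene_id)
                         for r in gene_table.itertuples()], validate=False)

    # --- CpG positions: piecewise-exponential spacings, denser inside CGIs
    for chrom, size in config.chrom_sizes.items():
        boundaries = [0]
        cgi_s, cgi_e = cgis.chrom_arrays(chrom)
        for a, b in zip(cgi_s, cgi_e):
            boundaries.extend([a, b])
        boundaries.append(size)
        pos_parts = []
        for i in range(len(boundaries) - 1):
            seg_start, seg_end = boundaries[i], boundaries[i + 1]
            if seg_end <= seg_start:
                continue
            in_cgi = i % 2 == 1
            spacing = config.cpg_spacing / (config.cgi_density_multiplier if in_cgi else 1.0)
            n_expect = (seg_end - seg_start) / spacing
            n_draw = int(n_expect + 6 * math.sqrt(n_expect) + 10)
            gaps = rng.exponential(spacing, n_draw)
            p = seg_start + np.cumsum(np.maximum(2, gaps.astype(int)))
            pos_parts.append(p[p < seg_end])
        pos = np.unique(np.concatenate(pos_parts)) if pos_parts else np.array([], dtype=int)
        # drop CpGs in excluded regions
        keep = ~excluded.contains_points(chrom, pos)
        pos = pos[keep]
        # solo-WCGW labels
        wcgw = rng.random(len(pos)) < config.wcgw_prob
        if len(pos) > 1:
            gap_left = np.diff(pos, prepend=pos[0] - 10 * int(config.solo_distance))
            gap_right = np.diff(pos, append=pos[-1] + 10 * int(config.solo_distance))
            solo = (gap_left > config.solo_distance) & (gap_right > config.solo_distance)
        else:
            solo = np.ones(len(pos), dtype=bool)
        cpg_frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                        "is_solo_wcgw": wcgw & solo}))

    cpgs = pd.concat(cpg_frames, ignore_index=True)

    # Latent per-CpG base level, stable across samples outside PMDs.  Levels
    # are locally stratified quantiles of the background Beta (permuted
    # within ~100-CpG blocks) so that every caller window sees the same
    # polarized composition; iid draws would make window dispersion
    # heterogeneous along the genome.
    from scipy.stats import beta as beta_dist

    n_cpg = len(cpgs)
    a_bg = config.background_mean * config.background_concentration
    b_bg = (1.0 - config.background_mean) * config.background_concentration
    block = 101
    ranks = np.empty(n_cpg)
    for start in range(0, n_cpg, block):
        k = min(block, n_cpg - start)
        ranks[start:start + k] = rng.permutation((np.arange(k) + 0.5) / k)
    base_mu = beta_dist.ppf(ranks, a_bg, b_bg)
    shores = default_shores(cgis, config.chrom_sizes)
    in_shore = shores.contains_points(cpgs.chrom.to_numpy(), cpgs.pos.to_numpy())
    a_sh, b_sh = _beta_params(np.array(config.shore_mean),
                              np.array(config.shore_concentration))
    base_mu[in_shore] = beta_dist.ppf(ranks[in_shore], a_sh, b_sh)
    cpgs["base_mu"] = np.clip(base_mu, 1e-4, 1.0 - 1e-4)

    layout = GenomeLayout(
        chrom_sizes=dict(config.chrom_sizes),
        excluded=excluded,
        cgis=cgis,
        shores=default_shores(cgis, config.chrom_sizes),
        promoters=default_promoters(genes, config.chrom_sizes),
        genes=genes,
        gene_sets={"TSG": set(gene_table.loc[gene_table.is_tsg, "gene_id"])},
    )
    cgi_base = pd.Series(
        np.where(rng.random(len(cgis)) < config.cgi_constitutive_prob, "constitutive", "hypo"),
        index=list(cgis.df.name), name="base_state")
    truth = GroundTruth(domains=domains, propensities=propensities,
                        domain_tissue=domain_tissue, cgi_base_state=cgi_base,
                        gene_table=gene_table)
    # stash the CpG template on the layout for the per-sample generator
    layout.cpg_template = cpgs  # type: ignore[attr-defined]
    return layout, truth


def _beta_params(mean: np.ndarray, conc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = np.clip(mean, 1e-4, 1.0 - 1e-4)
    return mean * conc, (1.0 - mean) * conc


def generate_sample(layout: GenomeLayout, truth: GroundTruth, sample_index: int,
                    config: SimConfig, covariate: int = 0, counts: bool = True,
                    ) -> tuple[SampleMethylome | None, IntervalSet]:
    """Generate one sample's methylome and record its planted PMDs in ``truth``.

    ``counts=False`` stops after planting (PMD intervals, CGI states and the
    PMD depth are drawn identically; the per-CpG count arrays are skipped) —
    useful for interval-arithmetic checks on large cohorts.
    """
    if sample_index >= config.n_samples:
        raise ValueError("sample_index out of range")
    rng = _rng(config.seed, 2, sample_index)
    sample_id = f"S{sample_index:03d}"
    tissue = (sample_index % config.n_tissues) + 1 if config.n_tissues > 1 else 0

    # --- activate permissive domains
    lo, hi = config.activity_range
    activity = rng.uniform(lo, hi)
    n_dom = len(truth.propensities)
    p = np.clip(truth.propensities * activity, 0.0, 1.0)
    eligible = (truth.domain_tissue == 0) | (truth.domain_tissue == tissue)
    active = (rng.random(n_dom) < p) & eligible

    dom_df = truth.domains.df
    pmd_rows = []
    for k in np.flatnonzero(active):
        r = dom_df.iloc[k]
        s, e = int(r.start), int(r.end)
        for edge in (0, 1):
            delta = int(rng.uniform(0, config.boundary_jitter))
            sign = 1 if rng.random() < 0.5 else -1
            if edge == 0:
                s = s - delta if sign > 0 else s + delta  # extend left / truncate
            else:
                e = e + delta if sign > 0 else e - delta
        if e - s >= 20_000:
            pmd_rows.append((r.chrom, max(0, s), e))
    planted = (IntervalSet(pmd_rows, validate=False).merged()
               .clip(layout.chrom_sizes).subtract(layout.excluded)
               if pmd_rows else IntervalSet())

    pmd_mean = rng.uniform(*config.pmd_mean_range)

    # --- per-CGI state for this sample
    cgi_df = layout.cgis.df
    in_pmd_bp = layout.cgis.overlap_lengths(planted)
    cgi_len = (cgi_df.end - cgi_df.start).to_numpy()
    cgi_in_pmd = in_pmd_bp >= config.cgi_in_pmd_min_overlap * cgi_len
    base = truth.cgi_base_state.reindex(cgi_df.name).to_numpy()
    gain = rng.random(len(cgi_df)) < config.cgi_gain_prob
    if config.zero_contrast:
        state = base.copy()  # no PMD-driven CGI gain without methylation contrast
    else:
        state = np.where(cgi_in_pmd, np.where(gain, "gained", "hypo"), base)
    gained_level_mean = np.maximum(pmd_mean, config.cgi_gain_min_mean)
    level_mean = np.select(
        [state == "gained", state == "constitutive"],
        [gained_level_mean, config.background_mean],
        default=config.cgi_hypo_mean)
    # constitutive CGIs that sit inside a PMD without gaining keep hypo level
    a, b = _beta_params(level_mean, np.full(len(cgi_df), config.cgi_concentration))
    cgi_level = rng.beta(a, b) if len(cgi_df) else np.array([])

    if not counts:
        truth.pmds_by_sample[sample_id] = planted
        truth.pmd_mean_by_sample[sample_id] = pmd_mean
        truth.sample_tissue[sample_id] = tissue
        truth.cgi_state_by_sample[sample_id] = pd.Series(state, index=list(cgi_df.name))
        return None, planted

    # --- per-CpG true methylation
    cpgs = layout.cpg_template  # type: ignore[attr-defined]
    chrom = cpgs.chrom.to_numpy()
    pos = cpgs.pos.to_numpy()
    n = len(cpgs)
    in_pmd = planted.contains_points(chrom, pos)
    mean = cpgs.base_mu.to_numpy().copy()
    conc = np.full(n, config.replicate_concentration)
    zero_contrast = config.zero_contrast
    if not zero_contrast:
        mean[in_pmd] = pmd_mean
        conc[in_pmd] = config.pmd_concentration

    # covariate-responsive regions: first half of every chromosome
    if covariate:
        sizes = cpgs.chrom.map(layout.chrom_sizes).to_numpy()
        resp = pos < sizes / 2
        mean = np.where(resp & ~in_pmd, np.clip(mean - config.covariate_effect, 0.01, 0.99), mean)

    in_prom = layout.promoters.contains_points(chrom, pos)
    mean[in_prom & ~in_pmd] = config.promoter_hypo_mean
    conc[in_prom & ~in_pmd] = config.cgi_cpg_concentration
    if not zero_contrast:
        mean[in_prom & in_pmd] = pmd_mean
        conc[in_prom & in_pmd] = config.pmd_concentration

    # CGI CpGs follow their island's level
    in_cgi = layout.cgis.contains_points(chrom, pos)
    if len(cgi_df):
        cgi_idx = _assign_to_intervals(chrom, pos, cgi_df)
        has_cgi = cgi_idx >= 0
        mean[has_cgi] = cgi_level[cgi_idx[has_cgi]]
        conc[has_cgi] = config.cgi_cpg_concentration

    solo = cpgs.is_solo_wcgw.to_numpy()
    if not zero_contrast:
        shift = solo & in_pmd & ~in_cgi
        mean[shift] = np.clip(mean[shift] + config.solo_offset, 0.01, 0.99)

    a, b = _beta_params(mean, conc)
    p_true = rng.beta(a, b)

    # --- counts
    r = config.coverage_shape
    t = rng.negative_binomial(r, r / (r + config.coverage_mean), n)
    m = rng.binomial(t, p_true)

    df = pd.DataFrame({"chrom": chrom, "pos": pos, "m": m, "t": t,
                       "is_solo_wcgw": solo})
    meth = SampleMethylome(sample_id, df,
                           {"tissue": tissue, "covariate": covariate,
                            "true_pmd_mean": pmd_mean, "activity": activity})
    meth = annotate_cpgs(meth, layout)

    truth.pmds_by_sample[sample_id] = planted
    truth.pmd_mean_by_sample[sample_id] = pmd_mean
    truth.sample_tissue[sample_id] = tissue
    truth.cgi_state_by_sample[sample_id] = pd.Series(state, index=list(cgi_df.name))
    return meth, planted


def _assign_to_intervals(chrom: np.ndarray, pos: np.ndarray, idf: pd.DataFrame) -> np.ndarray:
    """Index of the covering interval per point, -1 if none (intervals disjoint)."""
    out = np.full(len(pos), -1, dtype=int)
    for c, sub in idf.groupby("chrom"):
        m = chrom == c
        if not m.any():
            continue
        s = sub.start.to_numpy()
        e = sub.end.to_numpy()
        idx = np.searchsorted(s, pos[m], side="right") - 1
        ok = (idx >= 0) & (pos[m] < e[np.clip(idx, 0, None)])
        res = np.where(ok, sub.index.to_numpy()[np.clip(idx, 0, None)], -1)
        out[m] = res
    return out


@dataclass
class Cohort:
    samples: list[SampleMethylome]
    truth: GroundTruth
    layout: GenomeLayout
    sample_sheet: pd.DataFrame
    config: SimConfig

    @property
    def pmds_by_sample(self) -> dict[str, IntervalSet]:
        return self.truth.pmds_by_sample


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the full cohort: layout, per-sample methylomes, sample sheet."""
    config.validate()
    layout, truth = generate_layout(config)
    cov_rng = _rng(config.seed, 3)
    covariates = (cov_rng.random(config.n_samples) < 0.5).astype(int)
    samples = []
    rows = []
    for i in range(config.n_samples):
        meth, _ = generate_sample(layout, truth, i, config, covariate=int(covariates[i]))
        samples.append(meth)
        rows.append({"sample_id": meth.sample_id,
                     "covariate": int(covariates[i]),
                     "tissue": meth.metadata["tissue"],
                     "true_pmd_mean": meth.metadata["true_pmd_mean"]})
    return Cohort(samples, truth, layout, pd.DataFrame(rows), config)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort to disk: methcounts TSVs, truth BED/JSON, sample sheet."""
    import json
    from pathlib import Path

    from .io import write_intervals, write_methylome, write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "methylomes").mkdir(exist_ok=True)
    for s in cohort.samples:
        write_methylome(s, outdir / "methylomes" / f"{s.sample_id}.tsv")
    write_sample_sheet(cohort.sample_sheet, outdir / "sample_sheet.tsv")
    write_intervals(cohort.layout.cgis, outdir / "cgis.bed", bed6=True)
    write_intervals(cohort.layout.genes, outdir / "genes.bed", bed6=True)
    write_intervals(cohort.layout.excluded, outdir / "excluded.bed")
    (outdir / "truth").mkdir(exist_ok=True)
    for sid, pmds in cohort.truth.pmds_by_sample.items():
        write_intervals(pmds, outdir / "truth" / f"{sid}.planted.bed")
    meta = {
        "pmd_mean_by_sample": cohort.truth.pmd_mean_by_sample,
        "sample_tissue": cohort.truth.sample_tissue,
        "cgi_base_state": cohort.truth.cgi_base_state.to_dict(),
    }
    with open(outdir / "truth" / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    with open(outdir / "layout.yaml", "w") as fh:
        yaml.safe_dump({"chrom_sizes": cohort.layout.chrom_sizes,
                        "excluded": "excluded.bed", "cgis": "cgis.bed",
                        "genes": "genes.bed"}, fh)
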