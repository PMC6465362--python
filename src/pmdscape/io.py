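"""Readers/writers for methylomes, interval files, sample sheets and layouts.

Formats
-------
* methcounts-style TSV: ``chrom  pos  strand  context  fraction  coverage``
  with 0-based positions; methylated counts are reconstructed as
  ``M = round(fraction * coverage)``.
* bedGraph: ``chrom  start  end  fraction`` (coverage assumed constant).
* BED3/BED6 for interval sets, 0-based half-open.
* TSV sample sheets, JSON ground truth, YAML layout descriptions.

CpGs reported on the minus strand are collapsed onto the plus-strand
cytosine at ``pos - 1`` and counts are summed per position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .intervals import IntervalSet

logger = logging.getLogger(__name__)

METH_COLUMNS = ["chrom", "pos", "m", "t"]
FLAG_COLUMNS = ["is_solo_wcgw", "in_cgi", "in_shore", "in_promoter"]

SHORE_FLANK_BP = 2_000      # default CGI shore width when no shore file given
PROMOTER_FLANK_BP = 1_000   # default promoter = TSS +/- 1 kb


@dataclass
class SampleMethylome:
    """One sample's per-CpG methylation counts.

    ``data`` columns: chrom, pos (0-based), m, t plus boolean flag columns
    once :func:`annotate_cpgs` has been applied.  Rows are sorted by
    (chrom, pos) and unique; ``0 <= m <= t`` always holds.
    """

    sample_id: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        for col in ("chrom", "pos", "m", "t"):
            if col not in df.columns:
                raise ValueError(f"methylome missing column {col!r}")
        if len(df):
            if (df.m < 0).any() or (df.m > df.t).any():
                raise ValueError("methylome violates 0 <= M <= T")
            key = df[["chrom", "pos"]]
            if key.duplicated().any():
                raise ValueError("duplicate (chrom, pos) records")
            if not df.equals(df.sort_values(["chrom", "pos"], kind="mergesort")):
                logger.warning("methylome %s was unsorted; sorting", self.sample_id)
                self.data = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fraction(self) -> np.ndarray:
        t = self.data.t.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.data.m.to_numpy(dtype=float) / t
        return np.where(t > 0, f, np.nan)

    def covered(self, min_coverage: int = 1) -> pd.DataFrame:
        return self.data[self.data.t >= min_coverage]


@dataclass
class GenomeLayout:
    """Chromosome sizes plus annotation interval sets."""

    chrom_sizes: dict[str, int]
    excluded: IntervalSet = field(default_factory=IntervalSet)
    cgis: IntervalSet = field(default_factory=IntervalSet)
    shores: IntervalSet = field(default_factory=IntervalSet)
    promoters: IntervalSet = field(default_factory=IntervalSet)
    genes: IntervalSet = field(default_factory=IntervalSet)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        for name, iset in [("excluded", self.excluded), ("cgis", self.cgis),
                           ("shores", self.shores), ("promoters", self.promoters),
                           ("genes", self.genes)]:
            df = iset.df
            unknown = set(df.chrom) - set(self.chrom_sizes)
            if unknown:
                raise ValueError(f"{name} intervals on unknown chromosomes: {sorted(unknown)}")
            sizes = df.chrom.map(self.chrom_sizes)
            if len(df) and (df.end > sizes).any():
                raise ValueError(f"{name} intervals exceed chromosome bounds")

    def non_excluded_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return self.chrom_sizes[chrom] - self.excluded.total_length(chrom)
        return sum(self.chrom_sizes.values()) - self.excluded.total_length()

    def non_excluded(self) -> IntervalSet:
        whole = IntervalSet([(c, 0, l) for c, l in self.chrom_sizes.items()])
        return whole.subtract(self.excluded)


def default_shores(cgis: IntervalSet, chrom_sizes: Mapping[str, int]) -> IntervalSet:
    """2-kb flanks of CGIs, CGI bodies themselves removed."""
    rows = []
    for _, r in cgis.df.iterrows():
        rows.append((r.chrom, max(0, r.start - SHORE_FLANK_BP), r.end + SHORE_FLANK_BP))
    flanked = IntervalSet(rows).clip(chrom_sizes)
    return flanked.subtract(cgis)


def default_promoters(genes: IntervalSet, chrom_sizes: Mapping[str, int]) -> IntervalSet:
    """TSS +/- 1 kb (TSS = interval start; synthetic genes are plus-strand)."""
    rows = []
    for _, r in genes.df.iterrows():
        rows.append((r.chrom, max(0, r.start - PROMOTER_FLANK_BP),
                     r.start + PROMOTER_FLANK_BP, r.name if isinstance(r.name, str) else ""))
    return IntervalSet(rows).clip(chrom_sizes)


# --------------------------------------------------------------------- I/O

def read_methylome(path, fmt: str = "methcounts", min_coverage: int = 0,
                   sample_id: str | None = None, bedgraph_coverage: int = 1) -> SampleMethylome:
    """Read a per-CpG methylation table.

    ``fmt='methcounts'`` expects 6 columns (chrom, pos, strand, context,
    fraction, coverage); ``fmt='bedgraph'`` expects 4 columns (chrom, start,
    end, fraction) with an assumed constant coverage ``bedgraph_coverage``.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    rows = []
    solo = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                if fmt == "methcounts":
                    chrom, pos, strand, context, frac, cov = parts[:6]
                    pos = int(pos)
                    frac = float(frac)
                    cov = int(cov)
                    if strand not in "+-":
                        raise ValueError(f"bad strand {strand!r}")
                    if strand == "-":
                        pos -= 1
                elif fmt == "bedgraph":
                    chrom, start, _end, frac = parts[:4]
                    pos = int(start)
                    frac = float(frac)
                    cov = bedgraph_coverage
                    context = "CpG"
                else:
                    raise ValueError(f"unknown format {fmt!r}")
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"fraction {frac} outside [0, 1]")
                if cov < 0:
                    raise ValueError(f"negative coverage {cov}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from None
            rows.append((chrom, pos, int(round(frac * cov)), cov))
            solo.append("solo" in context.lower())
    if not rows:
        logger.warning("empty methylome file %s", path)
        df = pd.DataFrame(columns=METH_COLUMNS + ["is_solo_wcgw"])
        return SampleMethylome(sample_id, df)
    df = pd.DataFrame(rows, columns=METH_COLUMNS)
    df["is_solo_wcgw"] = solo
    # strand-collapse duplicates created by +/- records of the same CpG
    if df.duplicated(["chrom", "pos"]).any():
        df = (df.groupby(["chrom", "pos"], as_index=False)
                .agg(m=("m", "sum"), t=("t", "sum"), is_solo_wcgw=("is_solo_wcgw", "any")))
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if min_coverage > 0:
        df = df[df.t >= min_coverage].reset_index(drop=True)
    return SampleMethylome(sample_id, df)


def write_methylome(methylome: SampleMethylome, path, fmt: str = "methcounts") -> None:
    path = Path(path)
    df = methylome.data
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(df.t > 0, df.m / df.t.replace(0, 1), 0.0) if len(df) else np.array([])
    with open(path, "w") as fh:
        if fmt == "methcounts":
            solo = df["is_solo_wcgw"] if "is_solo_wcgw" in df.columns else pd.Series(False, index=df.index)
            for (chrom, pos, t), f, s in zip(df[["chrom", "pos", "t"]].itertuples(index=False),
                                             frac, solo):
                ctx = "soloWCGW" if s else "CpG"
                fh.write(f"{chrom}\t{pos}\t+\t{ctx}\t{f:.6f}\t{t}\n")
        elif fmt == "bedgraph":
            for (chrom, pos), f in zip(df[["chrom", "pos"]].itertuples(index=False), frac):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{f:.6f}\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def read_intervals(path, strict: bool = True, keep_overlaps: bool = False) -> IntervalSet:
    """Read BED3/BED6.  Overlapping intervals are rejected when ``strict``,
    merged otherwise; ``keep_overlaps`` retains them verbatim (gene
    annotations legitimately overlap)."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else ""
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({chrom}:{start}-{end})")
            rows.append((chrom, start, end, name, score))
    iset = IntervalSet(rows)
    if not keep_overlaps and not iset.is_nonoverlapping():
        if strict:
            raise ValueError(f"{path}: overlapping intervals (strict mode)")
        logger.warning("%s: overlapping intervals merged", path)
        iset = iset.merged()
    return iset


def write_intervals(iset: IntervalSet, path, bed6: bool = False) -> None:
    with open(path, "w") as fh:
        for r in iset.df.itertuples(index=False):
            if bed6:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t{r.score:g}\t+\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("sample sheet must have a 'sample_id' column")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_layout(path) -> GenomeLayout:
    """Load a layout description from YAML.

    Keys: ``chrom_sizes`` (mapping) and optional BED paths ``excluded``,
    ``cgis``, ``shores``, ``promoters``, ``genes`` plus ``gene_sets``
    (mapping set name -> TSV/“one gene per line” file).  Relative paths are
    resolved against the YAML file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    known = {"chrom_sizes", "excluded", "cgis", "shores", "promoters", "genes", "gene_sets"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown layout keys: {sorted(unknown)}")
    base = path.parent

    def _load(key, strict=True, keep_overlaps=False):
        if key not in cfg or cfg[key] is None:
            return IntervalSet()
        return read_intervals(base / cfg[key], strict=strict, keep_overlaps=keep_overlaps)

    chrom_sizes = {str(k): int(v) for k, v in cfg["chrom_sizes"].items()}
    cgis = _load("cgis")
    genes = _load("genes", keep_overlaps=True)  # real gene annotations overlap
    shores = _load("shores") if "shores" in cfg else default_shores(cgis, chrom_sizes)
    promoters = _load("promoters") if "promoters" in cfg else default_promoters(genes, chrom_sizes)
    gene_sets = {}
    for name, p in (cfg.get("gene_sets") or {}).items():
        with open(base / p) as fh:
            gene_sets[name] = {ln.strip().split("\t")[0] for ln in fh if ln.strip()}
    return GenomeLayout(chrom_sizes=chrom_sizes, excluded=_load("excluded", strict=False),
                        cgis=cgis, shores=shores, promoters=promoters,
                        genes=genes, gene_sets=gene_sets)


def annotate_cpgs(methylome: SampleMethylome, layout: GenomeLayout) -> SampleMethylome:
    """Fill per-CpG membership flags from the layout's annotation sets."""
    df = methylome.data.copy()
    unknown = set(df.chrom) - set(layout.chrom_sizes)
    if unknown:
        raise ValueError(f"CpGs on unknown chromosomes: {sorted(unknown)}")
    chrom = df.chrom.to_numpy()
    pos = df.pos.to_numpy()
    df["in_cgi"] = layout.cgis.contains_points(chrom, pos)
    df["in_shore"] = layout.shores.contains_points(chrom, pos)
    df["in_promoter"] = layout.promoters.contains_points(chrom, pos)
    if "is_solo_wcgw" not in df.columns:
        df["is_solo_wcgw"] = False
    return SampleMethylome(methylome.sample_id, df, dict(methylome.metadata))
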