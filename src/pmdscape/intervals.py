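"""Genomic interval sets.

All coordinates throughout the package are 0-based, half-open ``[start, end)``
(BED convention).  An :class:`IntervalSet` is a per-chromosome collection of
such intervals, kept sorted by ``(chrom, start)``.  Most set algebra
(merge/intersect/subtract) operates on the merged representation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_COLUMNS = ["chrom", "start", "end", "name", "score"]


class IntervalSet:
    """Sorted set of 0-based half-open genomic intervals.

    Parameters
    ----------
    records
    	Iterable of ``(chrom, start, end[, name[, score]])`` tuples, or a
    	DataFrame with at least ``chrom``, ``start``, ``end`` columns.
    validate
    	If true (default), reject intervals with ``start >= end``.
    """

    def __init__(self, records: Iterable | pd.DataFrame | None = None, validate: bool = True):
        if records is None:
            df = pd.DataFrame(columns=_COLUMNS)
        elif isinstance(records, pd.DataFrame):
            df = records.copy()
        else:
            rows = []
            for rec in records:
                rec = tuple(rec)
                chrom, start, end = rec[0], int(rec[1]), int(rec[2])
                name = rec[3] if len(rec) > 3 else ""
                score = float(rec[4]) if len(rec) > 4 else 0.0
                rows.append((chrom, start, end, name, score))
            df = pd.DataFrame(rows, columns=_COLUMNS)
        if "name" not in df.columns:
            df["name"] = ""
        if "score" not in df.columns:
            df["score"] = 0.0
        df = df[_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if validate and len(df):
            bad = df[df.start >= df.end]
            if len(bad):
                first = bad.iloc[0]
                raise ValueError(
                    f"invalid interval {first.chrom}:{first.start}-{first.end} (start >= end)"
                )
            if (df.start < 0).any():
                raise ValueError("negative interval start")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        self._merged_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # ---------------------------------------------------------------- basics
    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"IntervalSet({len(self)} intervals, {self.total_length()} bp)"

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    def copy(self) -> "IntervalSet":
        return IntervalSet(self.df.copy(), validate=False)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.df.chrom.unique())

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Raw (possibly overlapping) starts/ends for one chromosome."""
        sub = self.df[self.df.chrom == chrom]
        return sub.start.to_numpy(), sub.end.to_numpy()

    def _merged(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._merged_cache is None:
            out = {}
            for chrom, sub in self.df.groupby("chrom", sort=True):
                s = sub.start.to_numpy()
                e = sub.end.to_numpy()
                out[chrom] = _merge_chrom(s, e)
            self._merged_cache = out
        return self._merged_cache

    def merged(self) -> "IntervalSet":
        """Union of this set's own intervals (overlaps and bookends merged)."""
        rows = []
        for chrom, (s, e) in self._merged().items():
            rows.extend((chrom, a, b) for a, b in zip(s, e))
        return IntervalSet(rows, validate=False)

    def is_nonoverlapping(self) -> bool:
        for chrom, sub in self.df.groupby("chrom"):
            s = sub.start.to_numpy()
            e = sub.end.to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                return False
        return True

    def total_length(self, chrom: str | None = None) -> int:
        """Total bp covered (union length; overlaps counted once)."""
        merged = self._merged()
        if chrom is not None:
            if chrom not in merged:
                return 0
            s, e = merged[chrom]
            return int((e - s).sum())
        return int(sum((e - s).sum() for s, e in merged.values()))

    # ------------------------------------------------------------ set algebra
    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        rows = []
        a, b = self._merged(), other._merged()
        for chrom in set(a) & set(b):
            s, e = _intersect_chrom(*a[chrom], *b[chrom])
            rows.extend((chrom, lo, hi) for lo, hi in zip(s, e))
        return IntervalSet(rows, validate=False)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        df = pd.concat([self.df, other.df], ignore_index=True)
        return IntervalSet(df, validate=False).merged()

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        rows = []
        a, b = self._merged(), other._merged()
        for chrom, (s, e) in a.items():
            if chrom not in b:
                rows.extend((chrom, lo, hi) for lo, hi in zip(s, e))
                continue
            cs, ce = _subtract_chrom(s, e, *b[chrom])
            rows.extend((chrom, lo, hi) for lo, hi in zip(cs, ce))
        return IntervalSet(rows, validate=False)

    def clip(self, chrom_sizes: Mapping[str, int]) -> "IntervalSet":
        df = self.df[self.df.chrom.isin(chrom_sizes)].copy()
        sizes = df.chrom.map(chrom_sizes).to_numpy()
        df["start"] = np.clip(df.start.to_numpy(), 0, sizes)
        df["end"] = np.minimum(df.end.to_numpy(), sizes)
        df = df[df.start < df.end]
        return IntervalSet(df, validate=False)

    # -------------------------------------------------------------- queries
    def contains_points(self, chrom: str | Sequence[str], pos) -> np.ndarray:
        """Boolean membership of point positions (vectorized per chromosome)."""
        pos = np.asarray(pos, dtype=np.int64)
        merged = self._merged()
        if isinstance(chrom, str):
            if chrom not in merged:
                return np.zeros(pos.shape, dtype=bool)
            s, e = merged[chrom]
            idx = np.searchsorted(s, pos, side="right") - 1
            ok = idx >= 0
            out = np.zeros(pos.shape, dtype=bool)
            out[ok] = pos[ok] < e[idx[ok]]
            return out
        chrom = np.asarray(chrom)
        out = np.zeros(pos.shape, dtype=bool)
        for c in np.unique(chrom):
            m = chrom == c
            out[m] = self.contains_points(str(c), pos[m])
        return out

    def overlap_lengths(self, other: "IntervalSet") -> np.ndarray:
        """bp of ``other`` (merged) overlapped by each interval of ``self``.

        Order follows ``self.df`` rows.
        """
        b = other._merged()
        out = np.zeros(len(self.df), dtype=np.int64)
        for chrom, sub in self.df.groupby("chrom"):
            if chrom not in b:
                continue
            s2, e2 = b[chrom]
            cum = np.concatenate([[0], np.cumsum(e2 - s2)])
            st = sub.start.to_numpy()
            en = sub.end.to_numpy()
            i0 = np.searchsorted(e2, st, side="right")
            i1 = np.searchsorted(s2, en, side="left")
            ov = np.zeros(len(sub), dtype=np.int64)
            for k in range(len(sub)):
                if i1[k] <= i0[k]:
                    continue
                full = cum[i1[k]] - cum[i0[k]]
                full -= max(0, st[k] - s2[i0[k]])
                full -= max(0, e2[i1[k] - 1] - en[k])
                ov[k] = max(0, full)
            out[sub.index] = ov
        return out

    # ---------------------------------------------------------------- export
    def to_dataframe(self) -> pd.DataFrame:
        return self.df.copy()


def _merge_chrom(s: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(s) == 0:
        return s.astype(np.int64), e.astype(np.int64)
    order = np.argsort(s, kind="mergesort")
    s, e = s[order], e[order]
    # running max of ends; a new block starts where start > max(previous ends)
    run_e = np.maximum.accumulate(e)
    new_block = np.concatenate([[True], s[1:] > run_e[:-1]])
    block = np.cumsum(new_block) - 1
    ms = s[new_block]
    me = np.zeros(len(ms), dtype=np.int64)
    np.maximum.at(me, block, e)
    return ms.astype(np.int64), me


def _intersect_chrom(s1, e1, s2, e2) -> tuple[np.ndarray, np.ndarray]:
    out_s, out_e = [], []
    i = j = 0
    n1, n2 = len(s1), len(s2)
    while i < n1 and j < n2:
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if lo < hi:
            out_s.append(lo)
            out_e.append(hi)
        if e1[i] < e2[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def _subtract_chrom(s1, e1, s2, e2) -> tuple[np.ndarray, np.ndarray]:
    out_s, out_e = [], []
    j = 0
    n2 = len(s2)
    for a, b in zip(s1, e1):
        cur = a
        while j < n2 and e2[j] <= cur:
            j += 1
        k = j
        while k < n2 and s2[k] < b:
            if s2[k] > cur:
                out_s.append(cur)
                out_e.append(min(s2[k], b))
            cur = max(cur, e2[k])
            if cur >= b:
                break
            k += 1
        if cur < b:
            out_s.append(cur)
            out_e.append(b)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlap_stats(a: IntervalSet, b: IntervalSet) -> dict[str, float]:
    """bp-level Jaccard and directional containment of two interval sets."""
    inter = a.intersection(b).total_length()
    la = a.total_length()
    lb = b.total_length()
    union = la + lb - inter
    return {
        "jaccard": inter / union if union else 1.0,
        "frac_a_in_b": inter / la if la else 0.0,
        "frac_b_in_a": inter / lb if lb else 0.0,
        "intersection_bp": inter,
        "union_bp": union,
    }
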