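"""Genomic interval algebra over 0-based half-open (BED) coordinates.

Every downstream stage of the pipeline — contact-peak reconciliation,
super-enhancer consensus, the Ψ/Ω triple intersection and the shuffle-based
permutation nulls — is built on the small set of deterministic operations
defined here: sort, merge, intersect (``-u`` semantics), subtract (``-v``
semantics), slop and a seeded non-overlapping shuffle.

Two base on neighbouring intervals touch but do not overlap: ``[0, 100)`` and
``[100, 200)`` share no base.  "Overlap" throughout means sharing at least one
base.  Strand is never consulted; gene strand is carried only as annotation by
higher-level tables.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "ChromSizes",
    "merge",
    "intersect_keep",
    "subtract_filter",
    "slop",
    "shuffle",
    "ShufflePlacementError",
]

_CORE_COLS = ["chrom", "start", "end"]


class ShufflePlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be achieved on a chromosome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic range ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (end <= start)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        super().__init__(sizes)

    def validate(self, ivs: "IntervalSet") -> None:
        """Raise if any interval falls on an unknown chrom or past its end."""
        for chrom, sub in ivs.df.groupby("chrom", sort=False, observed=True):
            if chrom not in self:
                raise KeyError(f"chromosome {chrom!r} absent from chrom sizes")
            if int(sub["end"].max()) > self[chrom]:
                bad = sub[sub["end"] > self[chrom]].iloc[0]
                raise ValueError(
                    f"interval {chrom}:{bad.start}-{bad.end} exceeds chrom length {self[chrom]}"
                )


@dataclass
class IntervalSet:
    """An ordered collection of intervals with optional per-interval payload.

    Backed by a DataFrame with at least ``chrom``, ``start``, ``end`` columns;
    any further columns (name, score, lncRNA id, mark, ...) ride along through
    the operations that preserve record identity (intersect/subtract/slop).
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_CORE_COLS))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        missing = [c for c in _CORE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"IntervalSet frame lacks columns {missing}")
        df = df.reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"invalid interval record {r.chrom}:{r.start}-{r.end} (end <= start or start < 0)"
            )
        self.df = df

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_intervals(cls, ivs: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [(iv.chrom, iv.start, iv.end) for iv in ivs]
        return cls(pd.DataFrame(rows, columns=_CORE_COLS))

    @classmethod
    def from_records(cls, rows: Iterable[tuple], columns: list[str] | None = None) -> "IntervalSet":
        return cls(pd.DataFrame(list(rows), columns=columns or _CORE_COLS))

    # -- basics -------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for r in self.df.itertuples(index=False):
            yield GenomicInterval(r.chrom, int(r.start), int(r.end))

    def sort(self) -> "IntervalSet":
        """Sorted copy; tie-break (chrom lexicographic, start, end)."""
        out = self.df.sort_values(_CORE_COLS, kind="mergesort").reset_index(drop=True)
        return IntervalSet(out)

    def total_length(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def copy(self) -> "IntervalSet":
        return IntervalSet(self.df.copy())


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def merge(ivs: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge overlapping/nearby intervals.

    Two intervals on one chromosome are merged when they overlap, touch, or
    are separated by a gap *strictly less than* ``max_gap`` bases.  With
    ``max_gap=0`` only overlapping or touching intervals are merged.  The
    strict inequality follows the "separated by less than d" stitching rule
    used for super-enhancer consolidation (note: bedtools ``merge -d`` uses
    <=; the one-base difference is covered by a boundary test).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if len(ivs) == 0:
        return IntervalSet()
    # merge iff gap < threshold, where touching (gap 0) always merges
    thr = max(max_gap, 1)
    s = ivs.sort().df
    out_rows: list[tuple[str, int, int]] = []
    for chrom, sub in s.groupby("chrom", sort=True, observed=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cummax_end = np.maximum.accumulate(ends)
        # new group whenever this start is >= running end + thr - ... i.e. gap >= thr
        new_grp = np.empty(len(sub), dtype=bool)
        new_grp[0] = True
        new_grp[1:] = starts[1:] - cummax_end[:-1] >= thr
        grp = np.cumsum(new_grp) - 1
        for g in range(grp[-1] + 1):
            m = grp == g
            out_rows.append((chrom, int(starts[m].min()), int(ends[m].max())))
    return IntervalSet(pd.DataFrame(out_rows, columns=_CORE_COLS))


def _coverage_arrays(b: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Disjoint sorted coverage per chrom for overlap queries."""
    cov = merge(b, 0)
    out = {}
    for chrom, sub in cov.df.groupby("chrom", sort=False, observed=True):
        out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def overlaps_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean mask over ``a.df`` rows: does this record share >=1 bp with ``b``?"""
    mask = np.zeros(len(a), dtype=bool)
    if len(a) == 0 or len(b) == 0:
        return mask
    cov = _coverage_arrays(b)
    chroms = a.df["chrom"].to_numpy()
    starts = a.df["start"].to_numpy()
    ends = a.df["end"].to_numpy()
    for chrom, (bs, be) in cov.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        s, e = starts[sel], ends[sel]
        # last covered block whose start is <= query start
        j = np.searchsorted(bs, s, side="right") - 1
        hit = np.zeros(len(s), dtype=bool)
        ok = j >= 0
        hit[ok] = be[j[ok]] > s[ok]
        # or the next block starts before the query ends
        k = j + 1
        ok2 = k < len(bs)
        hit[ok2] |= bs[k[ok2]] < e[ok2]
        mask[np.flatnonzero(sel)] = hit
    return mask


def intersect_keep(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Report-once intersection (bedtools ``intersect -u`` semantics).

    Each ``a`` record is kept, with original coordinates and payload, iff it
    overlaps at least one ``b`` interval by >=1 bp; kept once regardless of
    how many ``b`` intervals it touches.
    """
    return IntervalSet(a.df[overlaps_any(a, b)].reset_index(drop=True))


def subtract_filter(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Whole-record exclusion (bedtools ``intersect -v`` semantics).

    Removes every ``a`` record overlapping ``b``; records are never clipped.
    """
    return IntervalSet(a.df[~overlaps_any(a, b)].reset_index(drop=True))


def slop(ivs: IntervalSet, pad: int, sizes: ChromSizes) -> IntervalSet:
    """Symmetric extension by ``pad`` bp, clamped to ``[0, chrom length)``."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    df = ivs.df.copy()
    for chrom in df["chrom"].unique():
        if chrom not in sizes:
            raise KeyError(f"chromosome {chrom!r} absent from chrom sizes")
    lens = df["chrom"].map(sizes).to_numpy()
    df["start"] = np.maximum(0, df["start"].to_numpy() - pad)
    df["end"] = np.minimum(lens, df["end"].to_numpy() + pad)
    return IntervalSet(df)


def count_overlaps(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Per ``a``-record count of ``b`` intervals sharing >=1 bp with it."""
    counts = np.zeros(len(a), dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        return counts
    bs_sorted = b.sort().df
    for chrom, sub in bs_sorted.groupby("chrom", sort=False, observed=True):
        sel = (a.df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        s = a.df["start"].to_numpy()[sel]
        e = a.df["end"].to_numpy()[sel]
        bstart = sub["start"].to_numpy()
        bend = sub["end"].to_numpy()
        # b sorted by start; count b with bstart < e minus b with bend <= s
        n_start_before_end = np.searchsorted(bstart, e, side="left")
        bend_sorted = np.sort(bend)
        n_end_before_start = np.searchsorted(bend_sorted, s, side="right")
        counts[np.flatnonzero(sel)] = n_start_before_end - n_end_before_start
    return counts


def shuffle(
    ivs: IntervalSet,
    sizes: ChromSizes,
    rng: np.random.Generator | int,
    exclude: IntervalSet | None = None,
    max_tries_per_interval: int = 1000,
    max_restarts: int = 20,
) -> IntervalSet:
    """Chromosome-preserving, non-overlapping random repositioning.

    Mirrors ``bedtools shuffle -chrom -noOverlapping``: each interval keeps its
    chromosome and length and receives a uniformly drawn start; placements are
    rejected until they overlap neither previously placed intervals nor the
    optional ``exclude`` set.  Placement is sequential with a bounded per-
    interval retry budget and whole-chromosome restarts; for a single interval
    per chromosome the start is exactly uniform.  Deterministic for a fixed
    seed or Generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sizes.validate(ivs)
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if exclude is not None:
        for chrom, sub in merge(exclude, 0).df.groupby("chrom", sort=False, observed=True):
            excl_by_chrom[chrom] = list(zip(sub["start"], sub["end"]))
    out_rows: list[tuple[str, int, int]] = []
    for chrom, sub in ivs.sort().df.groupby("chrom", sort=True, observed=True):
        lengths = (sub["end"] - sub["start"]).to_numpy()
        clen = sizes[chrom]
        if int(lengths.sum()) >= clen:
            raise ShufflePlacementError(
                f"total interval length {int(lengths.sum())} on {chrom} leaves no room "
                f"for non-overlapping placement (chrom length {clen})"
            )
        placed = _place_chrom(
            lengths, clen, rng, excl_by_chrom.get(chrom, []),
            max_tries_per_interval, max_restarts, chrom,
        )
        out_rows.extend((chrom, int(s), int(s + l)) for s, l in placed)
    return IntervalSet(pd.DataFrame(out_rows, columns=_CORE_COLS))


def _place_chrom(
    lengths: np.ndarray,
    clen: int,
    rng: np.random.Generator,
    exclude: list[tuple[int, int]],
    max_tries: int,
    max_restarts: int,
    chrom: str,
) -> list[tuple[int, int]]:
    for _restart in range(max_restarts):
        occ: list[tuple[int, int]] = sorted(exclude)
        ok = True
        placed: list[tuple[int, int]] = []
        for L in lengths:
            L = int(L)
            hi = clen - L  # inclusive upper bound for start
            success = False
            for _ in range(max_tries):
                s = int(rng.integers(0, hi + 1))
                e = s + L
                i = bisect.bisect_right(occ, (s, clen + 1))
                if i > 0 and occ[i - 1][1] > s:
                    continue
                if i < len(occ) and occ[i][0] < e:
                    continue
                occ.insert(i, (s, e))
                placed.append((s, L))
                success = True
                break
            if not success:
                ok = False
                break
        if ok:
            return placed
    raise ShufflePlacementError(
        f"could not place {len(lengths)} intervals on {chrom} (length {clen}) "
        f"within the retry budget; the toy genome is too crowded"
    )
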