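"""Independent per-base oracles and small utilities shared across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from lncse.intervals import IntervalSet


def bitmap(ivs: IntervalSet, chrom: str, length: int) -> np.ndarray:
    """Per-base occupancy of one chromosome."""
    cov = np.zeros(length, dtype=bool)
    sub = ivs.df[ivs.df["chrom"] == chrom]
    for r in sub.itertuples(index=False):
        cov[r.start:r.end] = True
    return cov


def bitmap_merge(ivs: IntervalSet, max_gap: int, chrom_lengths: dict[str, int]) -> list[tuple]:
    """Merge oracle: dilate gaps shorter than max(1, max_gap) on a bitmap."""
    thr = max(max_gap, 1)
    out = []
    for chrom in sorted(chrom_lengths):
        cov = bitmap(ivs, chrom, chrom_lengths[chrom])
        runs = _runs(cov)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < thr:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out.extend((chrom, s, e) for s, e in merged)
    return out


def _runs(cov: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(cov.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if cov[0]:
        starts = [0] + starts
    if cov[-1]:
        ends = ends + [len(cov)]
    return list(zip(starts, ends))


def bitmap_hits(a: IntervalSet, b: IntervalSet, chrom_lengths: dict[str, int]) -> np.ndarray:
    """Oracle mask: which a-records share >=1 base with b's coverage."""
    covs = {c: bitmap(b, c, n) for c, n in chrom_lengths.items()}
    mask = np.zeros(len(a), dtype=bool)
    for i, r in enumerate(a.df.itertuples(index=False)):
        mask[i] = bool(covs[r.chrom][r.start:r.end].any())
    return mask


def bitmap_counts(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Oracle per-a-record count of overlapping b records (pairwise scan)."""
    counts = np.zeros(len(a), dtype=int)
    for i, ra in enumerate(a.df.itertuples(index=False)):
        for rb in b.df.itertuples(index=False):
            if ra.chrom == rb.chrom and ra.start < rb.end and rb.start < ra.end:
                counts[i] += 1
    return counts


def random_interval_set(rng: np.random.Generator, n: int,
                        chrom_lengths: dict[str, int],
                        max_width: int = 5_000) -> IntervalSet:
    chroms = sorted(chrom_lengths)
    rows = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        w = int(rng.integers(1, max_width + 1))
        s = int(rng.integers(0, chrom_lengths[c] - w + 1))
        rows.append((c, s, s + w))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def match_planted_se(ses_df: pd.DataFrame, planted: list[dict]) -> pd.Series:
    """Map recovered consensus SE rows to planted SE keys by overlap."""
    def match(row):
        for p in planted:
            if (p["chrom"] == row["chrom"] and p["start"] < row["end"]
                    and row["start"] < p["end"]):
                return p["key"]
        return None

    return ses_df.apply(match, axis=1)
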