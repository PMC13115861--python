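"""Consensus RNA-chromatin contact peaks from split-probe replicate fractions.

A one-to-all RNA-chromatin experiment sequenced with an odd/even split-probe
design yields, per biological replicate, two peak sets that act as an internal
reproducibility control plus an input control used upstream at peak-calling
time.  This module implements the two reconciliation rules downstream of peak
calling:

1. within a replicate, an odd and an even peak support each other when their
   250 bp-extended forms share at least one base; supported pairs are
   collapsed to a single replicate-level interval;
2. across replicates, an interval is retained when it overlaps replicate-level
   intervals from at least ``min_support`` replicates in total; retained
   intervals are pooled and merged into the final consensus set.

The interval reconstructed from a supported odd/even pair is, in the default
``"union"`` mode, the union of the two original peaks.  The alternative
``"literal"`` mode computes ``min(starts)+pad`` / ``max(ends)-pad`` from the
original coordinates, which can invert short overlapping pairs; such
degenerate records are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    ChromSizes,
    IntervalSet,
    count_overlaps,
    merge,
    overlaps_any,
    slop,
)

logger = logging.getLogger(__name__)

FRACTIONS = ("odd", "even", "input")


@dataclass
class FractionPeakSet:
    replicate: str
    fraction: str
    peaks: IntervalSet

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}")
        self.peaks = self.peaks.sort()


@dataclass
class ReplicatePeakSet:
    replicate: str
    peaks: IntervalSet  # merged within the replicate


@dataclass
class ConsensusContactPeaks:
    peaks: IntervalSet
    support: pd.DataFrame = field(default_factory=pd.DataFrame)  # chrom,start,end,n_replicates

    def __len__(self) -> int:
        return len(self.peaks)


def _overlapping_pairs(a: IntervalSet, b: IntervalSet) -> list[tuple[int, int]]:
    """Indices (i, j) of records of a and b sharing >=1 base. O(n*m) per chrom."""
    pairs: list[tuple[int, int]] = []
    for chrom in a.df["chrom"].unique():
        ia = np.flatnonzero((a.df["chrom"] == chrom).to_numpy())
        ib = np.flatnonzero((b.df["chrom"] == chrom).to_numpy())
        if len(ia) == 0 or len(ib) == 0:
            continue
        s_a = a.df["start"].to_numpy()[ia][:, None]
        e_a = a.df["end"].to_numpy()[ia][:, None]
        s_b = b.df["start"].to_numpy()[ib][None, :]
        e_b = b.df["end"].to_numpy()[ib][None, :]
        hit = (s_a < e_b) & (s_b < e_a)
        for i, j in zip(*np.nonzero(hit)):
            pairs.append((int(ia[i]), int(ib[j])))
    return pairs


def reconcile_fractions(
    odd: FractionPeakSet,
    even: FractionPeakSet,
    sizes: ChromSizes,
    pad: int = 250,
    mode: str = "union",
) -> ReplicatePeakSet:
    """Collapse cross-supported odd/even peak pairs into replicate-level peaks.

    Peaks with no cross-fraction partner (after symmetric ``pad`` extension)
    are dropped; the surviving reconstructed intervals are merged (gap 0)
    within the replicate.
    """
    if odd.replicate != even.replicate:
        raise ValueError(
            f"fraction sets belong to different replicates: {odd.replicate!r} vs {even.replicate!r}"
        )
    if mode not in ("union", "literal"):
        raise ValueError(f"unknown reconciliation mode {mode!r}")
    odd_ext = slop(odd.peaks, pad, sizes)
    even_ext = slop(even.peaks, pad, sizes)
    pairs = _overlapping_pairs(odd_ext, even_ext)
    rows: list[tuple[str, int, int]] = []
    n_degenerate = 0
    for i, j in pairs:
        ro = odd.peaks.df.iloc[i]
        re = even.peaks.df.iloc[j]
        lo, hi = min(ro.start, re.start), max(ro.end, re.end)
        if mode == "literal":
            lo, hi = lo + pad, hi - pad
            if hi <= lo:
                n_degenerate += 1
                continue
        rows.append((ro.chrom, int(lo), int(hi)))
    if n_degenerate:
        logger.warning(
            "replicate %s: dropped %d degenerate reconstructed interval(s) in literal mode",
            odd.replicate, n_degenerate,
        )
    if not rows:
        return ReplicatePeakSet(odd.replicate, IntervalSet())
    supported = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return ReplicatePeakSet(odd.replicate, merge(supported, 0))


def replicate_consensus(
    reps: list[ReplicatePeakSet],
    min_support: int = 2,
) -> ConsensusContactPeaks:
    """Retain intervals supported by >= ``min_support`` replicates, pool, merge.

    A replicate-level interval counts as supported when it overlaps (>=1 bp)
    intervals from at least ``min_support - 1`` *other* replicates.  Support
    in the provenance table is the number of distinct replicates contributing
    an overlapping interval to each final consensus peak.
    """
    if min_support > len(reps):
        raise ValueError(
            f"min_support={min_support} exceeds the number of replicates ({len(reps)})"
        )
    kept_frames = []
    for i, rep in enumerate(reps):
        if len(rep.peaks) == 0:
            continue
        n_others = np.zeros(len(rep.peaks), dtype=int)
        for j, other in enumerate(reps):
            if i == j or len(other.peaks) == 0:
                continue
            n_others += overlaps_any(rep.peaks, other.peaks).astype(int)
        kept = rep.peaks.df[n_others >= (min_support - 1)]
        if len(kept):
            kept_frames.append(kept)
    if not kept_frames:
        return ConsensusContactPeaks(IntervalSet(), pd.DataFrame(
            columns=["chrom", "start", "end", "n_replicates"]))
    pooled = IntervalSet(pd.concat(kept_frames, ignore_index=True))
    consensus = merge(pooled, 0)
    # provenance: number of distinct replicates overlapping each consensus peak
    n_sup = np.zeros(len(consensus), dtype=int)
    for rep in reps:
        if len(rep.peaks) == 0:
            continue
        n_sup += (count_overlaps(consensus, rep.peaks) > 0).astype(int)
    prov = consensus.df.copy()
    prov["n_replicates"] = n_sup
    return ConsensusContactPeaks(consensus, prov)


def consensus_from_fractions(
    fraction_sets: list[FractionPeakSet],
    sizes: ChromSizes,
    pad: int = 250,
    min_support: int = 2,
    mode: str = "union",
) -> ConsensusContactPeaks:
    """End-to-end: group fractions by replicate, reconcile, take the consensus.

    Input fractions are accepted for manifest completeness but not used here:
    they act as the control at peak-calling time, upstream of this module.
    """
    by_rep: dict[str, dict[str, FractionPeakSet]] = {}
    for fs in fraction_sets:
        by_rep.setdefault(fs.replicate, {})[fs.fraction] = fs
    reps = []
    for rep_id in sorted(by_rep):
        d = by_rep[rep_id]
        if "odd" not in d or "even" not in d:
            raise ValueError(f"replicate {rep_id!r} lacks an odd or even fraction")
        reps.append(reconcile_fractions(d["odd"], d["even"], sizes, pad=pad, mode=mode))
    return replicate_consensus(reps, min_support=min_support)
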