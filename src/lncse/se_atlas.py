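"""Per-condition consensus super-enhancers and tissue-specificity classes.

Super-enhancer annotations arrive as one BED per sample (e.g. three cancer
cell-line samples and six normal tissue samples).  Per condition, each
sample's SEs are first consolidated by stitching entries separated by less
than ``intra_gap`` (default 12,500 bp, the conventional SE stitching
distance); candidates merged across samples are then retained only with
support from at least ``min_support`` samples (all three for the cancer
condition, five of six for normal, in the defaults used by the drivers).
Cancer and normal consensus sets are finally compared at a >=1 bp overlap to
label each SE cancer-specific, normal-specific, or shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, count_overlaps, merge, overlaps_any

CONDITIONS = ("cancer", "normal")
SPECIFICITY = ("cancer-specific", "normal-specific", "shared")


@dataclass
class SESample:
    sample: str
    condition: str
    ses: IntervalSet

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        self.ses = self.ses.sort()


@dataclass
class ConsensusSE:
    """A merged consensus super-enhancer with its downstream annotations."""

    se_id: str
    interval: GenomicInterval
    condition: str
    support: int
    specificity: str | None = None
    psi_label: str | None = None  # "psi" / "omega" / None (n/a)
    mark_profile: list[tuple[str, str]] = field(default_factory=list)  # (mark, sign)
    contact_count: int | None = None


def _as_interval_set(ses: list[ConsensusSE]) -> IntervalSet:
    rows = [(s.interval.chrom, s.interval.start, s.interval.end, s.se_id) for s in ses]
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


def build_condition_consensus(
    samples: list[SESample],
    min_support: int,
    intra_gap: int = 12_500,
    cross_gap: int = 0,
    id_prefix: str = "se",
    id_start: int = 1,
) -> list[ConsensusSE]:
    """Merge one condition's samples into supported consensus SEs.

    ``intra_gap`` is the within-sample stitching distance (strict ``<``);
    ``cross_gap`` the merge distance for forming cross-sample candidates
    (default 0: only overlapping/touching sample SEs join a candidate).
    Ids are assigned in genomic sort order starting at ``id_start``.
    """
    if not samples:
        raise ValueError("no SE samples provided")
    conditions = {s.condition for s in samples}
    if len(conditions) != 1:
        raise ValueError(f"mixed conditions in one consensus build: {sorted(conditions)}")
    condition = samples[0].condition
    if min_support > len(samples):
        raise ValueError(f"min_support={min_support} exceeds sample count {len(samples)}")
    self_merged = [merge(s.ses, intra_gap) for s in samples]
    union = IntervalSet(pd.concat([m.df for m in self_merged], ignore_index=True))
    candidates = merge(union, cross_gap)
    support = np.zeros(len(candidates), dtype=int)
    for m in self_merged:
        support += (count_overlaps(candidates, m) > 0).astype(int)
    kept = candidates.df[support >= min_support].reset_index(drop=True)
    out = []
    for k, r in enumerate(kept.itertuples(index=False)):
        out.append(
            ConsensusSE(
                se_id=f"{id_prefix}_{id_start + k}",
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                condition=condition,
                support=int(support[support >= min_support][k]),
            )
        )
    return out


def _max_pair_overlap(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Per a-record maximum single-partner overlap width (bp) against b."""
    out = np.zeros(len(a), dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        return out
    for chrom in a.df["chrom"].unique():
        ia = np.flatnonzero((a.df["chrom"] == chrom).to_numpy())
        sel_b = (b.df["chrom"] == chrom).to_numpy()
        if not sel_b.any():
            continue
        s_a = a.df["start"].to_numpy()[ia][:, None]
        e_a = a.df["end"].to_numpy()[ia][:, None]
        s_b = b.df["start"].to_numpy()[sel_b][None, :]
        e_b = b.df["end"].to_numpy()[sel_b][None, :]
        ov = np.minimum(e_a, e_b) - np.maximum(s_a, s_b)
        out[ia] = np.maximum(ov.max(axis=1), 0)
    return out


def classify_specificity(
    cancer: list[ConsensusSE],
    normal: list[ConsensusSE],
    min_overlap_bp: int = 1,
) -> tuple[list[ConsensusSE], list[ConsensusSE]]:
    """Label each consensus SE by cross-condition overlap (>= ``min_overlap_bp``).

    The default 1 labels an SE "shared" as soon as it shares a single base
    with any SE of the other condition, the default-parameter comparison used
    throughout; larger values require a single partner covering that many
    bases.
    """
    c_set = _as_interval_set(cancer) if cancer else IntervalSet()
    n_set = _as_interval_set(normal) if normal else IntervalSet()
    if min_overlap_bp == 1:
        c_hit = overlaps_any(c_set, n_set) if len(cancer) else np.array([], dtype=bool)
        n_hit = overlaps_any(n_set, c_set) if len(normal) else np.array([], dtype=bool)
    else:
        c_hit = _max_pair_overlap(c_set, n_set) >= min_overlap_bp
        n_hit = _max_pair_overlap(n_set, c_set) >= min_overlap_bp
    for se, hit in zip(cancer, c_hit):
        se.specificity = "shared" if hit else "cancer-specific"
    for se, hit in zip(normal, n_hit):
        se.specificity = "shared" if hit else "normal-specific"
    return cancer, normal


def specificity_summary(cancer: list[ConsensusSE], normal: list[ConsensusSE]) -> dict[str, int]:
    """Class counts with shared regions deduplicated across the two conditions.

    A shared region is represented once: shared cancer SEs and shared normal
    SEs are merged (>=1 bp overlap chains) and the merged regions counted.
    """
    n_cancer_specific = sum(1 for s in cancer if s.specificity == "cancer-specific")
    n_normal_specific = sum(1 for s in normal if s.specificity == "normal-specific")
    shared_rows = [
        (s.interval.chrom, s.interval.start, s.interval.end)
        for s in list(cancer) + list(normal)
        if s.specificity == "shared"
    ]
    if shared_rows:
        shared_merged = merge(
            IntervalSet(pd.DataFrame(shared_rows, columns=["chrom", "start", "end"])), 0
        )
        n_shared = len(shared_merged)
    else:
        n_shared = 0
    return {
        "cancer_specific": n_cancer_specific,
        "normal_specific": n_normal_specific,
        "shared": n_shared,
        "total": n_cancer_specific + n_normal_specific + n_shared,
    }


def ses_from_table(df: pd.DataFrame) -> list[ConsensusSE]:
    """Inverse of :func:`consensus_table` (stage outputs re-enter the pipeline)."""
    out = []
    for r in df.itertuples(index=False):
        marks = []
        if isinstance(r.marks, str) and r.marks:
            for item in r.marks.split(";"):
                mark, sign = item[:-1].rsplit("(", 1)
                marks.append((mark, sign))
        out.append(
            ConsensusSE(
                se_id=r.se_id,
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                condition=r.condition,
                support=int(r.support),
                specificity=None if pd.isna(r.specificity) else r.specificity,
                psi_label=None if pd.isna(r.psi_label) else r.psi_label,
                mark_profile=marks,
                contact_count=None if pd.isna(r.contact_count) else int(r.contact_count),
            )
        )
    return out


def consensus_table(ses: list[ConsensusSE]) -> pd.DataFrame:
    rows = []
    for s in ses:
        rows.append(
            {
                "se_id": s.se_id,
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "condition": s.condition,
                "support": s.support,
                "specificity": s.specificity,
                "psi_label": s.psi_label,
                "marks": ";".join(f"{m}({sg})" for m, sg in s.mark_profile),
                "contact_count": s.contact_count,
            }
        )
    return pd.DataFrame(rows)
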