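"""Two-stage triple intersection: contact-confirmed correlation peaks and Ψ/Ω labels.

The classification asks, for each cancer-specific super-enhancer, whether the
focal lncRNA both physically contacts the genome there *and* shows a
cross-cell-type correlation between its expression and a histone mark at the
same locus.  Stage one intersects the lncRNA's correlation peaks with the
consensus contact peaks ("confirmed" peaks); stage two labels an SE Ψ
(lncRNA-reactive) when at least one confirmed peak falls within it, else Ω.

Also here: per-SE contact-peak density (for the Ψ-vs-contacted-Ω density
comparison), promoter/TSS-mode detection for Ω-SEs, and the multi-lncRNA
SE-overlap ranking that places the focal lncRNA among all catalogued lncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ConsensusContactPeaks
from .intervals import IntervalSet, count_overlaps, intersect_keep, overlaps_any
from .se_atlas import ConsensusSE, _as_interval_set

logger = logging.getLogger(__name__)

HISTONE_MARKS = (
    "H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "H3K36me3", "H3K9me3", "H4K20me1",
)
SIGNS = ("+", "-")


def validate_correlation_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Check the mark vocabulary, sign values and sign/rho consistency."""
    bad_mark = set(peaks["mark"]) - set(HISTONE_MARKS)
    if bad_mark:
        raise ValueError(f"unknown histone mark(s) {sorted(bad_mark)}")
    bad_sign = set(peaks["sign"]) - set(SIGNS)
    if bad_sign:
        raise ValueError(f"correlation sign must be '+' or '-', got {sorted(bad_sign)}")
    if "rho" in peaks.columns:
        rho = peaks["rho"].astype(float)
        with_rho = rho.notna()
        expected = np.where(peaks.loc[with_rho, "sign"] == "+", 1.0, -1.0)
        if (np.sign(rho[with_rho]) * expected < 0).any():
            raise ValueError("correlation sign inconsistent with rho sign")
        if (rho[with_rho].abs() > 1).any():
            raise ValueError("correlation rho outside [-1, 1]")
    return peaks


def confirm_peaks(
    corr_peaks: pd.DataFrame,
    contacts: ConsensusContactPeaks,
) -> pd.DataFrame:
    """Correlation peaks of one focal lncRNA that overlap >=1 contact peak.

    Report-once semantics: coordinates and annotations pass through unchanged.
    Rejects tables containing more than one lncRNA id as a guard against
    accidentally unfiltered input.
    """
    ids = corr_peaks["lncrna_id"].unique()
    if len(ids) > 1:
        raise ValueError(
            f"confirm_peaks expects a single focal lncRNA, got {len(ids)} ids: "
            f"{sorted(ids)[:5]}..."
        )
    ivs = IntervalSet(corr_peaks)
    return intersect_keep(ivs, contacts.peaks).df


def classify_ses(
    ses: list[ConsensusSE],
    confirmed: pd.DataFrame,
) -> list[ConsensusSE]:
    """Assign Ψ/Ω labels and mark profiles to cancer-specific SEs in place.

    An SE is Ψ iff >=1 confirmed peak overlaps it by >=1 bp.  The mark
    profile lists the distinct (mark, sign) pairs among its overlapping
    confirmed peaks — one "mark instance" per distinct pair, so a handful of
    Ψ-SEs can carry more instances than there are SEs.
    """
    se_set = _as_interval_set(ses)
    conf = IntervalSet(confirmed) if len(confirmed) else IntervalSet()
    for k, se in enumerate(ses):
        if len(conf) == 0:
            se.psi_label = "omega"
            se.mark_profile = []
            continue
        row = se_set.df.iloc[[k]]
        inside = intersect_keep(conf, IntervalSet(row)).df
        if len(inside):
            se.psi_label = "psi"
            pairs = sorted(set(zip(inside["mark"], inside["sign"])))
            se.mark_profile = pairs
        else:
            se.psi_label = "omega"
            se.mark_profile = []
    return ses


def psi_summary(ses: list[ConsensusSE]) -> dict:
    from .pipeline import percentage  # local import to avoid a cycle

    n = len(ses)
    n_psi = sum(1 for s in ses if s.psi_label == "psi")
    n_omega = n - n_psi
    n_instances = sum(len(s.mark_profile) for s in ses)
    n_compound = sum(1 for s in ses if len(s.mark_profile) >= 2)
    return {
        "n_ses": n,
        "n_psi": n_psi,
        "n_omega": n_omega,
        "pct_psi": percentage(n_psi, n) if n else None,
        "pct_omega": percentage(n_omega, n) if n else None,
        "n_mark_instances": n_instances,
        "n_compound": n_compound,
    }


def contact_density(ses: list[ConsensusSE], contacts: ConsensusContactPeaks) -> np.ndarray:
    """Contact peaks overlapping each SE (a peak spanning two SEs counts in both)."""
    if not ses:
        return np.zeros(0, dtype=np.int64)
    counts = count_overlaps(_as_interval_set(ses), contacts.peaks)
    for se, c in zip(ses, counts):
        se.contact_count = int(c)
    return counts


def tss_window(genes: pd.DataFrame, pad: int) -> pd.DataFrame:
    """Promoter windows [TSS-pad, TSS+pad) from a gene table with strand.

    TSS is the annotation start for '+' genes and the last base (end-1) for
    '-' genes; unknown strand falls back to the start with a warning.
    """
    g = genes.copy()
    unknown = ~g["strand"].isin(["+", "-"])
    if unknown.any():
        logger.warning(
            "%d gene(s) with unknown strand; using the start coordinate as TSS",
            int(unknown.sum()),
        )
    tss = np.where(g["strand"] == "-", g["end"].to_numpy() - 1, g["start"].to_numpy())
    g["tss"] = tss
    g["start"] = np.maximum(0, tss - pad)
    g["end"] = tss + pad
    return g


def tss_mode(
    omega_ses: list[ConsensusSE],
    confirmed: pd.DataFrame,
    genes: pd.DataFrame,
    targets: pd.DataFrame,
    promoter_pad: int = 2000,
) -> pd.DataFrame:
    """Ω-SEs whose body lacks confirmed marks but whose target promoter has one.

    ``targets`` is the association table (se_id, gene_id, ...) from
    :mod:`lncse.targets`.  Returns one row per (SE, gene, mark, sign).
    """
    if not len(confirmed) or not len(targets):
        return pd.DataFrame(columns=["se_id", "gene_id", "mark", "sign"])
    omega_ids = {s.se_id for s in omega_ses if s.psi_label == "omega"}
    sub = targets[targets["se_id"].isin(omega_ids)]
    gene_idx = genes.set_index("gene_id")
    conf = IntervalSet(confirmed)
    rows = []
    for r in sub.itertuples(index=False):
        if r.gene_id not in gene_idx.index:
            continue
        g = gene_idx.loc[r.gene_id]
        win = tss_window(
            pd.DataFrame([{**g.to_dict(), "gene_id": r.gene_id}]), promoter_pad
        )
        hits = intersect_keep(conf, IntervalSet(win)).df
        for h in hits.itertuples(index=False):
            rows.append({"se_id": r.se_id, "gene_id": r.gene_id, "mark": h.mark, "sign": h.sign})
    out = pd.DataFrame(rows, columns=["se_id", "gene_id", "mark", "sign"])
    return out.drop_duplicates().reset_index(drop=True)


def se_tss_concordance(
    psi_ses: list[ConsensusSE],
    confirmed: pd.DataFrame,
    genes: pd.DataFrame,
    targets: pd.DataFrame,
    promoter_pad: int = 2000,
) -> list[str]:
    """Ψ-SE ids whose body (by definition) and >=1 target promoter are both marked."""
    psi_ids = [s.se_id for s in psi_ses if s.psi_label == "psi"]
    if not psi_ids or not len(confirmed) or not len(targets):
        return []
    hits = tss_mode(
        # reuse the promoter-scan machinery on the Ψ set by faking omega labels
        [ _relabel(s) for s in psi_ses if s.psi_label == "psi" ],
        confirmed, genes, targets, promoter_pad,
    )
    return sorted(set(hits["se_id"]))


def _relabel(se: ConsensusSE) -> ConsensusSE:
    import copy

    c = copy.copy(se)
    c.psi_label = "omega"
    return c


def lncrna_se_ranking(
    all_corr_peaks: pd.DataFrame,
    ses: list[ConsensusSE],
    focal: str,
    tie_rule: str = "le",
) -> dict:
    """Rank the focal lncRNA by how many SEs harbour >=1 of its correlation peaks.

    Counts use SE-level presence (duplicated peak rows cannot inflate them).
    The percentile is computed among lncRNAs with count >= 1 as
    ``100 * #(count <= focal) / #(count >= 1)`` (``tie_rule="lt"`` switches to
    a strict comparison).
    """
    if focal not in set(all_corr_peaks["lncrna_id"]):
        raise ValueError(f"focal lncRNA {focal!r} absent from the correlation peak table")
    se_set = _as_interval_set(ses)
    counts: dict[str, int] = {}
    for lnc, sub in all_corr_peaks.groupby("lncrna_id", sort=True):
        hit = overlaps_any(se_set, IntervalSet(sub.reset_index(drop=True)))
        counts[str(lnc)] = int(hit.sum())
    focal_count = counts[focal]
    nonzero = np.array([c for c in counts.values() if c >= 1])
    if focal_count >= 1 and len(nonzero):
        if tie_rule == "le":
            pct = 100.0 * float((nonzero <= focal_count).mean())
        elif tie_rule == "lt":
            pct = 100.0 * float((nonzero < focal_count).mean())
        else:
            raise ValueError(f"unknown tie rule {tie_rule!r}")
    else:
        pct = 0.0
    n_ge = int((nonzero >= focal_count).sum()) - 1 if focal_count >= 1 else None
    return {
        "counts": counts,
        "focal": focal,
        "focal_count": focal_count,
        "n_lncrnas": len(counts),
        "n_with_overlap": int(len(nonzero)),
        "percentile": pct,
        "n_comparable_or_greater": n_ge,
    }
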