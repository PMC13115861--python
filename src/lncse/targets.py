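"""SE target-gene assignment, lead genes, Welch DE, and triple validation.

A gene is a target of a super-enhancer when it either overlaps the SE or its
annotated start coordinate lies within ``window`` bp (default 100 kb,
inclusive) of the nearer SE boundary, and the gene is expressed in the
analysis condition (mean TPM strictly greater than ``tpm_min``, default 1).
Per SE, the *lead* gene is the target with the smallest adjusted differential
expression p-value (cell line vs. normal reference); it may be
non-significant and is flagged as such.

Triple validation asks for concordant evidence in three independent layers:
up in the cell line (padj < alpha and log2FC > 0), up in the tumor cohort
(p < alpha and log2FC > 0), and positive co-expression with the focal lncRNA
across tumors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand", "biotype"]


@dataclass
class TargetParams:
    window: int = 100_000
    tpm_min: float = 1.0
    alpha: float = 0.05
    coexpr_p_max: float | None = 0.05  # None: sign-only co-expression criterion


def assign_targets(
    ses: list,
    genes: pd.DataFrame,
    tpm_column: str,
    window: int = 100_000,
    tpm_min: float = 1.0,
    biotypes: list[str] | None = None,
) -> pd.DataFrame:
    """One row per (SE, expressed gene) association within the window.

    ``distance`` is 0 for overlapping genes, else
    ``min(|gene_start - se_end|, |se_start - gene_start|)`` in half-open
    coordinates.  The expression filter is strict (``TPM > tpm_min``), so a
    gene at exactly the threshold is excluded.
    """
    g = genes
    if biotypes is not None:
        g = g[g["biotype"].isin(biotypes)]
    rows = []
    for se in ses:
        iv = se.interval
        sub = g[g["chrom"] == iv.chrom]
        for r in sub.itertuples(index=False):
            overlap = r.start < iv.end and iv.start < r.end
            if overlap:
                dist = 0
            else:
                dist = min(abs(r.start - iv.end), abs(iv.start - r.start))
            if not overlap and dist > window:
                continue
            expressed = getattr(r, tpm_column) > tpm_min
            if not expressed:
                continue
            rows.append(
                {
                    "se_id": se.se_id,
                    "gene_id": r.gene_id,
                    "symbol": r.symbol,
                    "distance": dist,
                    "tpm": getattr(r, tpm_column),
                }
            )
    return pd.DataFrame(rows, columns=["se_id", "gene_id", "symbol", "distance", "tpm"])


def lead_gene(
    assocs: pd.DataFrame,
    de: pd.DataFrame,
    alpha: float = 0.05,
    all_se_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One lead gene per SE with targets: the smallest-padj target.

    Missing DE entries are treated as padj = 1 (with a warning).  Ties are
    broken by larger |log2FC|, then lexicographic gene id.  SEs with no
    targets are reported with a null lead so summary tables can show them.
    """
    de_idx = de.set_index("gene_id")
    rows = []
    missing: list[str] = []
    for se_id, sub in assocs.groupby("se_id", sort=True):
        cand = []
        for r in sub.itertuples(index=False):
            if r.gene_id in de_idx.index:
                padj = float(de_idx.loc[r.gene_id, "padj"])
                lfc = float(de_idx.loc[r.gene_id, "log2FC"])
            else:
                missing.append(r.gene_id)
                padj, lfc = 1.0, 0.0
            cand.append((padj, -abs(lfc), str(r.gene_id), lfc))
        padj, _negabs, gene_id, lfc = sorted(cand)[0]
        rows.append(
            {
                "se_id": se_id,
                "lead_gene": gene_id,
                "log2FC": lfc,
                "padj": padj,
                "significant": bool(padj < alpha),
                "n_targets": len(sub),
            }
        )
    if missing:
        logger.warning("no DE record for %d gene(s) (padj treated as 1): %s",
                       len(missing), sorted(set(missing))[:5])
    lead = pd.DataFrame(rows, columns=[
        "se_id", "lead_gene", "log2FC", "padj", "significant", "n_targets"])
    if all_se_ids is not None:
        have = set(lead["se_id"])
        extra = [
            {"se_id": s, "lead_gene": None, "log2FC": np.nan, "padj": np.nan,
             "significant": False, "n_targets": 0}
            for s in all_se_ids if s not in have
        ]
        if extra:
            lead = pd.concat([lead, pd.DataFrame(extra)], ignore_index=True)
    return lead


def welch_de(
    expr: pd.DataFrame,
    groups: pd.Series,
    group_a: str = "tumor",
    group_b: str = "normal",
) -> pd.DataFrame:
    """Per-gene Welch's t-test on a log2(TPM+1) genes x samples matrix.

    log2FC is mean(group_a) - mean(group_b) on the log scale.  Degenerate
    genes (zero variance in both groups, equal means) get t = 0, p = 1.
    """
    a = expr.loc[:, groups[expr.columns] == group_a].to_numpy(dtype=float)
    b = expr.loc[:, groups[expr.columns] == group_b].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("Welch's t-test needs >=2 samples per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    na, nb = a.shape[1], b.shape[1]
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, na + nb - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (ma == mb), 1.0, p)
    return pd.DataFrame(
        {"gene_id": expr.index, "log2FC": ma - mb, "t": t, "df": df, "p": p}
    ).reset_index(drop=True)


def triple_validate(
    assocs: pd.DataFrame,
    de_cellline: pd.DataFrame,
    de_cohort: pd.DataFrame,
    coexpr: pd.DataFrame,
    params: TargetParams | None = None,
) -> pd.DataFrame:
    """Flag each association on the three evidence layers and their conjunction.

    Layer 1 (cell line): padj < alpha and log2FC > 0.
    Layer 2 (cohort DE): p < alpha and log2FC > 0.
    Layer 3 (co-expression): rho > 0, and p < ``coexpr_p_max`` when that
    threshold is set (``None`` reduces the layer to the sign of rho).
    A gene missing from a table fails that layer (logged).
    """
    params = params or TargetParams()
    d1 = de_cellline.set_index("gene_id")
    d2 = de_cohort.set_index("gene_id")
    d3 = coexpr.set_index("gene_id")
    out = assocs.copy()
    flags1, flags2, flags3 = [], [], []
    unmapped: list[str] = []
    for gid in out["gene_id"]:
        if gid in d1.index:
            r = d1.loc[gid]
            flags1.append(bool(r["padj"] < params.alpha and r["log2FC"] > 0))
        else:
            unmapped.append(str(gid))
            flags1.append(False)
        if gid in d2.index:
            r = d2.loc[gid]
            flags2.append(bool(r["p"] < params.alpha and r["log2FC"] > 0))
        else:
            unmapped.append(str(gid))
            flags2.append(False)
        if gid in d3.index and np.isfinite(d3.loc[gid, "rho"]):
            r = d3.loc[gid]
            ok = r["rho"] > 0
            if params.coexpr_p_max is not None:
                ok = ok and r["p"] < params.coexpr_p_max
            flags3.append(bool(ok))
        else:
            unmapped.append(str(gid))
            flags3.append(False)
    if unmapped:
        logger.warning("%d gene/table lookups failed during triple validation: %s",
                       len(unmapped), sorted(set(unmapped))[:5])
    out["cellline_up"] = flags1
    out["cohort_up"] = flags2
    out["coexpr_pos"] = flags3
    out["triple_validated"] = out["cellline_up"] & out["cohort_up"] & out["coexpr_pos"]
    return out
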