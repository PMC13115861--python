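"""Tumor-cohort co-expression of a focal lncRNA with SE target genes.

Spearman correlations (exact small-sample p, t-approximation otherwise),
Benjamini-Hochberg adjustment, a random-gene-set permutation null for the
set-level co-expression metrics, and a purity-corrected partial Spearman:
bulk tumor expression mixes tumor and non-tumor cells, so two genes can
co-vary simply because both track tumor purity.  The partial coefficient
rank-transforms both expression vectors and the purity estimates, regresses
each ranked expression vector on ranked purity, and correlates the
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_SPEARMAN_N = 10  # below this, p by exhaustive rank-permutation


@dataclass
class ExpressionCohort:
    """log2(TPM+1) genes x samples matrix with tumor/normal labels and purity."""

    expr: pd.DataFrame
    sample_class: pd.Series  # index: sample id; values in {tumor, normal}
    purity: pd.Series  # index: sample id; NaN where unavailable

    def __post_init__(self) -> None:
        if not self.expr.columns.equals(self.sample_class.index):
            self.sample_class = self.sample_class.reindex(self.expr.columns)
        self.purity = self.purity.reindex(self.expr.columns)
        if self.sample_class.isna().any():
            missing = self.expr.columns[self.sample_class.isna()]
            raise ValueError(f"samples without class labels: {list(missing)[:5]}")

    def tumor_matrix(self, require_purity: bool = False) -> pd.DataFrame:
        cols = self.expr.columns[(self.sample_class == "tumor").to_numpy()]
        if require_purity:
            cols = [c for c in cols if np.isfinite(self.purity[c])]
        return self.expr[list(cols)]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with mid-rank ties; exact p below n=10, else t-approximation.

    Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n < EXACT_SPEARMAN_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _t_approx_p(rho, n)
    return rho, p


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p over all n! pairings of the observed rank vectors."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    perms = np.array(list(permutations(range(n))))
    rhos = (ry_c[perms] * rx_c[None, :]).sum(axis=1) / denom
    k = int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return k / len(rhos)


def partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Purity-corrected rank partial correlation.

    Ranks x, y, z (mid-rank ties), OLS-regresses rank(x) and rank(y) each on
    rank(z), and returns the Pearson correlation of the residual vectors.
    Constant z degenerates to ordinary Spearman rho (slope 0).  Samples with
    missing values in any of the three vectors are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    if x.size < 3:
        raise ValueError("partial spearman needs >= 3 complete triples")
    rx, ry, rz = stats.rankdata(x), stats.rankdata(y), stats.rankdata(z)
    rzc = rz - rz.mean()
    denom = float((rzc**2).sum())

    def resid(r: np.ndarray) -> np.ndarray:
        rc = r - r.mean()
        if denom == 0:
            return rc
        beta = float((rc * rzc).sum()) / denom
        return rc - beta * rzc

    ex, ey = resid(rx), resid(ry)
    if np.ptp(ex) == 0 or np.ptp(ey) == 0:
        return float("nan")
    return float(np.corrcoef(ex, ey)[0, 1])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorised machinery for the random-gene-set null
# ---------------------------------------------------------------------------

def _rank_rows(m: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, m)


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    c = m - m.mean(axis=1, keepdims=True)
    sd = c.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = c / sd
    z[~np.isfinite(z)] = 0.0
    return z


def spearman_profile(
    expr: pd.DataFrame,
    focal: str,
    purity: pd.Series | None = None,
) -> pd.DataFrame:
    """Spearman rho (and t-approx p) of every gene against the focal gene.

    With ``purity`` given, all correlations are purity-corrected partial
    Spearman coefficients computed on the samples with finite purity.
    Constant genes yield NaN rho and p.
    """
    if focal not in expr.index:
        raise KeyError(f"focal gene {focal!r} absent from the expression matrix")
    mat = expr.to_numpy(dtype=float)
    if purity is not None:
        z = purity.reindex(expr.columns).to_numpy(dtype=float)
        keep = np.isfinite(z)
        mat = mat[:, keep]
        z = z[keep]
    n = mat.shape[1]
    ranked = _rank_rows(mat)
    if purity is not None:
        rz = stats.rankdata(z)
        rzc = rz - rz.mean()
        denom = float((rzc**2).sum())
        if denom > 0:
            centred = ranked - ranked.mean(axis=1, keepdims=True)
            betas = centred @ rzc / denom
            ranked = centred - betas[:, None] * rzc[None, :]
    zmat = _standardize_rows(ranked)
    constant = np.ptp(mat, axis=1) == 0
    fidx = expr.index.get_loc(focal)
    rho = zmat @ zmat[fidx] / n
    rho[fidx] = 1.0
    p = np.array([_t_approx_p(r, n) if np.isfinite(r) else np.nan for r in rho])
    rho = np.where(constant, np.nan, rho)
    p = np.where(constant, np.nan, p)
    out = pd.DataFrame({"gene_id": expr.index, "rho": rho, "p": p, "n": n})
    return out.reset_index(drop=True)


def correlation_table(
    cohort: ExpressionCohort,
    focal: str,
    genes: list[str],
) -> pd.DataFrame:
    """Per-gene CorrelationResult table: rho, p, BH fdr, partial rho, n."""
    tumor = cohort.tumor_matrix()
    prof = spearman_profile(tumor, focal).set_index("gene_id")
    tumor_p = cohort.tumor_matrix(require_purity=True)
    partial = spearman_profile(tumor_p, focal, purity=cohort.purity).set_index("gene_id")
    rows = []
    for g in genes:
        if g not in prof.index:
            rows.append({"gene_id": g, "rho": np.nan, "p": np.nan,
                         "partial_rho": np.nan, "n": 0, "n_partial": 0})
            continue
        rows.append(
            {
                "gene_id": g,
                "rho": prof.loc[g, "rho"],
                "p": prof.loc[g, "p"],
                "partial_rho": partial.loc[g, "rho"] if g in partial.index else np.nan,
                "n": int(prof.loc[g, "n"]),
                "n_partial": int(partial.loc[g, "n"]) if g in partial.index else 0,
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "rho", "p", "partial_rho",
                                      "n", "n_partial"])
    finite = out["p"].notna()
    fdr = np.full(len(out), np.nan)
    if finite.any():
        fdr[finite.to_numpy()] = bh_adjust(out.loc[finite, "p"].to_numpy())
    out["fdr"] = fdr
    return out


def _set_metrics(rho: np.ndarray, p: np.ndarray, alpha: float) -> tuple[int, float, float]:
    ok = np.isfinite(rho)
    n_sig_pos = int(np.sum(ok & (rho > 0) & (p < alpha)))
    med = float(np.nanmedian(rho)) if ok.any() else float("nan")
    mean = float(np.nanmean(rho)) if ok.any() else float("nan")
    return n_sig_pos, med, mean


@dataclass
class GeneSetNullResult:
    observed: dict
    null: dict  # metric -> np.ndarray of draws
    p: dict
    n_sets: int
    seed: int
    set_size: int
    purity_corrected: bool

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": {k: float(np.mean(v)) for k, v in self.null.items()},
            "null_sd": {k: float(np.std(v, ddof=1)) for k, v in self.null.items()},
            "empirical_p": self.p,
            "n_sets": self.n_sets,
            "set_size": self.set_size,
            "seed": self.seed,
            "purity_corrected": self.purity_corrected,
        }


def expressed_background(
    cohort: ExpressionCohort,
    min_nonzero_fraction: float = 0.2,
) -> list[str]:
    """Genes with a nonzero value in at least this fraction of tumor samples."""
    tumor = cohort.tumor_matrix()
    frac = (tumor.to_numpy() > 0).mean(axis=1)
    return list(tumor.index[frac >= min_nonzero_fraction])


def random_geneset_null(
    cohort: ExpressionCohort,
    focal: str,
    target_genes: list[str],
    background: list[str] | None = None,
    n_sets: int = 10_000,
    seed: int = 0,
    purity_correct: bool = False,
    alpha: float = 0.05,
) -> GeneSetNullResult:
    """Set-level co-expression metrics against equal-size random gene sets.

    Metrics: number of significant positive correlations (rho > 0, unadjusted
    p < alpha), median rho, mean rho.  Draws are without replacement from the
    expressed background (focal excluded); empirical p uses the add-one
    convention per metric.
    """
    from .permutation import empirical_p

    if background is None:
        background = expressed_background(cohort)
    # sorted+deduplicated: draws depend only on the set, not input order
    background = sorted(set(background) - {focal})
    targets = [g for g in target_genes if g != focal]
    k = len(targets)
    if k == 0:
        raise ValueError("empty target gene set")
    if len(background) < k:
        raise ValueError(
            f"background ({len(background)}) smaller than the target set ({k})"
        )
    tumor = cohort.tumor_matrix(require_purity=purity_correct)
    prof = spearman_profile(
        tumor, focal, purity=cohort.purity if purity_correct else None
    ).set_index("gene_id")
    rho_all = prof["rho"]
    p_all = prof["p"]
    obs = _set_metrics(rho_all.reindex(targets).to_numpy(),
                       p_all.reindex(targets).to_numpy(), alpha)
    rng = np.random.default_rng(seed)
    bg_rho = rho_all.reindex(background).to_numpy()
    bg_p = p_all.reindex(background).to_numpy()
    draws = {m: np.empty(n_sets) for m in ("n_sig_pos", "median_rho", "mean_rho")}
    for i in range(n_sets):
        idx = rng.choice(len(background), size=k, replace=False)
        n_sig, med, mean = _set_metrics(bg_rho[idx], bg_p[idx], alpha)
        draws["n_sig_pos"][i] = n_sig
        draws["median_rho"][i] = med
        draws["mean_rho"][i] = mean
    observed = {"n_sig_pos": obs[0], "median_rho": obs[1], "mean_rho": obs[2]}
    pvals = {m: empirical_p(observed[m], draws[m]) for m in draws}
    return GeneSetNullResult(
        observed=observed,
        null=draws,
        p=pvals,
        n_sets=n_sets,
        seed=seed,
        set_size=k,
        purity_corrected=purity_correct,
    )
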