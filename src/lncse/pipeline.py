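"""End-to-end orchestration: contacts -> SE atlas -> Ψ/Ω -> stats -> targets -> co-expression.

`run_all` executes the stages in order, writing each stage's outputs before
the next begins, and assembles a RunReport whose every number is
recomputable from the stage output files.  Percentages are half-up rounded
at one decimal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as lio
from .contacts import FractionPeakSet, consensus_from_fractions
from .coexpression import ExpressionCohort, correlation_table, random_geneset_null
from .intervals import IntervalSet, subtract_filter
from .permutation import (
    mann_whitney_one_sided,
    permute_overlap_enrichment,
    permute_triple_enrichment,
)
from .psi import (
    classify_ses,
    confirm_peaks,
    contact_density,
    lncrna_se_ranking,
    psi_summary,
    se_tss_concordance,
    tss_mode,
    validate_correlation_peaks,
)
from .se_atlas import (
    SESample,
    _as_interval_set,
    build_condition_consensus,
    classify_specificity,
    consensus_table,
    specificity_summary,
)
from .targets import TargetParams, assign_targets, lead_gene, triple_validate, welch_de

logger = logging.getLogger(__name__)


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up at ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(100 * numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the pipeline's canonical operating point: 12.5 kb
    intra-sample SE stitching, 250 bp fraction-reconciliation padding, >=2-of-3
    replicate support, 3-of-3 / 5-of-6 SE sample support, 100 kb target
    window with TPM > 1, 1000 shuffle iterations, 10,000 random gene sets.
    """

    # inputs
    chrom_sizes: str = ""
    blacklist: str | None = None
    contact_manifest: str = ""
    se_manifest: str = ""
    correlation_peaks: str = ""
    genes: str = ""
    de_cellline: str = ""
    cohort_expr: str = ""
    cohort_samples: str = ""
    focal_lncrna: str = "LNC_FOCAL"
    # thresholds
    intra_gap: int = 12_500
    cross_gap: int = 0
    pad: int = 250
    reconcile_mode: str = "union"
    contact_min_support: int = 2
    cancer_min_support: int = 3
    normal_min_support: int = 5
    min_overlap_bp: int = 1
    window: int = 100_000
    tpm_min: float = 1.0
    promoter_pad: int = 2_000
    alpha: float = 0.05
    coexpr_p_max: float | None = 0.05
    n_iter: int = 1_000
    n_sets: int = 10_000
    shuffle_exclude_blacklist: bool = False
    seed: int = 0
    out_dir: str = "run_out"

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, out_dir: str | Path,
                    seed: int = 0, **overrides) -> "RunConfig":
        """Conventional paths of a synthetic input bundle directory."""
        b = Path(bundle_dir)
        return cls(
            chrom_sizes=str(b / "chrom.sizes"),
            blacklist=str(b / "blacklist.bed"),
            contact_manifest=str(b / "contacts" / "manifest.tsv"),
            se_manifest=str(b / "se" / "manifest.tsv"),
            correlation_peaks=str(b / "correlation_peaks.tsv"),
            genes=str(b / "genes.tsv"),
            de_cellline=str(b / "expression" / "de_cellline.tsv"),
            cohort_expr=str(b / "cohort" / "expr.tsv"),
            cohort_samples=str(b / "cohort" / "samples.tsv"),
            seed=seed,
            out_dir=str(out_dir),
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_contacts(cfg: RunConfig, out: Path):
    sizes = lio.read_chrom_sizes(cfg.chrom_sizes)
    manifest = lio.read_manifest(cfg.contact_manifest, ["replicate", "fraction", "path"])
    base = Path(cfg.contact_manifest).parent
    blacklist = lio.read_bed(cfg.blacklist) if cfg.blacklist else None
    fraction_sets = []
    for r in manifest.itertuples(index=False):
        if r.fraction == "input":
            continue  # control used at peak-calling time, upstream of this stage
        peaks = lio.read_bed(base / r.path)
        if blacklist is not None:
            peaks = subtract_filter(peaks, blacklist)
        fraction_sets.append(FractionPeakSet(str(r.replicate), str(r.fraction), peaks))
    consensus = consensus_from_fractions(
        fraction_sets, sizes, pad=cfg.pad,
        min_support=cfg.contact_min_support, mode=cfg.reconcile_mode,
    )
    lio.write_bed(consensus.peaks, out / "consensus_contacts.bed")
    lio.write_table(consensus.support, out / "consensus_contacts_support.tsv")
    logger.info("contacts: %d consensus peaks", len(consensus))
    return sizes, blacklist, consensus


def stage_se_atlas(cfg: RunConfig, out: Path):
    manifest = lio.read_manifest(cfg.se_manifest, ["sample", "condition", "path"])
    base = Path(cfg.se_manifest).parent
    samples = [
        SESample(str(r.sample), str(r.condition), lio.read_bed(base / r.path))
        for r in manifest.itertuples(index=False)
    ]
    cancer_s = [s for s in samples if s.condition == "cancer"]
    normal_s = [s for s in samples if s.condition == "normal"]
    cancer = build_condition_consensus(
        cancer_s, cfg.cancer_min_support, intra_gap=cfg.intra_gap,
        cross_gap=cfg.cross_gap, id_prefix="se")
    normal = build_condition_consensus(
        normal_s, cfg.normal_min_support, intra_gap=cfg.intra_gap,
        cross_gap=cfg.cross_gap, id_prefix="nse")
    cancer, normal = classify_specificity(cancer, normal, cfg.min_overlap_bp)
    summary = specificity_summary(cancer, normal)
    lio.write_table(consensus_table(cancer + normal), out / "consensus_ses.tsv")
    logger.info("se atlas: %s", summary)
    return cancer, normal, summary


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": cfg.to_dict()}

    sizes, blacklist, contacts = stage_contacts(cfg, out)
    report["contacts"] = {
        "n_consensus_peaks": len(contacts),
        "support_distribution": contacts.support["n_replicates"].value_counts().to_dict()
        if len(contacts.support) else {},
    }

    cancer, normal, se_summary = stage_se_atlas(cfg, out)
    report["se_atlas"] = se_summary
    cancer_specific = [s for s in cancer if s.specificity == "cancer-specific"]

    # stage: confirmation and Psi/Omega classification
    corr = validate_correlation_peaks(lio.read_correlation_peaks(cfg.correlation_peaks))
    focal_corr = corr[corr["lncrna_id"] == cfg.focal_lncrna].reset_index(drop=True)
    confirmed = confirm_peaks(focal_corr, contacts)
    lio.write_table(confirmed, out / "confirmed_peaks.tsv")
    classify_ses(cancer_specific, confirmed)
    densities = contact_density(cancer_specific, contacts)
    lio.write_table(consensus_table(cancer_specific), out / "classified_ses.tsv")
    summary = psi_summary(cancer_specific)
    summary["n_focal_corr_peaks"] = int(len(focal_corr))
    summary["n_confirmed_peaks"] = int(len(confirmed))
    if len(focal_corr):
        summary["pct_confirmed"] = percentage(len(confirmed), len(focal_corr))
    report["classification"] = summary

    # contact-density contrast: Psi vs other contacted SEs
    psi_counts = [int(c) for s, c in zip(cancer_specific, densities) if s.psi_label == "psi"]
    omega_counts = [int(c) for s, c in zip(cancer_specific, densities)
                    if s.psi_label == "omega" and c > 0]
    if psi_counts and omega_counts:
        u, p_u = mann_whitney_one_sided(np.array(psi_counts), np.array(omega_counts))
        report["contact_density"] = {
            "psi_median": float(np.median(psi_counts)),
            "contacted_omega_median": float(np.median(omega_counts)),
            "U": u, "p": round(p_u, 4),
        }

    # stage: lncRNA ranking
    ranking = lncrna_se_ranking(corr, cancer_specific, cfg.focal_lncrna)
    lio.write_table(
        pd.DataFrame(sorted(ranking["counts"].items()), columns=["lncrna_id", "n_ses"]),
        out / "lncrna_ranking.tsv")
    report["lncrna_ranking"] = {k: v for k, v in ranking.items() if k != "counts"}

    # stage: permutation tests
    se_set = _as_interval_set(cancer_specific)
    exclude = blacklist if cfg.shuffle_exclude_blacklist else None
    overlap_perm = permute_overlap_enrichment(
        se_set, contacts.peaks, sizes, n_iter=cfg.n_iter, seed=cfg.seed, exclude=exclude)
    triple_perm = permute_triple_enrichment(
        cancer_specific, focal_corr, contacts, sizes,
        n_iter=cfg.n_iter, seed=cfg.seed + 1, exclude=exclude)
    report["permutation"] = {
        "se_contact_overlap": overlap_perm.summary(),
        "triple_intersection": triple_perm.summary(),
    }

    # stage: target genes
    genes = lio.read_table(cfg.genes)
    assocs = assign_targets(cancer_specific, genes, "tpm_cancer",
                            window=cfg.window, tpm_min=cfg.tpm_min)
    lio.write_table(assocs, out / "associations.tsv")
    de_cl = lio.read_table(cfg.de_cellline)
    psi_ids = [s.se_id for s in cancer_specific if s.psi_label == "psi"]
    psi_assocs = assocs[assocs["se_id"].isin(psi_ids)].reset_index(drop=True)
    leads = lead_gene(psi_assocs, de_cl, alpha=cfg.alpha, all_se_ids=psi_ids)
    lio.write_table(leads, out / "lead_genes.tsv")

    expr = lio.read_expression_matrix(cfg.cohort_expr)
    meta = lio.read_table(cfg.cohort_samples).set_index("sample")
    cohort = ExpressionCohort(expr, meta["class"], meta["purity"])
    de_cohort = welch_de(expr, meta["class"])
    lio.write_table(de_cohort, out / "de_cohort.tsv")

    target_genes = sorted(set(psi_assocs["gene_id"]))
    coexpr = correlation_table(cohort, cfg.focal_lncrna, target_genes)
    lio.write_table(coexpr, out / "coexpression.tsv")
    params = TargetParams(window=cfg.window, tpm_min=cfg.tpm_min, alpha=cfg.alpha,
                          coexpr_p_max=cfg.coexpr_p_max)
    validated = triple_validate(psi_assocs, de_cl, de_cohort, coexpr, params)
    lio.write_table(validated, out / "triple_validation.tsv")
    triple_genes = sorted(set(validated.loc[validated["triple_validated"], "gene_id"]))
    report["targets"] = {
        "n_associations_cancer_specific": int(len(assocs)),
        "n_psi_associations": int(len(psi_assocs)),
        "n_psi_with_targets": int(psi_assocs["se_id"].nunique()),
        "n_leads_significant": int(leads["significant"].sum()),
        "n_triple_validated": len(triple_genes),
        "triple_validated_genes": triple_genes,
    }

    # stage: promoter (TSS) mode and SE-TSS concordance
    omega = [s for s in cancer_specific if s.psi_label == "omega"]
    psi = [s for s in cancer_specific if s.psi_label == "psi"]
    tss_hits = tss_mode(omega, confirmed, genes, assocs, cfg.promoter_pad)
    lio.write_table(tss_hits, out / "tss_mode.tsv")
    concordant = se_tss_concordance(psi, confirmed, genes, assocs, cfg.promoter_pad)
    report["tss"] = {
        "n_omega_tss_ses": int(tss_hits["se_id"].nunique()) if len(tss_hits) else 0,
        "n_psi_concordant": len(concordant),
        "concordant_psi_ses": concordant,
    }

    # stage: co-expression null
    if target_genes:
        null_plain = random_geneset_null(
            cohort, cfg.focal_lncrna, target_genes,
            n_sets=cfg.n_sets, seed=cfg.seed + 2, purity_correct=False, alpha=cfg.alpha)
        null_purity = random_geneset_null(
            cohort, cfg.focal_lncrna, target_genes,
            n_sets=cfg.n_sets, seed=cfg.seed + 3, purity_correct=True, alpha=cfg.alpha)
        report["coexpression"] = {
            "plain": null_plain.summary(),
            "purity_corrected": null_purity.summary(),
        }

    _write_report(report, out)
    return report


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def _flatten(d: dict, prefix: str = "") -> list[tuple[str, object]]:
    rows = []
    for k, v in d.items():
        key = f"{prefix}.{k}" if prefix else str(k)
        if isinstance(v, dict):
            rows.extend(_flatten(v, key))
        else:
            rows.append((key, v))
    return rows


def _write_report(report: dict, out: Path) -> None:
    clean = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(clean, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    rows = _flatten({k: v for k, v in clean.items() if k != "config"})
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
        out / "report.tsv", sep="\t", index=False)
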