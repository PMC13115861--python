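#!/usr/bin/env python
"""Ψ-SE target genes: window assignment, lead genes, triple validation.

Genes overlapping a cancer-specific SE or starting within 100 kb of its
boundary, with mean TPM > 1, become targets; the lead gene per Ψ-SE is the
target with the lowest adjusted DE p.  Triple validation requires cell-line
upregulation, cohort upregulation (genome-wide Welch on log2(TPM+1)), and
significant positive co-expression with the focal lncRNA.  Also reports the
promoter (TSS) mode of Ω-SEs and Ψ-SE body/TSS concordance.
"""

from pathlib import Path

import pandas as pd

import lncse.io as lio
from lncse.coexpression import ExpressionCohort, correlation_table
from lncse.psi import se_tss_concordance, tss_mode
from lncse.se_atlas import ses_from_table
from lncse.targets import TargetParams, assign_targets, lead_gene, triple_validate, welch_de

BUNDLE = Path("scratch/bundle")
OUT = Path("results/pipeline")
FOCAL = "LNC_FOCAL"


def main() -> None:
    ses_df = pd.read_csv(OUT / "classified_ses.tsv", sep="\t")
    cancer_specific = ses_from_table(ses_df)
    genes = lio.read_table(BUNDLE / "genes.tsv")
    assocs = assign_targets(cancer_specific, genes, "tpm_cancer")
    lio.write_table(assocs, OUT / "associations.tsv")

    de_cl = lio.read_table(BUNDLE / "expression" / "de_cellline.tsv")
    psi_ids = [s.se_id for s in cancer_specific if s.psi_label == "psi"]
    psi_assocs = assocs[assocs["se_id"].isin(psi_ids)].reset_index(drop=True)
    leads = lead_gene(psi_assocs, de_cl, all_se_ids=psi_ids)
    lio.write_table(leads, OUT / "lead_genes.tsv")

    expr = lio.read_expression_matrix(BUNDLE / "cohort" / "expr.tsv")
    meta = lio.read_table(BUNDLE / "cohort" / "samples.tsv").set_index("sample")
    cohort = ExpressionCohort(expr, meta["class"], meta["purity"])
    de_cohort = welch_de(expr, meta["class"])
    lio.write_table(de_cohort, OUT / "de_cohort.tsv")

    target_genes = sorted(set(psi_assocs["gene_id"]))
    coexpr = correlation_table(cohort, FOCAL, target_genes)
    lio.write_table(coexpr, OUT / "coexpression.tsv")
    validated = triple_validate(psi_assocs, de_cl, de_cohort, coexpr, TargetParams())
    lio.write_table(validated, OUT / "triple_validation.tsv")

    confirmed = lio.read_table(OUT / "confirmed_peaks.tsv")
    omega = [s for s in cancer_specific if s.psi_label == "omega"]
    psi = [s for s in cancer_specific if s.psi_label == "psi"]
    tss_hits = tss_mode(omega, confirmed, genes, assocs)
    lio.write_table(tss_hits, OUT / "tss_mode.tsv")
    concordant = se_tss_concordance(psi, confirmed, genes, assocs)

    triple_genes = sorted(validated.loc[validated["triple_validated"], "gene_id"])
    n_nolead = int(leads["lead_gene"].isna().sum())
    print(f"{len(psi_assocs)} Ψ-SE target associations across "
          f"{psi_assocs['se_id'].nunique()} of {len(psi_ids)} Ψ-SEs "
          f"({n_nolead} Ψ-SE(s) without an expressed target)")
    print(f"{len(triple_genes)} triple-validated gene(s): {', '.join(triple_genes)}")
    print(f"promoter-mode Ω-SEs: {tss_hits['se_id'].nunique() if len(tss_hits) else 0}; "
          f"Ψ-SEs with body/TSS concordance: {len(concordant)}")


if __name__ == "__main__":
    main()
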