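#!/usr/bin/env python
"""Two-stage triple intersection: confirmed peaks and Ψ/Ω labels.

Stage one keeps the focal lncRNA's correlation peaks that overlap a
consensus contact peak ("confirmed"); stage two labels each cancer-specific
SE Ψ when it contains >=1 confirmed peak, else Ω.  Also counts contact
peaks per SE and ranks the focal lncRNA among all catalogued lncRNAs by
SE overlap.
"""

from pathlib import Path

import pandas as pd

import lncse.io as lio
from lncse.contacts import ConsensusContactPeaks
from lncse.pipeline import percentage
from lncse.psi import (
    classify_ses,
    confirm_peaks,
    contact_density,
    lncrna_se_ranking,
    psi_summary,
    validate_correlation_peaks,
)
from lncse.se_atlas import consensus_table, ses_from_table

BUNDLE = Path("scratch/bundle")
OUT = Path("results/pipeline")
FOCAL = "LNC_FOCAL"


def main() -> None:
    contacts = ConsensusContactPeaks(lio.read_bed(OUT / "consensus_contacts.bed"))
    ses_df = pd.read_csv(OUT / "consensus_ses.tsv", sep="\t")
    cancer_specific = ses_from_table(ses_df[ses_df["specificity"] == "cancer-specific"])
    corr = validate_correlation_peaks(
        lio.read_correlation_peaks(BUNDLE / "correlation_peaks.tsv"))
    focal = corr[corr["lncrna_id"] == FOCAL].reset_index(drop=True)

    confirmed = confirm_peaks(focal, contacts)
    lio.write_table(confirmed, OUT / "confirmed_peaks.tsv")
    classify_ses(cancer_specific, confirmed)
    contact_density(cancer_specific, contacts)
    lio.write_table(consensus_table(cancer_specific), OUT / "classified_ses.tsv")

    s = psi_summary(cancer_specific)
    print(f"{len(confirmed)} of {len(focal)} correlation peaks confirmed "
          f"({percentage(len(confirmed), len(focal))}%)")
    print(f"{s['n_psi']} of {s['n_ses']} cancer-specific SEs are Ψ "
          f"({s['pct_psi']}%); {s['n_omega']} are Ω ({s['pct_omega']}%); "
          f"{s['n_mark_instances']} mark instances, {s['n_compound']} compound")

    ranking = lncrna_se_ranking(corr, cancer_specific, FOCAL)
    lio.write_table(
        pd.DataFrame(sorted(ranking["counts"].items()), columns=["lncrna_id", "n_ses"]),
        OUT / "lncrna_ranking.tsv")
    print(f"focal lncRNA overlaps {ranking['focal_count']} SEs: "
          f"{ranking['percentile']:.0f}th percentile among "
          f"{ranking['n_with_overlap']} lncRNAs with >=1 overlap")


if __name__ == "__main__":
    main()
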