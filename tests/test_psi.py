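"""Confirmation, Ψ/Ω labelling, mark profiles, TSS mode and lncRNA ranking."""

import numpy as np
import pandas as pd
import pytest

from lncse.contacts import ConsensusContactPeaks
from lncse.intervals import GenomicInterval, IntervalSet
from lncse.psi import (
    classify_ses,
    confirm_peaks,
    contact_density,
    lncrna_se_ranking,
    psi_summary,
    tss_mode,
    validate_correlation_peaks,
)
from lncse.se_atlas import ConsensusSE


def corr_df(*rows):
    return pd.DataFrame(list(rows),
                        columns=["chrom", "start", "end", "lncrna_id", "mark", "sign"])


def contacts(*rows):
    return ConsensusContactPeaks(
        IntervalSet(pd.DataFrame(list(rows), columns=["chrom", "start", "end"])))


def make_se(se_id, chrom, start, end, spec="cancer-specific"):
    return ConsensusSE(se_id, GenomicInterval(chrom, start, end), "cancer", 3,
                       specificity=spec)


class TestValidation:
    def test_unknown_mark_rejected(self):
        with pytest.raises(ValueError, match="unknown histone mark"):
            validate_correlation_peaks(corr_df(("chr1", 0, 10, "L", "H3K9ac", "+")))

    def test_sign_rho_consistency(self):
        df = corr_df(("chr1", 0, 10, "L", "H3K4me1", "+"))
        df["rho"] = [-0.4]
        with pytest.raises(ValueError, match="inconsistent"):
            validate_correlation_peaks(df)


class TestConfirmPeaks:
    def test_overlapping_peak_retained_with_annotations(self):
        out = confirm_peaks(corr_df(("chr1", 100, 300, "L", "H3K4me1", "+")),
                            contacts(("chr1", 250, 600)))
        assert len(out) == 1 and out.loc[0, "mark"] == "H3K4me1"
        assert (out.loc[0, "start"], out.loc[0, "end"]) == (100, 300)

    def test_disjoint_sets_empty(self):
        out = confirm_peaks(corr_df(("chr1", 100, 300, "L", "H3K4me1", "+")),
                            contacts(("chr1", 300, 600)))
        assert len(out) == 0

    def test_multiple_lncrnas_rejected(self):
        df = corr_df(("chr1", 0, 10, "A", "H3K4me1", "+"),
                     ("chr1", 20, 30, "B", "H3K4me1", "+"))
        with pytest.raises(ValueError, match="single focal lncRNA"):
            confirm_peaks(df, contacts(("chr1", 0, 5)))

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(0)
        rows = [("chr1", int(s), int(s) + 200, "L", "H3K4me1", "+")
                for s in rng.integers(0, 500_000, size=50)]
        ct = contacts(*[("chr1", int(s), int(s) + 400)
                        for s in rng.integers(0, 500_000, size=30)])
        once = confirm_peaks(corr_df(*rows), ct)
        twice = confirm_peaks(once, ct)
        assert twice.equals(once)
        assert set(map(tuple, once[["start", "end"]].values)) <= \
            set((r[1], r[2]) for r in rows)

    def test_planted_confirmed_count(self, bundle):
        import lncse.io as lio

        corr = lio.read_correlation_peaks(bundle["dir"] / "correlation_peaks.tsv")
        focal = corr[corr["lncrna_id"] == "LNC_FOCAL"].reset_index(drop=True)
        planted = IntervalSet(pd.DataFrame(
            bundle["truth"]["contacts"]["consensus_peaks"],
            columns=["chrom", "start", "end"]))
        out = confirm_peaks(focal, ConsensusContactPeaks(planted))
        assert len(out) == bundle["truth"]["correlation"]["n_confirmed"]


class TestClassifySEs:
    def test_psi_omega_partition_and_profiles(self):
        ses = [make_se("se_1", "chr1", 10_000, 30_000),
               make_se("se_2", "chr1", 100_000, 120_000)]
        confirmed = corr_df(("chr1", 15_000, 15_300, "L", "H3K4me1", "+"),
                            ("chr1", 16_000, 16_300, "L", "H3K4me3", "+"),
                            ("chr1", 15_100, 15_200, "L", "H3K4me1", "+"))
        classify_ses(ses, confirmed)
        assert ses[0].psi_label == "psi"
        # distinct (mark, sign) pairs only: duplicated H3K4me1(+) counts once
        assert ses[0].mark_profile == [("H3K4me1", "+"), ("H3K4me3", "+")]
        assert ses[1].psi_label == "omega" and ses[1].mark_profile == []
        s = psi_summary(ses)
        assert (s["n_psi"], s["n_omega"], s["n_mark_instances"], s["n_compound"]) == (1, 1, 2, 1)
        assert s["pct_psi"] == 50.0

    def test_empty_confirmed_all_omega(self):
        ses = [make_se("se_1", "chr1", 0, 1_000)]
        classify_ses(ses, corr_df())
        assert ses[0].psi_label == "omega"

    def test_psi_monotone_in_confirmed_set(self):
        ses = [make_se(f"se_{i}", "chr1", i * 50_000, i * 50_000 + 10_000)
               for i in range(1, 6)]
        rows = [("chr1", i * 50_000 + 100, i * 50_000 + 300, "L", "H3K4me1", "+")
                for i in range(1, 6)]
        for k in range(len(rows)):
            classify_ses(ses, corr_df(*rows[:k]))
            assert sum(s.psi_label == "psi" for s in ses) == k


class TestContactDensity:
    def test_counts_including_spanning_peak(self):
        ses = [make_se("a", "chr1", 0, 1_000), make_se("b", "chr1", 1_500, 2_500)]
        ct = contacts(("chr1", 100, 200), ("chr1", 900, 1_600), ("chr1", 2_400, 2_600))
        counts = contact_density(ses, ct)
        # the spanning peak counts once per SE
        assert counts.tolist() == [2, 2]

    def test_matches_bruteforce_oracle(self):
        from helpers import bitmap_counts, random_interval_set

        rng = np.random.default_rng(3)
        toy = {"chr1": 200_000}
        a = random_interval_set(rng, 40, toy, max_width=3_000)
        b = random_interval_set(rng, 120, toy, max_width=800)
        ses = [make_se(f"se_{i}", r.chrom, r.start, r.end)
               for i, r in enumerate(a.df.itertuples())]
        got = contact_density(ses, ConsensusContactPeaks(b))
        assert got.tolist() == bitmap_counts(a, b).tolist()


class TestLncRanking:
    def ranking_input(self, counts: dict[str, int], n_ses=10):
        ses = [make_se(f"se_{i}", "chr1", i * 100_000, i * 100_000 + 10_000)
               for i in range(n_ses)]
        rows = []
        for lnc, c in counts.items():
            for i in range(c):
                rows.append(("chr1", i * 100_000 + 500, i * 100_000 + 700,
                             lnc, "H3K4me1", "+"))
        return corr_df(*rows), ses

    def test_strictly_largest_count_is_percentile_100(self):
        counts = {f"l{i}": i for i in range(1, 10)}
        counts["focal"] = 9  # one SE more than the runner-up
        df, ses = self.ranking_input(counts)
        out = lncrna_se_ranking(df, ses, "focal")
        assert out["percentile"] == 100.0 and out["focal_count"] == 9

    def test_all_tied_percentile_100_under_le(self):
        counts = {f"l{i}": 3 for i in range(5)} | {"focal": 3}
        df, ses = self.ranking_input(counts)
        out = lncrna_se_ranking(df, ses, "focal")
        assert out["percentile"] == 100.0
        strict = lncrna_se_ranking(df, ses, "focal", tie_rule="lt")
        assert strict["percentile"] == 0.0

    def test_duplicated_peak_rows_do_not_inflate_counts(self):
        counts = {"focal": 4, "l1": 2}
        df, ses = self.ranking_input(counts)
        doubled = pd.concat([df, df], ignore_index=True)
        a = lncrna_se_ranking(df, ses, "focal")
        b = lncrna_se_ranking(doubled, ses, "focal")
        assert a["counts"] == b["counts"] and a["percentile"] == b["percentile"]

    def test_absent_focal_rejected(self):
        df, ses = self.ranking_input({"l1": 1})
        with pytest.raises(ValueError, match="absent"):
            lncrna_se_ranking(df, ses, "nope")

    def test_matches_sort_oracle_on_planted_fixture(self, bundle, classified_ses):
        """50-lncRNA synthetic table vs a brute-force count-and-sort oracle."""
        import lncse.io as lio

        corr = lio.read_correlation_peaks(bundle["dir"] / "correlation_peaks.tsv")
        df = classified_ses
        cancer = df[df["specificity"] == "cancer-specific"]
        ses = [make_se(r.se_id, r.chrom, r.start, r.end)
               for r in cancer.itertuples()]
        out = lncrna_se_ranking(corr, ses, "LNC_FOCAL")
        # oracle: per lncRNA, count SEs containing >=1 peak, brute force
        oracle = {}
        for lnc, sub in corr.groupby("lncrna_id"):
            hit = 0
            for se in ses:
                m = sub[(sub["chrom"] == se.interval.chrom)
                        & (sub["start"] < se.interval.end)
                        & (sub["end"] > se.interval.start)]
                hit += int(len(m) > 0)
            oracle[lnc] = hit
        assert out["counts"] == oracle
        nz = [c for c in oracle.values() if c >= 1]
        expected_pct = 100.0 * sum(c <= oracle["LNC_FOCAL"] for c in nz) / len(nz)
        assert out["percentile"] == pytest.approx(expected_pct)
        assert out["focal_count"] == bundle["truth"]["correlation"]["focal_se_count"]


class TestTssMode:
    def test_omega_tss_hit_reported(self):
        omega = [make_se("se_1", "chr1", 100_000, 120_000)]
        omega[0].psi_label = "omega"
        genes = pd.DataFrame([
            {"gene_id": "G1", "symbol": "G1", "chrom": "chr1", "start": 150_000,
             "end": 160_000, "strand": "+", "biotype": "protein_coding"},
        ])
        targets = pd.DataFrame([{"se_id": "se_1", "gene_id": "G1"}])
        confirmed = corr_df(("chr1", 149_500, 149_800, "L", "H3K4me1", "+"))
        out = tss_mode(omega, confirmed, genes, targets, promoter_pad=2_000)
        assert out.to_dict("records") == [
            {"se_id": "se_1", "gene_id": "G1", "mark": "H3K4me1", "sign": "+"}]

    def test_minus_strand_tss_at_end(self):
        omega = [make_se("se_1", "chr1", 100_000, 120_000)]
        omega[0].psi_label = "omega"
        genes = pd.DataFrame([
            {"gene_id": "G1", "symbol": "G1", "chrom": "chr1", "start": 150_000,
             "end": 160_000, "strand": "-", "biotype": "protein_coding"},
        ])
        targets = pd.DataFrame([{"se_id": "se_1", "gene_id": "G1"}])
        near_start = corr_df(("chr1", 149_500, 149_800, "L", "H3K4me1", "+"))
        near_end = corr_df(("chr1", 160_500, 160_800, "L", "H3K4me1", "+"))
        assert len(tss_mode(omega, near_start, genes, targets, 2_000)) == 0
        assert len(tss_mode(omega, near_end, genes, targets, 2_000)) == 1

    def test_planted_tss_mode_recovered(self, pipeline_run):
        got = pd.read_csv(pipeline_run["dir"] / "tss_mode.tsv", sep="\t")
        truth = pipeline_run["truth"]["tss_mode"]
        assert len(got) == len(truth)
        got_pairs = set(zip(got["gene_id"], got["mark"], got["sign"]))
        tru_pairs = set((t["gene_id"], t["mark"], t["sign"]) for t in truth)
        assert got_pairs == tru_pairs

    def test_planted_concordance_recovered(self, pipeline_run, classified_ses):
        report = pipeline_run["report"]
        concordant_ids = report["tss"]["concordant_psi_ses"]
        keys = classified_ses.set_index("se_id").loc[concordant_ids, "key"]
        assert sorted(keys) == sorted(pipeline_run["truth"]["concordant_psi"])
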