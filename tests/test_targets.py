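"""Target-gene windows, lead genes, Welch DE, triple validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncse.intervals import GenomicInterval
from lncse.se_atlas import ConsensusSE
from lncse.targets import (
    TargetParams,
    assign_targets,
    lead_gene,
    triple_validate,
    welch_de,
)


def se(se_id="se_1", chrom="chr1", start=500_000, end=520_000):
    return ConsensusSE(se_id, GenomicInterval(chrom, start, end), "cancer", 3,
                       specificity="cancer-specific", psi_label="psi")


def gene_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end",
                                       "strand", "biotype", "tpm_cancer"])


class TestAssignTargets:
    def g(self, gid, start, tpm, end=None, chrom="chr1"):
        return (gid, gid, chrom, start, end or start + 2_000, "+", "protein_coding", tpm)

    def test_window_boundary_inclusive_exclusive(self):
        genes = gene_table([
            self.g("at_100k", 620_000, 5.0),       # exactly 100 kb downstream
            self.g("past_100k", 620_001, 5.0),     # one base past
            self.g("left_100k", 400_000, 5.0),     # exactly 100 kb upstream
        ])
        out = assign_targets([se()], genes, "tpm_cancer")
        assert sorted(out["gene_id"]) == ["at_100k", "left_100k"]
        assert out.set_index("gene_id").loc["at_100k", "distance"] == 100_000

    def test_overlap_distance_zero_and_strict_tpm(self):
        genes = gene_table([
            self.g("overlap_ok", 510_000, 1.01),
            self.g("overlap_at_threshold", 512_000, 1.0),  # TPM exactly 1: excluded
        ])
        out = assign_targets([se()], genes, "tpm_cancer")
        assert out["gene_id"].tolist() == ["overlap_ok"]
        assert out.loc[0, "distance"] == 0

    def test_monotonicity_in_window_and_tpm(self):
        rng = np.random.default_rng(0)
        genes = gene_table([
            self.g(f"g{i}", int(s), float(t))
            for i, (s, t) in enumerate(zip(rng.integers(300_000, 800_000, 40),
                                           rng.uniform(0, 20, 40)))
        ])
        prev = None
        for window in (150_000, 100_000, 50_000, 10_000):
            n = len(assign_targets([se()], genes, "tpm_cancer", window=window))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for tpm_min in (0.0, 1.0, 5.0, 15.0):
            n = len(assign_targets([se()], genes, "tpm_cancer", tpm_min=tpm_min))
            if prev is not None:
                assert n <= prev
            prev = n


class TestLeadGene:
    def assoc(self):
        return pd.DataFrame([
            {"se_id": "se_1", "gene_id": "A", "symbol": "A", "distance": 0, "tpm": 5.0},
            {"se_id": "se_1", "gene_id": "B", "symbol": "B", "distance": 10, "tpm": 5.0},
        ])

    def test_lowest_padj_wins(self):
        de = pd.DataFrame([{"gene_id": "A", "log2FC": 1.0, "p": 1e-6, "padj": 1e-5},
                           {"gene_id": "B", "log2FC": 3.0, "p": 0.1, "padj": 0.2}])
        out = lead_gene(self.assoc(), de)
        assert out.loc[0, "lead_gene"] == "A" and bool(out.loc[0, "significant"])

    def test_tie_broken_by_abs_log2fc_then_id(self):
        de = pd.DataFrame([{"gene_id": "A", "log2FC": 1.0, "p": 0.01, "padj": 0.02},
                           {"gene_id": "B", "log2FC": -2.5, "p": 0.01, "padj": 0.02}])
        out = lead_gene(self.assoc(), de)
        assert out.loc[0, "lead_gene"] == "B"  # larger |log2FC|
        de2 = de.assign(log2FC=[1.0, -1.0])
        assert lead_gene(self.assoc(), de2).loc[0, "lead_gene"] == "A"  # id order

    def test_missing_de_treated_as_padj_one(self, caplog):
        de = pd.DataFrame([{"gene_id": "A", "log2FC": 1.0, "p": 0.5, "padj": 0.9}])
        with caplog.at_level("WARNING"):
            out = lead_gene(self.assoc(), de)
        assert out.loc[0, "lead_gene"] == "A"
        assert "no DE record" in caplog.text

    def test_targetless_se_reported_with_null_lead(self):
        de = pd.DataFrame([{"gene_id": "A", "log2FC": 1.0, "p": 0.5, "padj": 0.9}])
        out = lead_gene(self.assoc(), de, all_se_ids=["se_1", "se_2"])
        row = out.set_index("se_id").loc["se_2"]
        assert pd.isna(row["lead_gene"]) and row["n_targets"] == 0


class TestWelch:
    def _matrix(self, a, b):
        cols = [f"t{i}" for i in range(len(a))] + [f"n{i}" for i in range(len(b))]
        expr = pd.DataFrame([list(a) + list(b)], index=["g"], columns=cols)
        groups = pd.Series(["tumor"] * len(a) + ["normal"] * len(b), index=cols)
        return expr, groups

    def test_identical_groups_t_zero_p_one(self):
        expr, groups = self._matrix([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        out = welch_de(expr, groups)
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_matches_closed_form_and_scipy(self):
        a = [4.1, 5.3, 6.2]
        b = [3.0, 3.4, 2.8]
        expr, groups = self._matrix(a, b)
        out = welch_de(expr, groups)
        # closed form
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t = (ma - mb) / np.sqrt(va / 3 + vb / 3)
        df = (va / 3 + vb / 3) ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-10)
        assert out.loc[0, "df"] == pytest.approx(df, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-10)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert out.loc[0, "t"] == pytest.approx(ref.statistic, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-10)
        assert out.loc[0, "log2FC"] == pytest.approx(ma - mb)

    def test_planted_shift_recovered_at_large_n(self):
        rng = np.random.default_rng(1)
        delta = 0.8
        a = rng.normal(5 + delta, 1, size=4000)
        b = rng.normal(5, 1, size=1000)
        expr, groups = self._matrix(a, b)
        out = welch_de(expr, groups)
        assert out.loc[0, "log2FC"] == pytest.approx(delta, abs=0.1)

    def test_too_few_samples_rejected(self):
        expr, groups = self._matrix([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            welch_de(expr, groups)


class TestTripleValidation:
    def tables(self):
        assocs = pd.DataFrame([
            {"se_id": "se_13", "gene_id": "CDC20_like", "symbol": "CDC20_like",
             "distance": 0, "tpm": 30.0},
            {"se_id": "se_13", "gene_id": "down_gene", "symbol": "down_gene",
             "distance": 10, "tpm": 8.0},
            {"se_id": "se_13", "gene_id": "uncorr_gene", "symbol": "uncorr_gene",
             "distance": 20, "tpm": 8.0},
            {"se_id": "se_13", "gene_id": "unmapped_gene", "symbol": "unmapped_gene",
             "distance": 30, "tpm": 8.0},
        ])
        de_cl = pd.DataFrame([
            {"gene_id": "CDC20_like", "log2FC": 1.8, "p": 1e-4, "padj": 0.01},
            {"gene_id": "down_gene", "log2FC": -3.8, "p": 1e-9, "padj": 1e-8},
            {"gene_id": "uncorr_gene", "log2FC": 2.0, "p": 1e-4, "padj": 0.01},
            {"gene_id": "unmapped_gene", "log2FC": 2.0, "p": 1e-4, "padj": 0.01},
        ])
        de_cohort = pd.DataFrame([
            {"gene_id": "CDC20_like", "log2FC": 1.349, "p": 1e-6, "padj": 1e-5},
            {"gene_id": "down_gene", "log2FC": 1.3, "p": 1e-6, "padj": 1e-5},
            {"gene_id": "uncorr_gene", "log2FC": 1.3, "p": 1e-6, "padj": 1e-5},
            {"gene_id": "unmapped_gene", "log2FC": 1.3, "p": 1e-6, "padj": 1e-5},
        ])
        coexpr = pd.DataFrame([
            {"gene_id": "CDC20_like", "rho": 0.2226, "p": 1e-6, "fdr": 1e-4},
            {"gene_id": "down_gene", "rho": 0.3, "p": 1e-4, "fdr": 1e-3},
            {"gene_id": "uncorr_gene", "rho": 0.0, "p": 0.99, "fdr": 0.99},
        ])
        return assocs, de_cl, de_cohort, coexpr

    def test_flags_and_conjunction(self, caplog):
        assocs, de_cl, de_cohort, coexpr = self.tables()
        with caplog.at_level("WARNING"):
            out = triple_validate(assocs, de_cl, de_cohort, coexpr).set_index("gene_id")
        assert bool(out.loc["CDC20_like", "triple_validated"])
        # strongly downregulated in the cell line: fails layer 1 regardless
        assert not out.loc["down_gene", "cellline_up"]
        assert not out.loc["down_gene", "triple_validated"]
        # rho = 0 fails the co-expression layer
        assert not out.loc["uncorr_gene", "coexpr_pos"]
        # gene missing from the co-expression table fails that layer, logged
        assert not out.loc["unmapped_gene", "triple_validated"]
        assert "lookups failed" in caplog.text

    def test_sign_only_coexpr_criterion(self):
        assocs, de_cl, de_cohort, coexpr = self.tables()
        coexpr.loc[coexpr["gene_id"] == "uncorr_gene", "rho"] = 0.0023
        coexpr.loc[coexpr["gene_id"] == "uncorr_gene", "p"] = 0.96
        params = TargetParams(coexpr_p_max=None)
        out = triple_validate(assocs, de_cl, de_cohort, coexpr, params).set_index("gene_id")
        # a weakly positive, non-significant rho passes under the sign-only rule
        assert bool(out.loc["uncorr_gene", "triple_validated"])

    def test_planted_truth_recovered(self, pipeline_run):
        got = pipeline_run["report"]["targets"]["triple_validated_genes"]
        assert got == pipeline_run["truth"]["expression"]["triple_validated"]
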