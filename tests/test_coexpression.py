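"""Spearman (exact small-n p), partial correlation, BH, random-gene-set null."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncse.coexpression import (
    ExpressionCohort,
    bh_adjust,
    expressed_background,
    partial_spearman,
    random_geneset_null,
    spearman,
    spearman_profile,
)
from lncse.simulate import simulate_purity_confound


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.array([0.5, 1.2, 2.0, 3.3, 4.1, 5.0])
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho2, _ = spearman(x, -np.exp(x))
        assert rho2 == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)

    def test_constant_vector_reported_missing(self):
        rho, p = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_p_matches_rank_formula_bruteforce(self):
        """n=6 fixed vectors: rho and exact p vs full 720-permutation scan."""
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        rho, p = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        ref_rho = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        rhos = []
        for perm in permutations(range(6)):
            rhos.append(np.corrcoef(rx, ry[list(perm)])[0, 1])
        ref_p = np.mean(np.abs(rhos) >= abs(ref_rho) - 1e-12)
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_large_n_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestPartialSpearman:
    def test_constant_purity_equals_ordinary_spearman(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(size=40)
        z = np.full(40, 0.7)
        rho, _ = spearman(x, y)
        assert partial_spearman(x, y, z) == pytest.approx(rho, abs=1e-12)

    def test_missing_purity_dropped(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        z = rng.uniform(size=30)
        z[:5] = np.nan
        expected = partial_spearman(x[5:], y[5:], z[5:])
        assert partial_spearman(x, y, z) == pytest.approx(expected)

    def test_confound_removed_when_no_direct_coupling(self):
        sim = simulate_purity_confound(seed=0, n_samples=500, beta=0.0)
        rhos, partials = [], []
        for g in sim["genes"]:
            rhos.append(spearman(sim["focal"], g)[0])
            partials.append(partial_spearman(sim["focal"], g, sim["purity"]))
        assert np.mean(rhos) > 0.3  # the confound induces strong ordinary rho
        assert abs(np.mean(partials)) < 0.05

    def test_direct_effect_survives_confounding(self):
        sim = simulate_purity_confound(seed=1, n_samples=500, beta=0.8,
                                       gamma_gene=0.5, noise_sd=0.6)
        partials = [partial_spearman(sim["focal"], g, sim["purity"])
                    for g in sim["genes"]]
        assert np.mean(partials) > 0.2
        assert all(p > 0 for p in partials)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        out = bh_adjust(np.full(7, 0.2))
        assert np.allclose(out, 0.2)

    def test_hand_computed_step_up(self):
        p = np.array([0.01, 0.04, 0.03, 0.005, 0.55, 0.1])
        # sorted: .005 .01 .03 .04 .1 .55 -> raw m*p/i:
        # .03 .03 .06 .06 .12 .55; step-up monotone from the right
        expected = {0.005: 0.03, 0.01: 0.03, 0.03: 0.06, 0.04: 0.06, 0.1: 0.12, 0.55: 0.55}
        out = bh_adjust(p)
        for pi, fi in zip(p, out):
            assert fi == pytest.approx(expected[pi])

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=40))
        out = bh_adjust(p)
        assert np.all(np.diff(out) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


def _toy_cohort(seed=0, n_genes=60, n_tumor=80, n_normal=10, coupled=()):  # noqa: ANN001
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)] + ["FOCAL"]
    samples = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    f = rng.normal(size=n_tumor + n_normal)
    mat = rng.normal(5, 1, size=(n_genes + 1, n_tumor + n_normal))
    for gi in coupled:
        mat[gi] += 1.2 * f
    mat[-1] = 5 + f + rng.normal(0, 0.2, size=n_tumor + n_normal)
    expr = pd.DataFrame(np.maximum(mat, 0), index=genes, columns=samples)
    meta_class = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    purity = pd.Series(np.concatenate([rng.uniform(0.3, 0.9, n_tumor),
                                       np.full(n_normal, np.nan)]), index=samples)
    return ExpressionCohort(expr, meta_class, purity)


class TestSpearmanProfile:
    def test_profile_matches_per_gene_spearman(self):
        cohort = _toy_cohort(seed=4)
        tumor = cohort.tumor_matrix()
        prof = spearman_profile(tumor, "FOCAL").set_index("gene_id")
        for g in ["g0", "g5", "g59"]:
            rho, p = spearman(tumor.loc[g].to_numpy(), tumor.loc["FOCAL"].to_numpy())
            assert prof.loc[g, "rho"] == pytest.approx(rho, abs=1e-10)
            assert prof.loc[g, "p"] == pytest.approx(p, rel=1e-9)

    def test_purity_profile_matches_partial_spearman(self):
        cohort = _toy_cohort(seed=5)
        tumor = cohort.tumor_matrix(require_purity=True)
        prof = spearman_profile(tumor, "FOCAL", purity=cohort.purity).set_index("gene_id")
        z = cohort.purity.reindex(tumor.columns).to_numpy()
        for g in ["g1", "g30"]:
            expected = partial_spearman(tumor.loc[g].to_numpy(),
                                        tumor.loc["FOCAL"].to_numpy(), z)
            assert prof.loc[g, "rho"] == pytest.approx(expected, abs=1e-10)


class TestRandomGeneSetNull:
    def test_smoke_run_deterministic(self):
        cohort = _toy_cohort(seed=6)
        a = random_geneset_null(cohort, "FOCAL", ["g0", "g1", "g2"], n_sets=50, seed=9)
        b = random_geneset_null(cohort, "FOCAL", ["g0", "g1", "g2"], n_sets=50, seed=9)
        assert a.n_sets == 50 and len(a.null["median_rho"]) == 50
        for m in a.null:
            assert np.array_equal(a.null[m], b.null[m])

    def test_background_smaller_than_set_rejected(self):
        cohort = _toy_cohort(seed=7)
        with pytest.raises(ValueError, match="background"):
            random_geneset_null(cohort, "FOCAL", ["g0", "g1"],
                                background=["g0"], n_sets=10, seed=0)

    def test_planted_coupling_reaches_minimum_p(self):
        coupled = tuple(range(8))
        cohort = _toy_cohort(seed=8, coupled=coupled)
        res = random_geneset_null(cohort, "FOCAL", [f"g{i}" for i in coupled],
                                  n_sets=200, seed=1)
        assert res.p["median_rho"] == pytest.approx(1 / 201)
        assert res.observed["n_sig_pos"] == len(coupled)

    def test_null_calibrated_for_random_target_set(self):
        """Target sets drawn from the background give roughly uniform p."""
        ps = []
        for seed in range(40):
            cohort = _toy_cohort(seed=100 + seed)
            rng = np.random.default_rng(seed)
            targets = [f"g{i}" for i in rng.choice(60, size=8, replace=False)]
            res = random_geneset_null(cohort, "FOCAL", targets, n_sets=49, seed=2)
            ps.append(res.p["mean_rho"])
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_invariant_to_background_order(self):
        cohort = _toy_cohort(seed=9)
        bg = [f"g{i}" for i in range(60)]
        a = random_geneset_null(cohort, "FOCAL", ["g0", "g1"], background=bg,
                                n_sets=30, seed=3)
        b = random_geneset_null(cohort, "FOCAL", ["g0", "g1"],
                                background=list(reversed(bg)), n_sets=30, seed=3)
        for m in a.null:
            assert np.array_equal(a.null[m], b.null[m])

    def test_expressed_background_threshold(self):
        cohort = _toy_cohort(seed=10)
        # silence g0 in most tumor samples
        cohort.expr.loc["g0", cohort.expr.columns[:75]] = 0.0
        bg = expressed_background(cohort, min_nonzero_fraction=0.2)
        assert "g0" not in bg and "g1" in bg
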