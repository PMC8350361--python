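"""MVN correlation model, BIC selection, Gini, Weir-Cockerham F_ST, regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recland import divergence as dv
from recland import synthetic_data as sd


class TestProfileCorrelationModel:
    def test_identical_profiles_correlation_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.3, 500)
        Y = np.column_stack([x, x, rng.normal(0, 0.3, 500),
                             rng.normal(0, 0.3, 500)])
        fit = dv.fit_profile_correlation(Y, "full")
        assert abs(fit.correlation[0, 1] - 1) < 1e-6

    def test_full_recovery_within_tolerance(self):
        rng = np.random.default_rng(1)
        R = np.array([[1, .5, .3, .2], [.5, 1, .4, .25],
                      [.3, .4, 1, .35], [.2, .25, .35, 1.]])
        sds = np.array([.2, .25, .3, .22])
        Y = rng.multivariate_normal(np.full(4, 0.1), np.outer(sds, sds) * R,
                                    size=5000)
        fit = dv.fit_profile_correlation(Y, "full")
        assert np.abs(fit.correlation - R).max() < 0.03

    def test_separate_means_matches_sample_covariance(self):
        rng = np.random.default_rng(2)
        Y = rng.multivariate_normal(np.zeros(4), np.eye(4), size=800)
        fit = dv.fit_profile_correlation(Y, "full", common_mean=False)
        samp = np.cov(Y.T, bias=True)
        sdv = np.sqrt(np.diag(samp))
        assert np.abs(fit.correlation - samp / np.outer(sdv, sdv)).max() < 1e-6
        assert np.abs(fit.variances - np.diag(samp)).max() < 1e-10

    def test_common_mean_is_gls_solution(self):
        rng = np.random.default_rng(3)
        sigma = sd.equicorrelated_sigma(0.4, [0.5, 1.0, 1.5, 2.0])
        Y = rng.multivariate_normal(np.full(4, 2.0), sigma, size=2000)
        fit = dv.fit_profile_correlation(Y, "full")
        # at the optimum, mu satisfies the GLS normal equation
        E = Y - fit.mu
        cov = E.T @ E / len(Y)
        w = np.linalg.solve(cov, np.ones(4))
        mu_gls = (Y.mean(axis=0) @ w) / w.sum()
        assert abs(fit.mu[0] - mu_gls) < 1e-8

    def test_missing_or_small_input_rejected(self):
        with pytest.raises(ValueError):
            dv.fit_profile_correlation(np.full((10, 4), 1.0))
        bad = np.ones((50, 4))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            dv.fit_profile_correlation(bad)


class TestStructureComparison:
    @pytest.mark.parametrize("truth", ["equicorrelated", "full"])
    def test_bic_selects_generating_structure(self, truth):
        hits = 0
        reps = 40
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            if truth == "equicorrelated":
                sigma = sd.equicorrelated_sigma(0.3, [0.8, 1.0, 1.2, 0.9])
            else:
                R = np.array([[1, .5, .2, .2], [.5, 1, .3, .2],
                              [.2, .3, 1, .45], [.2, .2, .45, 1.]])
                sigma = R
            Y = rng.multivariate_normal(np.zeros(4), sigma, size=2000)
            full = dv.fit_profile_correlation(Y, "full")
            equi = dv.fit_profile_correlation(Y, "equicorrelated")
            best, _ = dv.compare_structures(full, equi)
            hits += best == truth
        assert hits / reps >= 0.9

    def test_bic_consistency_with_n(self):
        # under an equicorrelated truth the full model wins less as n grows
        wins = {}
        for n in (500, 8000):
            cnt = 0
            for i in range(15):
                rng = np.random.default_rng(7000 + i)
                sigma = sd.equicorrelated_sigma(0.35, [1.0] * 4)
                Y = rng.multivariate_normal(np.zeros(4), sigma, size=n)
                best, _ = dv.compare_structures(
                    dv.fit_profile_correlation(Y, "full"),
                    dv.fit_profile_correlation(Y, "equicorrelated"))
                cnt += best == "full"
            wins[n] = cnt
        assert wins[8000] <= wins[500]

    def test_identical_loglik_prefers_simpler(self):
        f = dv.CorrelationModelFit("full", 0.0, np.ones(4), np.eye(4),
                                   -100.0, 11, 500)
        e = dv.CorrelationModelFit("equicorrelated", 0.0, np.ones(4),
                                   np.eye(4), -100.0, 6, 500)
        best, delta = dv.compare_structures(f, e)
        assert best == "equicorrelated" and delta > 0

    def test_mismatched_n_errors(self):
        f = dv.CorrelationModelFit("full", 0.0, np.ones(4), np.eye(4),
                                   -1.0, 11, 500)
        e = dv.CorrelationModelFit("equicorrelated", 0.0, np.ones(4),
                                   np.eye(4), -1.0, 6, 400)
        with pytest.raises(ValueError):
            dv.compare_structures(f, e)


class TestWindowCorrelations:
    def _maps(self, a, b, groups=None):
        ma = pd.DataFrame({"value": a})
        mb = pd.DataFrame({"value": b})
        g = pd.Series(groups) if groups is not None else None
        return dv.profile_correlation_windows(ma, mb, g)

    def test_affine_relation_gives_one(self):
        a = np.linspace(0, 1, 30)
        out = self._maps(a, 2 * a + 1)
        assert np.isclose(out["pearson_r"].iloc[0], 1.0)

    def test_negative_relation(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        assert np.isclose(self._maps(a, -a)["pearson_r"].iloc[0], -1.0)

    def test_small_groups_skipped_and_nan_dropped(self):
        a = np.array([1.0, 2, 3, np.nan, 5, 6, 7, 1, 2])
        b = np.array([2.0, 4, 6, 8, 10, 11, 15, 3, 4])
        groups = ["g1"] * 7 + ["g2"] * 2
        out = self._maps(a, b, groups)
        assert list(out["group"]) == ["g1"]  # g2 has < 5 complete windows
        assert out["n_windows"].iloc[0] == 6  # NaN window dropped pairwise

    def test_zero_variance_reported_missing(self):
        out = self._maps(np.ones(8), np.arange(8.0))
        assert np.isnan(out["pearson_r"].iloc[0])

    def test_noise_attenuates_toward_closed_form(self):
        # adding independent noise sigma to both maps lowers the correlation
        # toward r0 / (1 + sigma^2/var)
        rng = np.random.default_rng(6)
        n = 40_000
        base = rng.normal(0, 1, n)
        a0 = base + rng.normal(0, 0.5, n)
        b0 = base + rng.normal(0, 0.5, n)
        r0 = np.corrcoef(a0, b0)[0, 1]
        sigma = 0.8
        a = a0 + rng.normal(0, sigma, n)
        b = b0 + rng.normal(0, sigma, n)
        r_att = self._maps(a, b)["pearson_r"].iloc[0]
        expected = r0 / (1 + sigma**2 / a0.var())
        assert abs(r_att - expected) < 0.02
        assert r_att < r0


class TestGini:
    def test_identical_profiles_zero(self):
        x = np.array([0.3, 1.2, 0.5, 2.0])
        assert dv.gini_pair(x, x) == 0.0
        assert dv.gini_pair(x, 5 * x) == 0.0  # scale invariance

    def test_point_mass_limit(self):
        n = 8
        a = np.zeros(n)
        a[3] = 1.0
        b = np.full(n, 1.0)
        assert np.isclose(dv.gini_pair(a, b), 1 - 1 / n)

    def test_worked_four_interval_example(self):
        a = np.array([0.1, 0.1, 0.1, 0.7])
        b = np.full(4, 0.25)
        assert np.isclose(dv.gini_pair(a, b), 0.45)

    def test_scale_invariance_property(self):
        rng = np.random.default_rng(4)
        a = rng.gamma(0.5, size=100)
        b = rng.gamma(0.5, size=100)
        g = dv.gini_pair(a, b)
        assert np.isclose(dv.gini_pair(3.7 * a, b), g)
        assert np.isclose(dv.gini_pair(a, 0.2 * b), g)
        assert g > 0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            dv.gini_pair(np.zeros(3), np.ones(3))


def brute_force_wc(ca, cb):
    """Per-locus loop implementation of the Weir-Cockerham components."""
    num = den = 0.0
    for l in range(ca.shape[0]):
        n1, n2 = ca[l].sum(), cb[l].sum()
        nt = n1 + n2
        nc = (nt - (n1**2 + n2**2) / nt) / 1.0
        for a in range(ca.shape[1]):
            p1, p2 = ca[l, a] / n1, cb[l, a] / n2
            pbar = (ca[l, a] + cb[l, a]) / nt
            msa = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / 1.0
            msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nt - 2)
            num += msa - msw
            den += msa + (nc - 1) * msw
    return num / den


class TestWcFst:
    def test_no_differentiation_near_zero(self):
        haps, _ = sd.simulate_population_genotypes(
            {"A": 0.0, "B": 0.0}, 100, 5000, seed=5)
        assert abs(dv.wc_fst_pair(haps["A"], haps["B"])) < 0.01

    def test_fixed_alternative_alleles_one(self):
        a = np.zeros((50, 40), dtype=int)
        b = np.ones((50, 40), dtype=int)
        assert np.isclose(dv.wc_fst_pair(a, b), 1.0)

    def test_balding_nichols_recovery(self):
        haps, truth = sd.simulate_population_genotypes(
            {"A": 0.05, "B": 0.05}, 100, 5000, seed=6)
        est = dv.wc_fst_pair(haps["A"], haps["B"])
        assert abs(est - 0.05) < 0.01

    def test_multiallelic_blocks(self):
        haps, truth = sd.simulate_population_genotypes(
            {"A": 0.06, "B": 0.10}, 100, 3000, n_alleles=20, seed=7)
        est = dv.wc_fst_pair(haps["A"], haps["B"])
        assert abs(est - 0.08) < 0.015

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            L = rng.integers(2, 6)
            n1, n2 = rng.integers(4, 30, 2)
            ca = np.zeros((L, 2), dtype=int)
            cb = np.zeros((L, 2), dtype=int)
            ca[:, 0] = rng.integers(0, n1 + 1, L)
            ca[:, 1] = n1 - ca[:, 0]
            cb[:, 0] = rng.integers(0, n2 + 1, L)
            cb[:, 1] = n2 - cb[:, 0]
            mono = (ca[:, 0] + cb[:, 0] == 0) | (ca[:, 1] + cb[:, 1] == 0)
            if mono.all():
                continue
            got = dv.wc_fst_from_counts(ca, cb)
            want = brute_force_wc(ca.astype(float), cb.astype(float))
            assert abs(got - want) < 1e-10

    def test_negative_estimates_retained(self):
        # weak differentiation + small samples can push theta below zero
        rng = np.random.default_rng(9)
        found = False
        for s in range(20):
            haps, _ = sd.simulate_population_genotypes(
                {"A": 0.0, "B": 0.0}, 10, 50, seed=s)
            if dv.wc_fst_pair(haps["A"], haps["B"]) < 0:
                found = True
                break
        assert found

    def test_pairwise_matrix_symmetric_layout(self):
        haps, _ = sd.simulate_population_genotypes(
            {"A": 0.02, "B": 0.05, "C": 0.08}, 40, 500, seed=10)
        out = dv.wc_fst(haps)
        assert len(out) == 3
        assert set(map(tuple, out[["pop_a", "pop_b"]].values)) == {
            ("A", "B"), ("A", "C"), ("B", "C")}


class TestFstRegression:
    def test_exact_slope_on_collinear_points(self):
        res = dv.fst_correlation_regression(
            np.array([0.01, 0.05, 0.09]), np.array([0.5, 0.3, 0.1]))
        assert np.isclose(res.slope, -5.0)
        assert res.significant_negative

    def test_constant_correlation_flat(self):
        res = dv.fst_correlation_regression(
            np.array([0.01, 0.03, 0.05, 0.07]), np.full(4, 0.4))
        assert np.isclose(res.slope, 0.0)
        assert not res.significant_negative
        assert res.ci_low <= 0 <= res.ci_high

    def test_order_invariance(self):
        x = np.array([0.02, 0.08, 0.05, 0.03])
        y = np.array([0.4, 0.1, 0.3, 0.45])
        r1 = dv.fst_correlation_regression(x, y)
        perm = [2, 0, 3, 1]
        r2 = dv.fst_correlation_regression(x[perm], y[perm])
        assert np.isclose(r1.slope, r2.slope)
        assert np.isclose(r1.ci_low, r2.ci_low)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            dv.fst_correlation_regression(np.array([0.1, 0.2]),
                                          np.array([0.3, 0.2]))


def _gene_test_data(rng, n_controls=30, amplify=1.0):
    pops = ["WE", "EE", "WA", "EA"]
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    corr = {p: c for p, c in zip(pairs, [0.47, 0.40, 0.30, 0.35, 0.25, 0.20])}
    gcorr = pd.DataFrame([(a, b, c) for (a, b), c in corr.items()],
                         columns=["pop_a", "pop_b", "correlation"])
    rows = []
    base_slope = -0.15

    def fst_for(slope):
        return {p: 0.1 + slope * (corr[p] - 0.3) + rng.normal(0, 0.01)
                for p in corr}

    for g in range(n_controls):
        f = fst_for(base_slope)
        for (a, b), v in f.items():
            rows.append((f"ctrl{g}", "1AR1", "control", a, b, v))
    f = fst_for(base_slope * amplify)
    for (a, b), v in f.items():
        rows.append(("meio1", "1AR1", "meiotic", a, b, v))
    return pd.DataFrame(rows, columns=["gene", "region", "role",
                                       "pop_a", "pop_b", "fst"]), gcorr


class TestMeioticGeneTest:
    def test_null_gene_unflagged_p_moderate(self):
        rng = np.random.default_rng(11)
        gene_fst, gcorr = _gene_test_data(rng, amplify=1.0)
        out = dv.meiotic_gene_test(gene_fst, gcorr, fdr_alpha=1e-4)
        assert len(out) == 1
        assert not out["fdr_significant"].iloc[0]

    def test_amplified_gene_flagged(self):
        rng = np.random.default_rng(12)
        gene_fst, gcorr = _gene_test_data(rng, n_controls=60, amplify=8.0)
        out = dv.meiotic_gene_test(gene_fst, gcorr, fdr_alpha=0.05)
        assert out["p_emp"].iloc[0] <= 1 / 61 + 1e-12
        assert out["fdr_significant"].iloc[0]

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(13)
        ps = []
        for rep in range(60):
            gene_fst, gcorr = _gene_test_data(rng, n_controls=20, amplify=1.0)
            out = dv.meiotic_gene_test(gene_fst, gcorr)
            ps.append(out["p_emp"].iloc[0])
        ks = stats.kstest(np.array(ps), "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_controls_errors(self):
        rng = np.random.default_rng(14)
        gene_fst, gcorr = _gene_test_data(rng, n_controls=3)
        with pytest.raises(ValueError, match="1AR1"):
            dv.meiotic_gene_test(gene_fst, gcorr)
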