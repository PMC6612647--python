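"""Dosage score, dosage regression (with IRLS and sandwich oracles), score
statistics, and LD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgwas.association import (CohortData, DosageScore, compute_cpg_dosage,
                               compute_score_stats, fit_dosage_regression,
                               ld_r2)
from cgwas.windows import Window
from conftest import make_annotation


def make_window(members):
    return Window("chr1", 1, 1000, members)


def make_cohort(dosages: dict, phenotype, covariates=None, effect_is_alt=None,
                binary=True):
    df = pd.DataFrame(dosages)
    df.index = [f"s{i}" for i in range(len(df))]
    eia = pd.Series(effect_is_alt) if effect_is_alt is not None else None
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=df.index)
    return CohortData(cohort_id="c1", dosages=df, phenotype=np.asarray(phenotype, float),
                      covariates=cov, effect_is_alt=eia, binary=binary)


class TestCpgDosage:
    def test_sum_of_alt_effect_dosages(self):
        win = make_window([make_annotation(100, "a"), make_annotation(200, "b")])
        cohort = make_cohort({"a": [1.2], "b": [0.7]}, [1])
        assert compute_cpg_dosage(win, cohort).values == pytest.approx([1.9])

    def test_ref_effect_orientation(self):
        win = make_window([make_annotation(100, "a", effect_is_alt=False)])
        cohort = make_cohort({"a": [0.5]}, [1])
        assert compute_cpg_dosage(win, cohort).values == pytest.approx([1.5])

    def test_all_homozygous_disrupting(self):
        win = make_window([make_annotation(100, "a"), make_annotation(200, "b")])
        cohort = make_cohort({"a": [0.0, 0.0], "b": [0.0, 0.0]}, [0, 1])
        assert compute_cpg_dosage(win, cohort).values == pytest.approx([0.0, 0.0])

    def test_orientation_invariance(self, rng):
        """Flipping a member's REF/ALT labels (d -> 2-d) leaves D, beta, p unchanged."""
        n = 400
        d1 = rng.binomial(2, 0.3, n).astype(float)
        d2 = rng.binomial(2, 0.4, n).astype(float)
        y = rng.binomial(1, 0.5, n)
        win = make_window([make_annotation(100, "a"), make_annotation(200, "b")])
        c_fwd = make_cohort({"a": d1, "b": d2}, y,
                            effect_is_alt={"a": True, "b": True})
        c_flip = make_cohort({"a": d1, "b": 2.0 - d2}, y,
                             effect_is_alt={"a": True, "b": False})
        s_fwd = compute_cpg_dosage(win, c_fwd)
        s_flip = compute_cpg_dosage(win, c_flip)
        assert np.allclose(s_fwd.values, s_flip.values)
        r_fwd = fit_dosage_regression(s_fwd, c_fwd)
        r_flip = fit_dosage_regression(s_flip, c_flip)
        assert r_fwd.beta == pytest.approx(r_flip.beta, abs=1e-10)
        assert r_fwd.p == pytest.approx(r_flip.p, abs=1e-10)
        ss_f = compute_score_stats(win, c_fwd)
        ss_r = compute_score_stats(win, c_flip)
        assert np.allclose(ss_f.U, ss_r.U) and np.allclose(ss_f.V, ss_r.V)


def _irls_logistic(X, y, tol=1e-12, iters=200):
    """Independent iteratively-reweighted-least-squares oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        new = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta, mu


class TestDosageRegression:
    def test_symmetric_dataset_gives_zero_beta(self):
        # equal case/control counts at D=0 and D=2
        D = np.array([0.0, 0.0, 2.0, 2.0])
        y = np.array([0, 1, 0, 1])
        win = make_window([make_annotation(100, "a")])
        cohort = make_cohort({"a": D}, y)
        res = fit_dosage_regression(DosageScore(win, D), cohort)
        assert res.beta == pytest.approx(0.0, abs=1e-8)

    def test_matches_irls_oracle(self, rng):
        n = 200
        D = rng.binomial(2, 0.3, n) + rng.binomial(2, 0.25, n).astype(float)
        age = rng.normal(70, 5, n)
        eta = -0.3 + 0.4 * D + 0.01 * (age - 70)
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        win = make_window([make_annotation(100, "a")])
        cohort = make_cohort({"a": np.clip(D, 0, 2)}, y, covariates={"age": age})
        res = fit_dosage_regression(DosageScore(win, D), cohort)
        X = np.column_stack([np.ones(n), age, D])
        beta_oracle, mu = _irls_logistic(X, y)
        assert res.beta == pytest.approx(beta_oracle[2], abs=1e-6)
        # HC0 sandwich oracle for the logistic fit
        w = mu * (1 - mu)
        bread = np.linalg.inv(X.T @ (X * w[:, None]))
        meat = X.T @ (X * ((y - mu) ** 2)[:, None])
        se_oracle = np.sqrt((bread @ meat @ bread)[2, 2])
        assert res.se == pytest.approx(se_oracle, rel=1e-6)

    def test_linear_hc0_matches_hand_formula(self):
        X = np.column_stack([np.ones(6), [0., 1, 2, 0, 1, 2]])
        y = np.array([0.1, 1.2, 1.9, -0.2, 1.1, 2.3])
        win = make_window([make_annotation(100, "a")])
        cohort = make_cohort({"a": X[:, 1]}, y, binary=False)
        res = fit_dosage_regression(DosageScore(win, X[:, 1]), cohort,
                                    family="quantitative")
        bread = np.linalg.inv(X.T @ X)
        beta = bread @ X.T @ y
        e = y - X @ beta
        cov = bread @ (X.T @ (X * (e**2)[:, None])) @ bread
        assert res.beta == pytest.approx(beta[1], rel=1e-10)
        assert res.se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)

    def test_flagged_degenerate_cases(self):
        win = make_window([make_annotation(100, "a")])
        const = make_cohort({"a": [1.0, 1.0, 1.0]}, [0, 1, 0])
        res = fit_dosage_regression(DosageScore(win, const.dosages["a"].to_numpy()), const)
        assert res.flag == "monomorphic window" and np.isnan(res.beta)
        onecls = make_cohort({"a": [0.0, 1.0, 2.0]}, [1, 1, 1])
        res = fit_dosage_regression(DosageScore(win, onecls.dosages["a"].to_numpy()), onecls)
        assert res.flag == "degenerate phenotype"

    def test_single_member_window_equals_single_snp_wald(self, rng):
        n = 300
        d = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 0.5, n)
        win = make_window([make_annotation(100, "a")])
        cohort = make_cohort({"a": d}, y)
        res = fit_dosage_regression(compute_cpg_dosage(win, cohort), cohort)
        import statsmodels.api as sm

        fit = sm.Logit(np.asarray(y, float),
                       np.column_stack([np.ones(n), d])).fit(disp=0, cov_type="HC0")
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(fit.tvalues[1])), rel=1e-8)


class TestScoreStats:
    def test_zero_residuals_give_zero_scores(self):
        win = make_window([make_annotation(100, "a")])
        cohort = make_cohort({"a": [0.0, 1.0, 2.0, 1.0]}, [0.5] * 4, binary=False)
        ss = compute_score_stats(win, cohort)
        assert np.allclose(ss.U, 0.0)

    def test_direct_formula_no_covariates(self, rng):
        n = 50
        G = rng.binomial(2, [0.3, 0.4], size=(n, 2)).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        win = make_window([make_annotation(100, "a"), make_annotation(200, "b")])
        cohort = make_cohort({"a": G[:, 0], "b": G[:, 1]}, y)
        ss = compute_score_stats(win, cohort)
        mu = y.mean()
        assert np.allclose(ss.U, G.T @ (y - mu))
        w = mu * (1 - mu)
        X = np.ones((n, 1))
        V = w * (G.T @ G) - w**2 * (G.T @ X) @ np.linalg.inv(w * X.T @ X) @ (X.T @ G)
        assert np.allclose(ss.V, V)

    def test_duplication_doubles_scores(self, rng):
        n = 80
        G = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        win = make_window([make_annotation(100, "a"), make_annotation(200, "b")])
        c1 = make_cohort({"a": G[:, 0], "b": G[:, 1]}, y)
        c2 = make_cohort({"a": np.tile(G[:, 0], 2), "b": np.tile(G[:, 1], 2)},
                         np.tile(y, 2))
        s1, s2 = compute_score_stats(win, c1), compute_score_stats(win, c2)
        assert np.allclose(2 * s1.U, s2.U)
        assert np.allclose(2 * s1.V, s2.V, atol=1e-8)

    def test_wald_and_score_pvalues_agree_asymptotically(self, rng):
        """Burden score test and dosage Wald test track each other under the null."""
        n, sims = 800, 200
        wald_p, score_p = [], []
        win = make_window([make_annotation(100, "a"), make_annotation(200, "b")])
        for _ in range(sims):
            G = rng.binomial(2, [0.3, 0.35], size=(n, 2)).astype(float)
            y = rng.binomial(1, 0.5, n)
            cohort = make_cohort({"a": G[:, 0], "b": G[:, 1]}, y)
            res = fit_dosage_regression(compute_cpg_dosage(win, cohort), cohort)
            ss = compute_score_stats(win, cohort)
            u = float(ss.U.sum())
            v = float(np.ones(2) @ ss.V @ np.ones(2))
            wald_p.append(res.p)
            score_p.append(stats.chi2.sf(u**2 / v, 1))
        assert np.corrcoef(wald_p, score_p)[0, 1] > 0.99


class TestLdR2:
    def test_identity_and_complement(self, rng):
        a = rng.binomial(2, 0.3, 100).astype(float)
        assert ld_r2(a, a) == pytest.approx(1.0)
        assert ld_r2(a, 2.0 - a) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self, rng):
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert ld_r2(a, b) < 0.01

    def test_constant_vector_flagged(self):
        assert np.isnan(ld_r2([1.0] * 10, list(range(10))))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ld_r2([1.0, 2.0], [1.0])
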