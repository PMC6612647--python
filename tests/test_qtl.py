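"""mQTL/eQTL window tests, residualization, the expression scan, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgwas.qtl import (OmicsMatrix, fit_window_qtl, hypergeometric_enrichment,
                       methylation_expression_scan, read_gmt, residualize_lmm)
from cgwas.windows import Window


def _ols_resid(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


class TestResidualize:
    def test_single_group_equals_ols(self, rng):
        n = 60
        y = rng.normal(size=n)
        cov = pd.DataFrame({"age": rng.normal(50, 5, n)})
        res = residualize_lmm(y, cov, np.zeros(n))
        X = np.column_stack([np.ones(n), cov["age"]])
        assert np.allclose(res, _ols_resid(y, X))

    def test_zero_group_variance_matches_ols(self, rng):
        n, k = 300, 6
        groups = np.repeat(np.arange(k), n // k)
        y = rng.normal(size=n)  # no group structure at all
        res = residualize_lmm(y, None, groups)
        assert np.allclose(res, y - y.mean(), atol=2e-3)

    def test_balanced_two_group_matches_closed_form_reml(self, rng):
        """Intercept-only balanced one-way REML has closed-form components."""
        k, per = 2, 200
        groups = np.repeat(np.arange(k), per)
        effects = np.array([1.0, -1.0])
        y = effects[groups] + rng.normal(0, 0.5, k * per)
        res = residualize_lmm(y, None, groups)
        # closed-form REML for balanced one-way layout
        gmeans = np.array([y[groups == j].mean() for j in range(k)])
        grand = y.mean()
        mse = sum(((y[groups == j] - gmeans[j]) ** 2).sum() for j in range(k)) / (k * per - k)
        msb = per * ((gmeans - grand) ** 2).sum() / (k - 1)
        sigma_b2 = max((msb - mse) / per, 0.0)
        shrink = per * sigma_b2 / (mse + per * sigma_b2)
        blup = shrink * (gmeans - grand)
        expected = y - grand - blup[groups]
        assert np.allclose(res, expected, atol=1e-5)


def _make_omics(rng, n=200, n_probes=6, chrom="chr1", positions=None,
                covariates=True):
    subjects = [f"s{i}" for i in range(n)]
    if positions is None:
        positions = np.linspace(10_000, 3_000_000, n_probes).astype(int)
    probes = [f"cg{i}" for i in range(n_probes)]
    vals = pd.DataFrame(rng.normal(0.5, 0.02, (n_probes, n)),
                        index=probes, columns=subjects)
    cov = pd.DataFrame({"age": rng.normal(70, 5, n),
                        "sex": rng.integers(0, 2, n).astype(float)},
                       index=subjects) if covariates else None
    feats = pd.DataFrame({"id": probes, "chrom": chrom, "pos": positions})
    return OmicsMatrix(features=feats, values=vals, covariates=cov)


class TestWindowQtl:
    def test_cis_scope_one_megabase_inclusive(self, rng):
        win = Window("chr1", 1_000_001, 1_001_000, [])
        # distances from the nearest boundary: inside, 1 Mb exactly, 1 Mb + 1
        positions = [1_000_500, 1_000_001 - 1_000_000, 1_001_000 + 1_000_000,
                     1_000_001 - 1_000_001, 1_001_000 + 1_000_001]
        omics = _make_omics(rng, n=50, n_probes=5, positions=positions)
        dosage = pd.Series(rng.binomial(2, 0.3, 50).astype(float),
                           index=omics.subjects)
        results = fit_window_qtl(win, dosage, omics, mode="mqtl_linear")
        kept = {r.feature_id for r in results}
        assert kept == {"cg0", "cg1", "cg2"}
        assert all(r.n_tests_in_correction == 3 for r in results)

    def test_bonferroni_arithmetic(self, rng):
        win = Window("chr1", 1, 1000, [])
        omics = _make_omics(rng, n=80, n_probes=4,
                            positions=[100, 500, 900, 950])
        dosage = pd.Series(rng.binomial(2, 0.3, 80).astype(float),
                           index=omics.subjects)
        for r in fit_window_qtl(win, dosage, omics, mode="mqtl_linear"):
            assert r.p_corrected == pytest.approx(min(1.0, r.p_nominal * 4))

    def test_bonferroni_monotone_in_scope(self, rng):
        win = Window("chr1", 1, 1000, [])
        dosage = pd.Series(rng.binomial(2, 0.3, 80).astype(float),
                           index=[f"s{i}" for i in range(80)])
        narrow = _make_omics(rng, n=80, n_probes=2, positions=[100, 500])
        wide = _make_omics(rng, n=80, n_probes=8,
                           positions=[100, 500, 600, 700, 750, 800, 850, 900])
        narrow.values.iloc[0] = wide.values.iloc[0]
        p_narrow = fit_window_qtl(win, dosage, narrow, mode="mqtl_linear")[0]
        p_wide = fit_window_qtl(win, dosage, wide, mode="mqtl_linear")[0]
        assert p_wide.p_corrected >= p_narrow.p_corrected - 1e-12

    def test_injected_effect_detected_across_seeds(self):
        """Probe with beta 0.005, noise SD 0.01, n 700 survives a 176-probe
        Bonferroni correction in nearly every replicate."""
        detected = 0
        seeds = 50
        n, n_probes = 700, 176
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            win = Window("chr1", 1, 1000, [])
            D = (rng.binomial(2, 0.36, n) + rng.binomial(2, 0.36, n)).astype(float)
            subjects = [f"s{i}" for i in range(n)]
            positions = np.linspace(100, 900_000, n_probes).astype(int)
            probes = [f"cg{i}" for i in range(n_probes)]
            vals = rng.normal(0.5, 0.01, (n_probes, n))
            vals[0] += 0.005 * D
            omics = OmicsMatrix(
                features=pd.DataFrame({"id": probes, "chrom": "chr1",
                                       "pos": positions}),
                values=pd.DataFrame(vals, index=probes, columns=subjects),
            )
            dosage = pd.Series(D, index=subjects)
            results = {r.feature_id: r
                       for r in fit_window_qtl(win, dosage, omics, mode="mqtl_linear")}
            assert results["cg0"].n_tests_in_correction == n_probes
            if results["cg0"].p_corrected < 0.05:
                detected += 1
        assert detected / seeds >= 0.95

    def test_two_stage_matches_joint_when_orthogonal(self, rng):
        """With batch covariates orthogonal to dosage, two-stage beta tracks
        the single-model beta."""
        n = 400
        subjects = [f"s{i}" for i in range(n)]
        batch = np.repeat(np.arange(4), n // 4)
        D = rng.binomial(2, 0.3, n) + rng.binomial(2, 0.3, n).astype(float)
        D = D - D.mean()
        batch_eff = np.array([0.3, -0.1, 0.2, -0.4])
        y = 0.05 * D + batch_eff[batch] + rng.normal(0, 0.05, n)
        omics = OmicsMatrix(
            features=pd.DataFrame({"id": ["cg0"], "chrom": "chr1", "pos": [500]}),
            values=pd.DataFrame(y[None, :], index=["cg0"], columns=subjects),
            groups=pd.DataFrame({"batch": batch, "family": np.arange(n)},
                                index=subjects),
        )
        dosage = pd.Series(D, index=subjects)
        win = Window("chr1", 1, 1000, [])
        two_stage = fit_window_qtl(win, dosage, omics, mode="mqtl_two_stage")[0]
        # joint model: y ~ dosage + batch dummies
        X = np.column_stack([np.ones(n), D] +
                            [(batch == b).astype(float) for b in range(1, 4)])
        import statsmodels.api as sm

        joint = sm.OLS(y, X).fit()
        assert two_stage.beta == pytest.approx(joint.params[1], rel=1e-2)


class TestScan:
    def _expr(self, rng, n, genes):
        subjects = [f"s{i}" for i in range(n)]
        vals = pd.DataFrame(genes, columns=subjects)
        feats = pd.DataFrame({"id": list(vals.index), "chrom": "chr1",
                              "pos": np.arange(len(vals)) * 1000 + 1})
        return OmicsMatrix(features=feats, values=vals)

    def test_low_detection_genes_removed(self, rng):
        n = 100
        expressed = np.abs(rng.normal(5, 1, n))
        sparse = np.zeros(n)
        sparse[:9] = 1.0  # 9% detection
        vals = pd.DataFrame([expressed, sparse], index=["gene_ok", "gene_sparse"],
                            columns=[f"s{i}" for i in range(n)])
        omics = OmicsMatrix(
            features=pd.DataFrame({"id": ["gene_ok", "gene_sparse"],
                                   "chrom": "chr1", "pos": [1, 2]}),
            values=vals)
        probe = pd.Series(rng.normal(0.5, 0.02, n), index=vals.columns)
        res = methylation_expression_scan(probe, omics)
        assert set(res["gene"]) == {"gene_ok"}
        assert res.attrs["n_removed"] == 1

    def test_null_selection_rate(self, rng):
        n, n_genes = 300, 2000
        vals = pd.DataFrame(np.abs(rng.normal(5, 1, (n_genes, n))),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(n)])
        omics = OmicsMatrix(
            features=pd.DataFrame({"id": vals.index, "chrom": "chr1",
                                   "pos": np.arange(n_genes) + 1}),
            values=vals)
        probe = pd.Series(rng.normal(0.5, 0.02, n), index=vals.columns)
        res = methylation_expression_scan(probe, omics)
        frac = res["selected"].mean()
        # binomial CI around the nominal 0.005 selection rate
        se = np.sqrt(0.005 * 0.995 / n_genes)
        assert abs(frac - 0.005) <= 4 * se
        assert res.attrs["n_retained"] == n_genes

    def test_true_association_selected(self):
        hits = 0
        seeds = 100
        n = 580
        for seed in range(seeds):
            rng = np.random.default_rng(seed)
            probe = rng.normal(0.5, 0.05, n)
            # R^2 = 0.05 target
            signal = (probe - probe.mean()) / probe.std()
            y = np.sqrt(0.05) * signal + np.sqrt(0.95) * rng.normal(size=n) + 5
            vals = pd.DataFrame(y[None, :], index=["g0"],
                                columns=[f"s{i}" for i in range(n)])
            omics = OmicsMatrix(
                features=pd.DataFrame({"id": ["g0"], "chrom": "c", "pos": [1]}),
                values=vals)
            res = methylation_expression_scan(
                pd.Series(probe, index=vals.columns), omics)
            hits += bool(res["selected"].iloc[0])
        assert hits / seeds >= 0.90

    def test_constant_probe_rejected(self, rng):
        omics = _make_omics(rng, n=30, n_probes=1)
        probe = pd.Series(np.full(30, 0.5), index=omics.values.columns)
        with pytest.raises(ValueError):
            methylation_expression_scan(probe, omics)


class TestEnrichment:
    def test_exact_tail_enumeration(self):
        bg = [f"g{i}" for i in range(20)]
        term = bg[:5]
        fg = bg[:3] + bg[10:12]  # 3 of 5 selected genes hit the term
        res = hypergeometric_enrichment(fg, {"T": term}, bg)[0]
        assert res.hits == 3 and res.term_size == 5
        assert res.p_hyper == pytest.approx(1126 / 15504, rel=1e-12)

    def test_zero_hits_gives_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        res = hypergeometric_enrichment(bg[10:12], {"T": bg[:5]}, bg)[0]
        assert res.p_hyper == pytest.approx(1.0)

    def test_single_term_fdr_equals_p(self):
        bg = [f"g{i}" for i in range(30)]
        res = hypergeometric_enrichment(bg[:4], {"T": bg[:10]}, bg)[0]
        assert res.fdr == pytest.approx(res.p_hyper)

    def test_bh_fdr_monotone_in_rank(self, rng):
        bg = [f"g{i}" for i in range(200)]
        fg = list(rng.choice(bg, size=30, replace=False))
        terms = {f"T{j}": list(rng.choice(bg, size=rng.integers(5, 40), replace=False))
                 for j in range(25)}
        results = hypergeometric_enrichment(fg, terms, bg)
        fdrs = [r.fdr for r in results]  # sorted ascending by p
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))
        assert all(r.fdr >= r.p_hyper - 1e-12 for r in results)

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["x"], {"T": ["a"]}, ["a", "b"])

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("TERM1\tdesc\tg1\tg2\tg3\nTERM2\tdesc\tg4\n")
        terms = read_gmt(str(path))
        assert terms == {"TERM1": ["g1", "g2", "g3"], "TERM2": ["g4"]}
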