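"""Window-level mQTL/eQTL tests, the expression-methylation scan, and
hypergeometric gene-set enrichment.

The mQTL/eQTL exposure is the window CpG dosage.  Family-based cohort data
are handled with a two-stage scheme: methylation is first residualized on
technical covariates with a batch (chip) random intercept, then the
residual is regressed on the dosage with a family random intercept.
Unrelated-cohort data use ordinary linear models.  mQTL p-values are
Bonferroni-corrected by the number of probes within 1 Mb of the window;
eQTL p-values by the number of genes tested in the run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

CIS_DISTANCE = 1_000_000
DETECT_FRACTION = 0.10
SCAN_SELECT_P = 0.005


@dataclass
class OmicsMatrix:
    """Feature-by-subject omics values with positions and covariates.

    ``features``: DataFrame with columns id, chrom, pos (1-based).
    ``values``: DataFrame indexed by feature id, columns are subject ids.
    ``covariates``: subject-level fixed covariates (index = subject id).
    ``groups``: subject-level grouping factors for random intercepts
    (e.g. columns 'batch', 'family').
    """

    features: pd.DataFrame
    values: pd.DataFrame
    covariates: Optional[pd.DataFrame] = None
    groups: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = set(self.values.index) - set(self.features["id"])
        if missing:
            raise ValueError(f"features missing positions: {sorted(missing)[:5]}")

    @property
    def subjects(self) -> List[str]:
        return list(self.values.columns)


@dataclass
class QtlResult:
    window: object
    feature_id: str
    beta: float
    se: float
    p_nominal: float
    p_corrected: float
    n_tests_in_correction: int
    flag: Optional[str] = None


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int
    hits: int
    background: int
    selected: int
    p_hyper: float
    fdr: float
    hit_genes: List[str] = field(default_factory=list)


def residualize_lmm(
    values: Sequence[float],
    fixed_covariates: Optional[pd.DataFrame] = None,
    random_grouping: Optional[Sequence] = None,
) -> np.ndarray:
    """Residuals of one feature after fixed covariates and a random intercept.

    The random-intercept model is fit by REML; residuals are conditional
    (both the fixed-effect fit and the group BLUPs are subtracted), so batch
    offsets are removed.  With fewer than two group levels, or on
    non-convergence, ordinary least-squares residuals are returned.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if fixed_covariates is not None and fixed_covariates.shape[1] > 0:
        X = np.column_stack([np.ones(n), fixed_covariates.to_numpy(dtype=float)])
    else:
        X = np.ones((n, 1))

    def _ols_resid() -> np.ndarray:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    if random_grouping is None:
        return _ols_resid()
    groups = np.asarray(random_grouping)
    if len(np.unique(groups)) < 2:
        return _ols_resid()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            fit = model.fit(reml=True, method="lbfgs")
        fitted_fixed = X @ fit.fe_params
        blups = fit.random_effects
        re = np.array([float(np.asarray(blups[g]).ravel()[0]) for g in groups])
        return y - fitted_fixed - re
    except Exception:  # pragma: no cover - statsmodels failure modes vary
        logger.warning("residualize_lmm: REML fit failed, falling back to OLS residuals")
        return _ols_resid()


def bonferroni(p_nominal: float, n_tests: int) -> float:
    """Bonferroni-corrected p: nominal p times the number of tests, capped at 1."""
    return min(1.0, p_nominal * n_tests)


def _window_distance(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """Distance from positions to the nearest window boundary (0 inside)."""
    return np.where(
        pos < start, start - pos, np.where(pos > end, pos - end, 0)
    )


def _dosage_fit(y, dosage, covariates, groups=None):
    """beta/se/p of the dosage term in y ~ dosage + covariates (+ family RE)."""
    n = len(y)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else np.empty((n, 0))
    X = np.column_stack([np.ones(n), np.asarray(dosage, dtype=float), cov])
    if groups is not None and len(np.unique(groups)) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(np.asarray(y, float), X, groups=np.asarray(groups)).fit(
                reml=True, method="lbfgs"
            )
        beta, se = float(fit.fe_params[1]), float(fit.bse_fe[1])
        return beta, se, float(2.0 * stats.norm.sf(abs(beta / se)))
    fit = sm.OLS(np.asarray(y, float), X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def fit_window_qtl(
    window,
    dosage_score: pd.Series,
    omics: OmicsMatrix,
    mode: str = "mqtl_linear",
    feature_ids: Optional[Sequence[str]] = None,
    cis_distance: int = CIS_DISTANCE,
    stage1_covariates: Optional[Sequence[str]] = None,
) -> List[QtlResult]:
    """Window-level QTL tests against omics features.

    ``dosage_score`` is the per-subject CpG dosage indexed by subject id.
    mQTL modes test all probes within ``cis_distance`` of the nearest window
    boundary and Bonferroni-correct by that probe count; eQTL modes test the
    named ``feature_ids`` and correct by the number of genes tested.

    Modes: ``mqtl_two_stage`` (stage-1 batch-random-intercept
    residualization, stage-2 dosage regression with family random
    intercept), ``mqtl_linear``, ``eqtl_linear``, ``eqtl_skato``.
    """
    subjects = [s for s in omics.subjects if s in dosage_score.index]
    if len(subjects) < len(omics.subjects):
        logger.info("fit_window_qtl: %d subjects lack dosage data",
                    len(omics.subjects) - len(subjects))
    dosage = dosage_score.loc[subjects].to_numpy(dtype=float)
    covars = omics.covariates.loc[subjects] if omics.covariates is not None else None
    groups = omics.groups.loc[subjects] if omics.groups is not None else None

    if mode.startswith("mqtl"):
        feats = omics.features
        if window.chrom is not None:
            feats = feats[feats["chrom"] == window.chrom]
        dist = _window_distance(feats["pos"].to_numpy(), window.start, window.end)
        selected = feats.loc[dist <= cis_distance, "id"].tolist()
    else:
        selected = list(feature_ids) if feature_ids is not None else list(omics.values.index)
    n_tests = len(selected)
    if n_tests == 0:
        logger.info("fit_window_qtl: empty feature selection for window %s", window.key)
        return []

    results: List[QtlResult] = []
    for fid in selected:
        y = omics.values.loc[fid, subjects].to_numpy(dtype=float)
        if mode == "mqtl_two_stage":
            batch = groups["batch"].to_numpy() if groups is not None and "batch" in groups else None
            fam = groups["family"].to_numpy() if groups is not None and "family" in groups else None
            s1_cols = list(stage1_covariates) if stage1_covariates else []
            s1_cov = covars[s1_cols] if (covars is not None and s1_cols) else None
            s2_cov = covars.drop(columns=s1_cols, errors="ignore") if covars is not None else None
            resid = residualize_lmm(y, s1_cov, batch)
            beta, se, p = _dosage_fit(resid, dosage, s2_cov, fam)
        elif mode in ("mqtl_linear", "eqtl_linear"):
            beta, se, p = _dosage_fit(y, dosage, covars)
        elif mode == "eqtl_skato":
            beta, se, p = _eqtl_skato(window, y, covars, dosage_score, subjects)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        results.append(QtlResult(
            window=window, feature_id=fid, beta=beta, se=se, p_nominal=p,
            p_corrected=bonferroni(p, n_tests), n_tests_in_correction=n_tests,
        ))
    return results


def _eqtl_skato(window, y, covars, dosage_score, subjects):
    """SKAT-O of window members against a quantitative expression trait."""
    from .association import CohortData, compute_score_stats
    from .skato import two_stage_window_pvalue

    member_dosages = getattr(window, "member_dosage_frame", None)
    if member_dosages is None:
        raise ValueError("eqtl_skato mode needs per-member dosages on the window "
                         "(attribute 'member_dosage_frame')")
    cohort = CohortData(
        cohort_id="omics", dosages=member_dosages.loc[subjects],
        phenotype=np.asarray(y, float), covariates=covars, binary=False,
    )
    ss = compute_score_stats(window, cohort)
    res = two_stage_window_pvalue(ss)
    return float("nan"), float("nan"), res.p_overall


def methylation_expression_scan(
    cpg_values: pd.Series,
    expression: OmicsMatrix,
    covariates: Optional[pd.DataFrame] = None,
    detect_fraction: float = DETECT_FRACTION,
    select_p: float = SCAN_SELECT_P,
) -> pd.DataFrame:
    """Genome-wide scan of gene expression on one methylation probe.

    Genes detected (value > 0) in fewer than ``detect_fraction`` of subjects
    are removed; each remaining gene is regressed on the probe value with
    covariates.  The returned frame has per-gene beta/se/p, a ``retained``
    count attribute, and a ``selected`` boolean column marking the
    enrichment foreground (p < ``select_p``).
    """
    subjects = [s for s in expression.subjects if s in cpg_values.index]
    probe = cpg_values.loc[subjects].to_numpy(dtype=float)
    if np.ptp(probe) < 1e-12:
        raise ValueError("probe values are constant")
    covars = covariates.loc[subjects] if covariates is not None else None
    vals = expression.values[subjects]
    detect = (vals > 0).mean(axis=1)
    retained = vals.loc[detect >= detect_fraction]
    rows = []
    for gid, y in retained.iterrows():
        beta, se, p = _dosage_fit(y.to_numpy(dtype=float), probe, covars)
        rows.append((gid, beta, se, p))
    out = pd.DataFrame(rows, columns=["gene", "beta", "se", "p"])
    out["selected"] = out["p"] < select_p
    out.attrs["n_retained"] = len(retained)
    out.attrs["n_removed"] = int((detect < detect_fraction).sum())
    return out


def read_gmt(path: str) -> Dict[str, List[str]]:
    """Parse a GMT gene-set file (term, description, genes...)."""
    terms: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = [g for g in parts[2:] if g]
    return terms


def hypergeometric_enrichment(
    foreground: Sequence[str],
    term_sets: Dict[str, Sequence[str]],
    background: Sequence[str],
) -> List[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment per term with BH FDR across terms.

    p = P(X >= k) with N background genes, K in the term, n selected.
    Terms are intersected with the background; results sorted ascending by p.
    """
    bg = set(background)
    fg = set(foreground)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    N, n = len(bg), len(fg)
    results = []
    for term, genes in term_sets.items():
        term_genes = set(genes) & bg
        K = len(term_genes)
        hit_genes = sorted(term_genes & fg)
        k = len(hit_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if (n and K) else 1.0
        results.append(EnrichmentResult(
            term_id=term, term_size=K, hits=k, background=N, selected=n,
            p_hyper=min(p, 1.0), fdr=np.nan, hit_genes=hit_genes,
        ))
    if results:
        from statsmodels.stats.multitest import multipletests

        pvals = [r.p_hyper for r in results]
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return sorted(results, key=lambda r: r.p_hyper)


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        (r.term_id, r.term_size, r.hits, r.selected, r.background, r.p_hyper, r.fdr,
         ",".join(r.hit_genes))
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "term", "term_size", "hits", "selected", "background", "p", "fdr", "hit_genes",
    ])
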