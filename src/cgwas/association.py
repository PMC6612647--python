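"""Per-cohort window association statistics.

The window exposure is the CpG dosage: for each individual, the sum over
window member CGSes of the imputed dosage of the CpG-creating effect
allele.  When a member's effect allele is the VCF ALT allele the dosage
contributes directly; when it is the REF allele the contribution is
2 - dosage, so the exposure is invariant to how the VCF happens to orient
each site.

Two window tests are provided: a dose-response regression of the trait on
the CpG dosage (logistic for case-control, linear for quantitative traits)
with heteroskedasticity-robust (HC0 sandwich) standard errors, and the
score statistics (U, V) of the window members under the covariates-only
null model, which feed SKAT-O and the score-statistic meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .skato import ScoreStats
from .windows import Window

logger = logging.getLogger(__name__)


class AssociationError(ValueError):
    pass


@dataclass
class CohortData:
    """One cohort's aligned genotype dosages, trait, and covariates.

    ``dosages`` holds the expected ALT-allele count in [0, 2] per individual
    and variant (columns are variant ids).  ``effect_is_alt`` records, for
    each variant, whether the CpG-creating allele is the ALT allele.
    """

    cohort_id: str
    dosages: pd.DataFrame
    phenotype: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    effect_is_alt: Optional[pd.Series] = None
    binary: bool = True

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if np.any(np.isnan(self.phenotype)):
            raise AssociationError(f"cohort {self.cohort_id}: missing phenotype values")
        if len(self.phenotype) != len(self.dosages):
            raise AssociationError(f"cohort {self.cohort_id}: phenotype/dosage length mismatch")
        d = self.dosages.to_numpy()
        if d.size and (d.min() < -1e-9 or d.max() > 2 + 1e-9):
            raise AssociationError(f"cohort {self.cohort_id}: dosages outside [0, 2]")

    @property
    def n(self) -> int:
        return len(self.phenotype)

    def covariate_matrix(self) -> np.ndarray:
        """Design matrix of covariates with intercept prepended."""
        n = self.n
        if self.covariates is None or self.covariates.shape[1] == 0:
            return np.ones((n, 1))
        X = np.column_stack([np.ones(n), self.covariates.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise AssociationError(f"cohort {self.cohort_id}: covariate matrix not full rank")
        return X


@dataclass
class DosageScore:
    window: Window
    values: np.ndarray  # per-individual CpG dosage D_i


@dataclass
class DosageTestResult:
    window: Window
    cohort_id: str
    beta: float
    se: float
    z: float
    p: float
    n: int
    flag: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.flag is None and np.isfinite(self.beta) and self.se > 0


def oriented_dosages(window: Window, cohort: CohortData) -> np.ndarray:
    """n x m matrix of effect-allele (CpG-creating) dosages for window members."""
    cols = []
    for member in window.members:
        vid = member.variant.id
        if vid not in cohort.dosages.columns:
            raise AssociationError(
                f"window {window.key}: member {vid} absent from cohort {cohort.cohort_id}"
            )
        d = cohort.dosages[vid].to_numpy(dtype=float)
        if cohort.effect_is_alt is not None:
            is_alt = bool(cohort.effect_is_alt.get(vid, True))
        else:
            is_alt = member.effect_allele == member.variant.alt_allele
        cols.append(d if is_alt else 2.0 - d)
    return np.column_stack(cols)


def compute_cpg_dosage(window: Window, cohort: CohortData) -> DosageScore:
    """Per-individual CpG dosage: sum of effect-allele dosages over members."""
    G = oriented_dosages(window, cohort)
    return DosageScore(window=window, values=G.sum(axis=1))


def fit_dosage_regression(
    score: DosageScore,
    cohort: CohortData,
    family: Optional[str] = None,
) -> DosageTestResult:
    """Trait ~ intercept + CpG dosage + covariates, with HC0 sandwich SEs.

    Logistic regression (maximum likelihood) for binary traits, least
    squares for quantitative traits.  Separation or non-convergence yields
    a flagged NA result rather than an exception.
    """
    if family is None:
        family = "binary" if cohort.binary else "quantitative"
    D = score.values
    window, n = score.window, cohort.n
    if np.ptp(D) < 1e-12:
        return DosageTestResult(window, cohort.cohort_id, np.nan, np.nan, np.nan, np.nan,
                                n, flag="monomorphic window")
    X = np.column_stack([cohort.covariate_matrix(), D])
    j = X.shape[1] - 1  # dosage column
    y = cohort.phenotype
    try:
        if family == "binary":
            if len(np.unique(y)) < 2:
                return DosageTestResult(window, cohort.cohort_id, np.nan, np.nan, np.nan,
                                        np.nan, n, flag="degenerate phenotype")
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, cov_type="HC0", maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                return DosageTestResult(window, cohort.cohort_id, np.nan, np.nan, np.nan,
                                        np.nan, n, flag="non-convergence")
        elif family == "quantitative":
            fit = sm.OLS(y, X).fit(cov_type="HC0")
        else:
            raise ValueError(f"unknown family {family!r}")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return DosageTestResult(window, cohort.cohort_id, np.nan, np.nan, np.nan, np.nan,
                                n, flag="separation")
    beta = float(fit.params[j])
    se = float(fit.bse[j])
    if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
        return DosageTestResult(window, cohort.cohort_id, np.nan, np.nan, np.nan, np.nan,
                                n, flag="unstable fit")
    z = beta / se
    from scipy.stats import norm

    p = float(2.0 * norm.sf(abs(z)))
    return DosageTestResult(window, cohort.cohort_id, beta, se, z, max(p, 5e-324), n)


def compute_score_stats(window: Window, cohort: CohortData) -> ScoreStats:
    """Score vector U and null covariance V of the window members.

    U = G'(y - yhat) from the covariates-only null fit; V = G'WG -
    G'WX (X'WX)^{-1} X'WG with W the null-model variance weights
    (yhat(1-yhat) for binary traits, the residual variance for linear).
    """
    G = oriented_dosages(window, cohort)
    X = cohort.covariate_matrix()
    y = cohort.phenotype
    n = cohort.n
    if cohort.binary:
        if X.shape[1] == 1:
            mu = np.full(n, y.mean())
        else:
            with np.errstate(all="ignore"):
                null_fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            mu = null_fit.predict(X)
        w = mu * (1.0 - mu)
    else:
        beta_null, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_null
        sigma2 = float(resid @ resid) / max(n - X.shape[1], 1)
        mu = X @ beta_null
        w = np.full(n, sigma2)
    U = G.T @ (y - mu)
    m_members = G.shape[1]
    if not np.any(w > 0):  # perfect null fit: scores carry no information
        return ScoreStats(window=window, cohort_id=cohort.cohort_id, U=U,
                          V=np.zeros((m_members, m_members)),
                          mafs=np.minimum(G.mean(axis=0) / 2.0, 1.0 - G.mean(axis=0) / 2.0),
                          n=n, member_ids=window.member_ids)
    GW = G * w[:, None]
    xtwx = X.T @ (X * w[:, None])
    try:
        xtwx_inv = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise AssociationError(
            f"singular weighted covariate cross-product in cohort {cohort.cohort_id}"
        ) from exc
    gwx = GW.T @ X
    V = GW.T @ G - gwx @ xtwx_inv @ gwx.T
    V = 0.5 * (V + V.T)
    freqs = G.mean(axis=0) / 2.0
    mafs = np.minimum(freqs, 1.0 - freqs)
    return ScoreStats(
        window=window, cohort_id=cohort.cohort_id, U=U, V=V, mafs=mafs, n=n,
        member_ids=window.member_ids,
    )


def ld_r2(dosages_a: Sequence[float], dosages_b: Sequence[float]) -> float:
    """Squared Pearson correlation between two dosage vectors (NaN if constant)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise AssociationError("dosage vectors differ in length")
    if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
        logger.warning("ld_r2: constant dosage vector, returning NaN")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def results_to_frame(results: Sequence[DosageTestResult]) -> pd.DataFrame:
    rows = [
        (r.window.chrom, r.window.start, r.window.end, r.cohort_id, r.n,
         r.window.n_members, r.beta, r.se, r.z, r.p, r.flag or "")
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "cohort", "n", "n_members", "beta", "se", "z", "p", "flag",
    ])
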