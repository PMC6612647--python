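"""Fixed-effects meta-analysis, genomic inflation, significance flags, GATES.

The dosage meta-analysis is METAL-style inverse-variance weighting of the
per-cohort coefficients.  Replication from summary statistics uses GATES,
which extends the Simes test: per-SNP p-values are combined with an
effective number of tests m_e derived from the eigenvalues of their
correlation matrix, itself obtained from genotype (LD) correlation through
a published sixth-order polynomial approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import DosageTestResult

logger = logging.getLogger(__name__)

GENOME_WIDE_THRESHOLD = 5e-8
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549364...


@dataclass
class MetaResult:
    window: object
    beta_meta: float
    se_meta: float
    z: float
    p: float
    n_cohorts: int
    n_total: int
    cohort_betas: List[float] = field(default_factory=list)
    cohort_ses: List[float] = field(default_factory=list)
    cohort_ids: List[str] = field(default_factory=list)
    het_q: float = float("nan")
    het_p: float = float("nan")
    flag: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.flag is None and np.isfinite(self.beta_meta)


def inverse_variance_meta(results: Sequence[DosageTestResult]) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling of cohort estimates.

    Flagged/NA cohorts are excluded (and counted); Cochran's Q
    heterogeneity is reported but never used for filtering.
    """
    usable = [r for r in results if r.ok]
    window = results[0].window if results else None
    if not usable:
        return MetaResult(window, np.nan, np.nan, np.nan, np.nan, 0, 0,
                          flag="no usable cohorts")
    betas = np.array([r.beta for r in usable])
    ses = np.array([r.se for r in usable])
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    z = beta_meta / se_meta
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (betas - beta_meta) ** 2))
    df = len(usable) - 1
    het_p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return MetaResult(
        window=window, beta_meta=beta_meta, se_meta=se_meta, z=z, p=max(p, 5e-324),
        n_cohorts=len(usable), n_total=int(np.sum([r.n for r in usable])),
        cohort_betas=list(betas), cohort_ses=list(ses),
        cohort_ids=[r.cohort_id for r in usable], het_q=q, het_p=het_p,
    )


# ---------------------------------------------------------------------------
# GATES

# Polynomial mapping genotype correlation r to p-value correlation
# (Li, Gui, Kwan & Sham 2011, GATES).
_GATES_POLY = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009, 0.0)


@dataclass
class GatesResult:
    window: object
    snp_pvalues: np.ndarray  # ascending
    m_e: float
    m_e_partial: np.ndarray  # m_e(j) per ascending-p prefix
    p_gates: float


def _pvalue_correlation(genotype_corr: np.ndarray) -> np.ndarray:
    r = np.asarray(genotype_corr, dtype=float)
    rp = np.polyval(_GATES_POLY, r)
    rp = np.where(np.abs(r) >= 1.0 - 1e-12, 1.0, rp)  # exact in the perfect-LD limit
    rp = np.clip(rp, 0.0, 1.0)
    np.fill_diagonal(rp, 1.0)
    return 0.5 * (rp + rp.T)


def _effective_tests(corr: np.ndarray) -> float:
    """m_e = m - sum over eigenvalues > 1 of (eigenvalue - 1)."""
    vals = np.linalg.eigvalsh(corr)
    if np.any(vals < -1e-8):
        logger.warning("GATES: p-value correlation not PSD; clipping eigenvalues at 0")
    vals = np.clip(vals, 0.0, None)
    m = corr.shape[0]
    return float(m - np.sum(vals[vals > 1.0] - 1.0))


def gates_combine(pvalues: Sequence[float], genotype_corr: np.ndarray, window=None) -> GatesResult:
    """Combine per-SNP p-values into a regional p-value (extended Simes).

    p_GATES = min_j m_e * p_(j) / m_e(j), with p_(j) the ascending p-values
    and m_e(j) the effective number of tests among the top j SNPs.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    corr = np.asarray(genotype_corr, dtype=float)
    m = p.shape[0]
    if corr.shape != (m, m):
        raise ValueError("correlation matrix shape does not match p-value count")
    if not np.allclose(corr, corr.T, atol=1e-8) or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("genotype correlation must be symmetric with unit diagonal")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    rp = _pvalue_correlation(corr[np.ix_(order, order)])
    m_e = _effective_tests(rp)
    m_e_partial = np.array([_effective_tests(rp[: j + 1, : j + 1]) for j in range(m)])
    p_gates = float(np.min(m_e * p_sorted / m_e_partial))
    p_gates = min(max(p_gates, float(p_sorted[0])), 1.0)
    return GatesResult(window=window, snp_pvalues=p_sorted, m_e=m_e,
                       m_e_partial=m_e_partial, p_gates=p_gates)


# ---------------------------------------------------------------------------
# diagnostics and flags


def genomic_lambda(pvalues: Sequence[float]) -> float:
    """Genomic inflation factor: median association chi2 over the null chi2_1 median."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0):
        logger.warning("genomic_lambda: clipping %d p-values at the smallest positive float",
                       int(np.sum(p <= 0)))
        p = np.maximum(p, 5e-324)
    chi2_stats = stats.chi2.isf(p, 1)
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)


def flag_significant(
    results: pd.DataFrame,
    threshold: float = GENOME_WIDE_THRESHOLD,
    skato_col: str = "p_skato",
    dosage_col: str = "p_dosage_meta",
) -> pd.DataFrame:
    """Genome-wide significance flags per method plus their conjunction."""
    out = results.copy()
    out["sig_skato"] = out[skato_col] <= threshold
    out["sig_dosage"] = out[dosage_col] <= threshold
    out["sig_both"] = out["sig_skato"] & out["sig_dosage"]
    return out


def meta_to_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        win = r.window
        rows.append((win.chrom, win.start, win.end, r.n_cohorts, r.n_total,
                     r.beta_meta, r.se_meta, r.z, r.p, r.het_q, r.het_p, r.flag or ""))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_cohorts", "n_total", "beta_meta", "se_meta",
        "z", "p", "het_q", "het_p", "flag",
    ])


def forest_table(result: MetaResult) -> pd.DataFrame:
    """Per-cohort estimates with 95% CIs plus the pooled row (forest-plot table)."""
    z975 = stats.norm.ppf(0.975)
    rows = [
        (cid, b, s, b - z975 * s, b + z975 * s)
        for cid, b, s in zip(result.cohort_ids, result.cohort_betas, result.cohort_ses)
    ]
    rows.append(("meta", result.beta_meta, result.se_meta,
                 result.beta_meta - z975 * result.se_meta,
                 result.beta_meta + z975 * result.se_meta))
    return pd.DataFrame(rows, columns=["cohort", "beta", "se", "ci_low", "ci_high"])


def metal_summary_frame(results: Sequence[DosageTestResult], effect_allele: str = "CPG") -> pd.DataFrame:
    """METAL-compatible per-cohort summary rows (marker, effect allele, beta, SE, p, N)."""
    rows = [
        (f"{r.window.chrom}:{r.window.start}-{r.window.end}", effect_allele,
         r.beta, r.se, r.p, r.n, r.cohort_id)
        for r in results
    ]
    return pd.DataFrame(rows, columns=["MARKER", "EFFECT_ALLELE", "BETA", "SE", "P", "N", "COHORT"])
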