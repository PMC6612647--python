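"""End-to-end discovery pipeline: annotate -> windows -> per-cohort tests ->
meta-analysis and SKAT-O -> diagnostics and reports.

All stages are pure functions of their file inputs and the run
configuration; rerunning a configuration reproduces the result tables
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotation import AnnotationSummary, annotate_variants, annotations_to_frame
from .association import (CohortData, compute_cpg_dosage, compute_score_stats,
                          fit_dosage_regression, results_to_frame)
from .meta import (GENOME_WIDE_THRESHOLD, flag_significant, forest_table,
                   genomic_lambda, inverse_variance_meta, meta_to_frame)
from .skato import (DEFAULT_RHO_GRID, SCREEN_THRESHOLD, meta_combine_scores,
                    two_stage_window_pvalue)
from .windows import (MIN_COHORT_FRACTION, MIN_MEMBERS, R2_MIN, WINDOW_LENGTH,
                      WINDOW_OFFSET, assign_and_filter, build_window_grid,
                      windows_to_frame)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a discovery run."""

    study_dir: str
    out_dir: str = "cgwas_out"
    window_length: int = WINDOW_LENGTH
    window_offset: int = WINDOW_OFFSET
    min_members: int = MIN_MEMBERS
    r2_min: float = R2_MIN
    min_cohort_fraction: float = MIN_COHORT_FRACTION
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID
    screen_threshold: float = SCREEN_THRESHOLD
    significance_threshold: float = GENOME_WIDE_THRESHOLD
    member_class: str = "CGS"
    seed: int = 0
    extra_covariate_variants: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window_length % self.window_offset != 0:
            raise ValueError("window length must be a multiple of the offset")
        for t in (self.r2_min, self.screen_threshold, self.significance_threshold):
            if t <= 0:
                raise ValueError("thresholds must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    windows: pd.DataFrame  # per-window joined results
    per_cohort: pd.DataFrame
    lambda_skato: float
    lambda_dosage: float
    annotation_summary: AnnotationSummary
    forest_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _study_cohorts(study_dir: Path, effect_is_alt: pd.Series) -> List[CohortData]:
    from .simulate import load_cohort

    cohorts = []
    for vcf_path in sorted(study_dir.glob("cohort*.vcf")):
        cid = vcf_path.stem
        pheno = study_dir / f"{cid}.pheno.tsv"
        cohorts.append(load_cohort(str(vcf_path), str(pheno), cid, effect_is_alt))
    if not cohorts:
        raise FileNotFoundError(f"no cohort*.vcf files under {study_dir}")
    return cohorts


def run_discovery(config: RunConfig) -> DiscoveryResult:
    """Run the discovery stage over a study directory.

    Expects reference.fa, sites.vcf, and per-cohort cohort*.vcf /
    cohort*.pheno.tsv files (the layout the simulator emits).
    """
    from pyfaidx import Fasta

    t0 = time.time()
    study = Path(config.study_dir)
    logger.info("discovery run: thresholds r2>%.2f, coverage>=%.2f, >=%d members, "
                "screen p<=%.1e, significance p<=%.1e",
                config.r2_min, config.min_cohort_fraction, config.min_members,
                config.screen_threshold, config.significance_threshold)

    summary = AnnotationSummary()
    annotations = list(annotate_variants(str(study / "reference.fa"),
                                         str(study / "sites.vcf"), summary))
    fasta = Fasta(str(study / "reference.fa"))
    chrom_lengths = {name: len(fasta[name]) for name in fasta.keys()}

    n_cohorts_total = len(list(study.glob("cohort*.vcf"))) or 1
    grid = build_window_grid(chrom_lengths, config.window_length, config.window_offset)
    windows = assign_and_filter(
        grid, annotations, n_cohorts_total=n_cohorts_total, r2_min=config.r2_min,
        min_cohort_fraction=config.min_cohort_fraction,
        min_members=config.min_members, member_class=config.member_class,
    )
    if not windows:
        logger.warning("no windows survived the filters")
        empty = pd.DataFrame(columns=[
            "chrom", "start", "end", "n_members", "p_skato", "rho_opt", "method_used",
            "beta_meta", "se_meta", "z", "p_dosage_meta", "n_cohorts",
            "sig_skato", "sig_dosage", "sig_both"])
        return DiscoveryResult(empty, pd.DataFrame(), float("nan"), float("nan"), summary)

    effect_is_alt = pd.Series(
        {a.variant.id: (a.effect_allele == a.variant.alt_allele) if a.is_cgs else True
         for a in annotations})
    cohorts = _study_cohorts(study, effect_is_alt)
    if config.extra_covariate_variants:
        # conditional analysis: named single-variant dosages become covariates
        for cohort in cohorts:
            for vid in config.extra_covariate_variants:
                cohort.covariates[f"dosage_{vid}"] = cohort.dosages[vid].to_numpy()

    rows = []
    per_cohort_results = []
    forest_tables: Dict[str, pd.DataFrame] = {}
    for window in windows:
        cohort_results = []
        score_stats = []
        for cohort in cohorts:
            score = compute_cpg_dosage(window, cohort)
            cohort_results.append(fit_dosage_regression(score, cohort))
            score_stats.append(compute_score_stats(window, cohort))
        per_cohort_results.extend(cohort_results)
        meta_res = inverse_variance_meta(cohort_results)
        pooled = meta_combine_scores(score_stats)
        skato_res = two_stage_window_pvalue(
            pooled, rho_grid=config.rho_grid, screen_threshold=config.screen_threshold)
        rows.append((window.chrom, window.start, window.end, window.n_members,
                     skato_res.p_overall, skato_res.rho_opt, skato_res.method_used,
                     meta_res.beta_meta, meta_res.se_meta, meta_res.z, meta_res.p,
                     meta_res.n_cohorts))
        key = f"{window.chrom}:{window.start}-{window.end}"
        forest_tables[key] = forest_table(meta_res)

    results = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "n_members", "p_skato", "rho_opt", "method_used",
        "beta_meta", "se_meta", "z", "p_dosage_meta", "n_cohorts"])
    results = flag_significant(results, config.significance_threshold)
    ok_sk = results["p_skato"].dropna()
    ok_do = results["p_dosage_meta"].dropna()
    lam_sk = genomic_lambda(ok_sk) if len(ok_sk) else float("nan")
    lam_do = genomic_lambda(ok_do) if len(ok_do) else float("nan")
    logger.info("discovery finished: %d windows, lambda_skato=%.3f, lambda_dosage=%.3f "
                "(%.1f s)", len(results), lam_sk, lam_do, time.time() - t0)
    return DiscoveryResult(results, results_to_frame(per_cohort_results),
                           lam_sk, lam_do, summary, forest_tables)


def run_reports(result: DiscoveryResult, config: RunConfig) -> Dict[str, str]:
    """Write the TSV/JSON report bundle and the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = str(p)

    _write(result.windows, "window_results.tsv")
    _write(result.per_cohort, "per_cohort_results.tsv")
    top = result.windows.sort_values("p_dosage_meta").head(1)
    if len(top):
        key = f"{top.iloc[0]['chrom']}:{top.iloc[0]['start']}-{top.iloc[0]['end']}"
        if key in result.forest_tables:
            _write(result.forest_tables[key], "forest_top_window.tsv")
    manifest = {
        "package": "cgwas",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "lambda_skato": result.lambda_skato,
        "lambda_dosage": result.lambda_dosage,
        "n_windows": int(len(result.windows)),
        "annotation": {"n_cgs": result.annotation_summary.n_cgs,
                       "n_non_cgs": result.annotation_summary.n_non_cgs,
                       "n_skipped": result.annotation_summary.n_skipped},
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    paths["manifest.json"] = str(mpath)
    return paths
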