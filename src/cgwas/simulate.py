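"""Synthetic multi-cohort study generator.

Generates every input the pipeline consumes: a reference sequence with
variants planted in sequence contexts that make them CGS or non-CGS by
construction, multi-cohort case-control genotypes in Hardy-Weinberg
equilibrium with imputation-noise-degraded dosages, a logistic disease
model whose linear predictor contains window CpG-dosage terms, and
methylation/expression matrices with injected cis-QTL effects plus batch
and family random intercepts.

Default study conditions mirror the discovery design this pipeline is
built for: 24 case-control cohorts at roughly 50% cases (about a thousand
subjects each at desk scale), common CGSes with MAFs in the range of the
reported top windows (0.25-0.39), window log-odds effects per CpG
dinucleotide of order -0.02 to 0.2, and well-imputed dosages (r2 near 1).
Every artifact is a pure, seeded function of the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .association import CohortData
from .qtl import OmicsMatrix

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic study."""

    seed: int = 0
    # genome / variants
    chrom: str = "chr1"
    chrom_length: int = 50_000
    gc_content: float = 0.41
    variant_density: float = 4.0  # variants per kb
    cgs_fraction: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    r2_low: float = 1.0
    r2_high: float = 1.0
    # cohorts / disease model
    n_cohorts: int = 24
    n_per_cohort: int = 1000
    case_fraction: float = 0.5
    effect_windows: Dict[int, float] = field(default_factory=dict)  # window start -> beta
    age_beta: float = 0.0
    sex_beta: float = 0.0
    n_pcs: int = 3
    pc_beta: float = 0.0
    cohort_beta_sd: float = 0.0  # per-cohort perturbation of window betas
    # omics
    n_omics_subjects: int = 700
    n_probes: int = 40
    n_genes: int = 20
    omics_effect_window: Optional[int] = None  # window start driving cis effects
    mqtl_gammas: Dict[int, float] = field(default_factory=dict)  # probe index -> gamma
    eqtl_gammas: Dict[int, float] = field(default_factory=dict)  # gene index -> gamma
    meth_noise_sd: float = 0.01
    expr_noise_sd: float = 1.0
    expr_baseline: float = 5.0
    expr_dropout: float = 0.2
    n_batches: int = 4
    batch_sd: float = 0.05
    family_size: int = 2
    family_sd: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.gc_content, self.cgs_fraction, self.case_fraction, self.expr_dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability parameter {p} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimulatedVariants:
    """Reference sequence plus the variant truth table."""

    chrom: str
    sequence: str
    variants: pd.DataFrame  # pos, id, ref, alt, maf, r2, ncoh, is_cgs, effect_allele, effect_is_alt

    @property
    def chrom_length(self) -> int:
        return len(self.sequence)


def simulate_reference_and_variants(config: SimulationConfig,
                                    rng: Optional[np.random.Generator] = None) -> SimulatedVariants:
    """Random reference sequence with variants planted at spaced positions.

    A configured fraction of variants is made CGS by construction: the site
    is given a G right flank with a C effect allele, or a C left flank with
    a G effect allele.  Non-CGS sites get flanks under which neither allele
    can complete a CpG.  Positions are spaced >= 3 bp so contexts never
    overlap.  The CpG-creating allele is assigned to REF or ALT at random
    so that downstream orientation handling is exercised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=L, p=probs)

    n_variants = int(round(config.variant_density * L / 1000))
    candidates = np.arange(2, L - 1, 3)  # 1-based positions with both flanks inside
    if n_variants > candidates.size:
        raise ValueError("variant density too high to avoid adjacent contexts")
    positions = np.sort(rng.choice(candidates, size=n_variants, replace=False))

    rows = []
    for i, pos in enumerate(positions):
        is_cgs = rng.random() < config.cgs_fraction
        other = rng.choice(["A", "T"])
        if is_cgs:
            if rng.random() < 0.5:  # CpG completed on the right: [C/x]G
                effect = "C"
                seq[pos] = "G"  # right flank (0-based pos == 1-based pos+1 - 1)
                left = rng.choice(["A", "G", "T"])
                seq[pos - 2] = left
            else:  # CpG completed on the left: C[G/x]
                effect = "G"
                seq[pos - 2] = "C"
                seq[pos] = rng.choice(["A", "C", "T"])
        else:
            effect = ""
            seq[pos - 2] = rng.choice(["A", "G", "T"])  # left != C
            seq[pos] = rng.choice(["A", "C", "T"])  # right != G
            a = rng.choice(_BASES)
            b = rng.choice([x for x in "ACGT" if x != a])
            alleles = (a, b)
        if is_cgs:
            alleles = (effect, other)
        effect_is_ref = bool(rng.random() < 0.5)
        ref, alt = (alleles if effect_is_ref else alleles[::-1])
        seq[pos - 1] = ref
        maf = rng.uniform(config.maf_low, config.maf_high)
        r2 = rng.uniform(config.r2_low, config.r2_high)
        rows.append((
            int(pos), f"v{i:05d}", ref, alt, maf, r2, config.n_cohorts,
            is_cgs, effect if is_cgs else "", (not effect_is_ref) if is_cgs else True,
        ))
    variants = pd.DataFrame(rows, columns=[
        "pos", "id", "ref", "alt", "maf", "r2", "ncoh",
        "is_cgs", "effect_allele", "effect_is_alt",
    ])
    return SimulatedVariants(chrom=config.chrom, sequence="".join(seq), variants=variants)


def _effect_dosage_matrix(genotypes: np.ndarray, variants: pd.DataFrame) -> np.ndarray:
    """Orient ALT-count genotypes to the CpG-creating effect allele."""
    flip = ~variants["effect_is_alt"].to_numpy(dtype=bool)
    oriented = genotypes.astype(float).copy()
    oriented[:, flip] = 2.0 - oriented[:, flip]
    return oriented


def _window_member_index(variants: pd.DataFrame, start: int, length: int = 1000) -> np.ndarray:
    pos = variants["pos"].to_numpy()
    return np.where((pos >= start) & (pos <= start + length - 1) & variants["is_cgs"].to_numpy())[0]


def tune_intercept(eta: np.ndarray, case_fraction: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) equal to the case fraction."""
    lo, hi = -40.0, 40.0
    f = lambda a: float(np.mean(expit(a + eta))) - case_fraction
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"case fraction {case_fraction} unattainable")
    return float(brentq(f, lo, hi, xtol=1e-10))


def _calibrated_dosages(g: np.ndarray, eps: np.ndarray, mafs: np.ndarray,
                        r2: np.ndarray) -> np.ndarray:
    """Noisy dosages whose squared correlation with the genotype matches r2.

    Dosages are the genotype plus Gaussian noise clipped to [0, 2]; because
    clipping attenuates the injected noise, the noise scale is calibrated
    per variant by bisection against the realized post-clipping squared
    correlation (r2 = 1 returns the genotype exactly).
    """
    n, m = g.shape
    dosage = g.astype(float).copy()
    for j in range(m):
        if r2[j] >= 1.0:
            continue
        target = max(r2[j], 1e-3)
        lo, hi = 0.0, 10.0 * np.sqrt(2 * mafs[j] * (1 - mafs[j]))

        def realized(scale: float) -> float:
            d = np.clip(g[:, j] + scale * eps[:, j], 0.0, 2.0)
            c = np.corrcoef(d, g[:, j])[0, 1]
            return c * c

        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if realized(mid) > target:
                lo = mid
            else:
                hi = mid
        scale = 0.5 * (lo + hi)
        dosage[:, j] = np.clip(g[:, j] + scale * eps[:, j], 0.0, 2.0)
    return dosage


def simulate_cohorts(sim: SimulatedVariants, config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None) -> List[CohortData]:
    """Per-cohort HWE genotypes, noisy dosages, covariates, and case status.

    Genotypes are Binomial(2, f_alt) with f_alt = MAF.  Imputed dosages are
    the genotype plus Gaussian noise in [0, 2], with the noise scale
    calibrated so the squared correlation with the true genotype matches
    the variant's emitted r2 (exactly the genotype when r2 = 1).  Case
    status is drawn from a logistic model whose
    linear predictor sums the configured window CpG-dosage effects and
    covariate effects, with the intercept tuned per cohort to the
    configured case fraction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    variants = sim.variants
    m = len(variants)
    mafs = variants["maf"].to_numpy()
    r2 = variants["r2"].to_numpy()
    member_idx = {start: _window_member_index(variants, start)
                  for start in config.effect_windows}
    cohorts: List[CohortData] = []
    for k in range(config.n_cohorts):
        n = config.n_per_cohort
        g = rng.binomial(2, mafs[None, :], size=(n, m))
        eps = rng.normal(0.0, 1.0, size=(n, m))
        dosage = _calibrated_dosages(g, eps, mafs, r2)

        age = rng.normal(75.0, 6.0, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        pcs = rng.normal(0.0, 1.0, size=(n, config.n_pcs))
        eta = config.age_beta * (age - 75.0) + config.sex_beta * sex + config.pc_beta * pcs.sum(axis=1)
        oriented_true = _effect_dosage_matrix(g, variants)
        for start, beta in config.effect_windows.items():
            idx = member_idx[start]
            beta_k = beta + (rng.normal(0.0, config.cohort_beta_sd) if config.cohort_beta_sd > 0 else 0.0)
            eta = eta + beta_k * oriented_true[:, idx].sum(axis=1)
        alpha = tune_intercept(eta, config.case_fraction)
        y = rng.binomial(1, expit(alpha + eta)).astype(float)

        cid = f"cohort{k + 1:02d}"
        samples = [f"{cid}_s{i:05d}" for i in range(n)]
        cov_cols = {"age": age, "sex": sex}
        for j in range(config.n_pcs):
            cov_cols[f"PC{j + 1}"] = pcs[:, j]
        cohorts.append(CohortData(
            cohort_id=cid,
            dosages=pd.DataFrame(dosage, index=samples, columns=variants["id"]),
            phenotype=y,
            covariates=pd.DataFrame(cov_cols, index=samples),
            effect_is_alt=pd.Series(variants["effect_is_alt"].to_numpy(),
                                    index=variants["id"]),
            binary=True,
        ))
    return cohorts


def simulate_omics(cohort: CohortData, sim: SimulatedVariants, config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame]:
    """Methylation and expression matrices with injected cis-QTL effects.

    Each configured probe/gene gains gamma * D, where D is the CpG dosage of
    the configured effect window in the supplied cohort.  Batch and family
    random intercepts and Gaussian noise are added; expression additionally
    undergoes detection dropout (values set to 0).  Returns the two
    matrices plus a truth table of injected effects.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = min(config.n_omics_subjects, cohort.n)
    subjects = list(cohort.dosages.index[:n])
    variants = sim.variants
    if config.omics_effect_window is not None:
        idx = _window_member_index(variants, config.omics_effect_window)
        cols = variants["id"].to_numpy()[idx]
        d = cohort.dosages.loc[subjects, cols].to_numpy()
        flip = ~variants["effect_is_alt"].to_numpy(dtype=bool)[idx]
        d[:, flip] = 2.0 - d[:, flip]
        D = d.sum(axis=1)
    else:
        D = np.zeros(n)

    L = sim.chrom_length
    probe_pos = np.sort(rng.choice(np.arange(1, L + 1), size=config.n_probes, replace=False))
    gene_pos = np.sort(rng.choice(np.arange(1, L + 1), size=config.n_genes, replace=False))
    probe_ids = [f"cg{i:05d}" for i in range(config.n_probes)]
    gene_ids = [f"GENE{i:03d}" for i in range(config.n_genes)]

    batch = rng.integers(0, config.n_batches, size=n)
    batch_eff = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    family = np.arange(n) // max(config.family_size, 1)
    family_eff = rng.normal(0.0, config.family_sd, size=family.max() + 1)

    covars = cohort.covariates.loc[subjects, ["age", "sex"]].copy()
    age_c = covars["age"].to_numpy() - covars["age"].mean()

    truth_rows = []
    meth = np.empty((config.n_probes, n))
    for i in range(config.n_probes):
        gamma = config.mqtl_gammas.get(i, 0.0)
        meth[i] = (0.5 + gamma * D + batch_eff[batch] + 1e-4 * age_c
                   + rng.normal(0.0, config.meth_noise_sd, size=n))
        truth_rows.append(("methylation", probe_ids[i], gamma))
    expr = np.empty((config.n_genes, n))
    for i in range(config.n_genes):
        gamma = config.eqtl_gammas.get(i, 0.0)
        expr[i] = (config.expr_baseline + gamma * D + family_eff[family]
                   + 0.01 * age_c + rng.normal(0.0, config.expr_noise_sd, size=n))
        truth_rows.append(("expression", gene_ids[i], gamma))
    if config.expr_dropout > 0:
        drop = rng.random(size=expr.shape) < config.expr_dropout
        expr[drop] = 0.0

    groups = pd.DataFrame({"batch": batch, "family": family}, index=subjects)
    meth_omics = OmicsMatrix(
        features=pd.DataFrame({"id": probe_ids, "chrom": sim.chrom, "pos": probe_pos}),
        values=pd.DataFrame(meth, index=probe_ids, columns=subjects),
        covariates=covars, groups=groups,
    )
    expr_omics = OmicsMatrix(
        features=pd.DataFrame({"id": gene_ids, "chrom": sim.chrom, "pos": gene_pos}),
        values=pd.DataFrame(expr, index=gene_ids, columns=subjects),
        covariates=covars, groups=groups,
    )
    truth = pd.DataFrame(truth_rows, columns=["layer", "feature", "gamma"])
    return meth_omics, expr_omics, truth


# ---------------------------------------------------------------------------
# file emission (the exact dialects the pipeline reads)


def write_fasta(sim: SimulatedVariants, path: str, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{sim.chrom}\n")
        for i in range(0, len(sim.sequence), line_width):
            fh.write(sim.sequence[i:i + line_width] + "\n")


def write_vcf(sim: SimulatedVariants, path: str, cohort: Optional[CohortData] = None) -> None:
    """Write a VCF v4.2 with INFO R2/MAF/NCOH and per-sample DS dosages."""
    variants = sim.variants
    samples = list(cohort.dosages.index) if cohort is not None else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={sim.chrom},length={sim.chrom_length}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality r2">\n')
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=NCOH,Number=1,Type=Integer,Description="Cohorts with data">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed ALT dosage">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header += ["FORMAT"] + samples
        fh.write("\t".join(header) + "\n")
        dosage = cohort.dosages.to_numpy() if cohort is not None else None
        for j, row in enumerate(variants.itertuples(index=False)):
            info = f"R2={row.r2:.4f};MAF={row.maf:.4f};NCOH={row.ncoh}"
            fields = [sim.chrom, str(row.pos), row.id, row.ref, row.alt, ".", "PASS", info]
            if samples:
                fields.append("DS")
                fields.extend(f"{dosage[i, j]:.3f}" for i in range(len(samples)))
            fh.write("\t".join(fields) + "\n")


def write_phenotypes(cohort: CohortData, path: str) -> None:
    out = cohort.covariates.copy()
    out.insert(0, "status", cohort.phenotype.astype(int))
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def load_cohort(vcf_path: str, pheno_path: str, cohort_id: str,
                effect_is_alt: Optional[pd.Series] = None) -> CohortData:
    """Rebuild a CohortData from a DS-dosage VCF and a phenotype TSV."""
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    ids, dosages = [], []
    for rec in vcf:
        ids.append(rec.ID)
        ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        dosages.append(ds)
    dosage_df = pd.DataFrame(np.column_stack(dosages) if dosages else np.empty((len(samples), 0)),
                             index=samples, columns=ids)
    pheno = pd.read_csv(pheno_path, sep="\t", index_col="sample_id")
    pheno = pheno.loc[samples]
    covars = pheno.drop(columns=["status"])
    return CohortData(
        cohort_id=cohort_id, dosages=dosage_df,
        phenotype=pheno["status"].to_numpy(dtype=float),
        covariates=covars, effect_is_alt=effect_is_alt, binary=True,
    )


def write_omics(omics: OmicsMatrix, prefix: str) -> None:
    omics.features.to_csv(f"{prefix}.features.tsv", sep="\t", index=False)
    omics.values.to_csv(f"{prefix}.values.tsv", sep="\t")
    if omics.covariates is not None:
        omics.covariates.to_csv(f"{prefix}.covariates.tsv", sep="\t")
    if omics.groups is not None:
        omics.groups.to_csv(f"{prefix}.groups.tsv", sep="\t")


def write_gmt(term_sets: Dict[str, List[str]], path: str) -> None:
    with open(path, "w") as fh:
        for term, genes in term_sets.items():
            fh.write("\t".join([term, "synthetic"] + list(genes)) + "\n")


def write_study(config: SimulationConfig, outdir: str) -> Dict[str, object]:
    """Emit a complete study directory and return the in-memory objects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim = simulate_reference_and_variants(config, rng)
    cohorts = simulate_cohorts(sim, config, rng)
    write_fasta(sim, str(out / "reference.fa"))
    write_vcf(sim, str(out / "sites.vcf"))
    for cohort in cohorts:
        write_vcf(sim, str(out / f"{cohort.cohort_id}.vcf"), cohort)
        write_phenotypes(cohort, str(out / f"{cohort.cohort_id}.pheno.tsv"))
    sim.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
    meth, expr, omics_truth = simulate_omics(cohorts[0], sim, config, rng)
    write_omics(meth, str(out / "methylation"))
    write_omics(expr, str(out / "expression"))
    omics_truth.to_csv(out / "truth_omics.tsv", sep="\t", index=False)
    # gene sets: one term collecting the responsive genes, plus random terms
    gene_ids = list(expr.values.index)
    responsive = [gene_ids[i] for i in config.eqtl_gammas if config.eqtl_gammas[i] != 0]
    terms = {"TERM_RESPONSIVE": responsive or gene_ids[:3]}
    term_size = min(5, len(gene_ids))
    for t in range(3):
        terms[f"TERM_RANDOM{t}"] = list(rng.choice(gene_ids, size=term_size,
                                                   replace=False))
    write_gmt(terms, str(out / "gene_sets.gmt"))
    logger.info("wrote study with %d variants, %d cohorts to %s",
                len(sim.variants), len(cohorts), outdir)
    return {"sim": sim, "cohorts": cohorts, "methylation": meth,
            "expression": expr, "config": asdict(config)}
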