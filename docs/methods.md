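# Methods

## CGS annotation

A biallelic SNV at position *p* can participate in at most two CpG
dinucleotides, (p−1, p) and (p, p+1). Substituting each allele into the
reference 3-mer and counting `CG` occurrences gives per-allele CpG counts
in {0, 1, 2}; a variant is a CGS iff the counts differ, and the allele
with the larger count is the CpG-creating **effect allele**. Because CpG
is its own reverse complement, forward-strand classification is complete;
the suite verifies strand symmetry exhaustively.

Edge rules: a flank that does not exist (sequence edge) contributes a
definitive count of zero; a flank read as `N` on a side that could decide
the call makes the variant non-CGS with a `context_incomplete` flag.
Alleles that create one CpG while destroying another (e.g. `C[G/C]G`) have
equal counts and are non-CGS: the net number of methylatable sites is
unchanged, and the dosage exposure below is defined on net CpG creation.
Contexts are taken from the reference only; haplotype-aware CpG formation
(a neighbouring variant altering the flank) is out of scope.

## Windows and filters

Windows are 1 kb, 1-based closed intervals anchored at position 1 with a
500 bp offset, so every unique 2 kb region lies in three windows. A
variant enters a window when `start ≤ pos ≤ end` (two windows except near
chromosome ends). Variant filters: imputation r² strictly greater than
0.4 (a variant at exactly 0.4 is removed) and genotype data in at least
half of the cohorts. Windows keep ≥ 2 members of the requested class
(CGS or non-CGS — the latter reproduces the negative-control design).
Windows possibly straddling assembly gaps are emitted; the variant
filters do the work.

## CpG dosage test

The window exposure is D_i = Σ_j d_ij over member CGSes, where d_ij is the
imputed (fractional, never rounded) dosage of the effect allele — the VCF
ALT dosage when the effect allele is ALT, otherwise 2 − dosage, making the
test invariant to VCF orientation. β is estimated by maximum-likelihood
logistic regression (case-control) or OLS (quantitative) of the trait on
intercept + D + covariates (age, sex, PCs; a named single-variant dosage
can be appended for conditional analysis — no special code path). Standard
errors are HC0 sandwich estimates; the sandwich flavour is a design choice
(HC0 is the GWAS summary-statistic convention), as is plain ML rather than
Firth under near-separation — separation and non-convergence yield flagged
NA results that the meta-analysis skips and counts.

## Score statistics and SKAT-O

Per cohort, U = Gᵀ(y − ŷ₀) and V = GᵀWG − GᵀWX(XᵀWX)⁻¹XᵀWG from the
covariates-only null model (W = ŷ₀(1−ŷ₀) for binary traits, σ̂² for
linear), with G oriented to effect alleles. Cohorts are pooled by summing
U and V (fixed-effects score meta-analysis); member lists must match
exactly, mismatches are errors.

SKAT-O forms Q_ρ = (1−ρ)Σ(w_jU_j)² + ρ(Σw_jU_j)² on the grid
ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} (configurable) with
w_j = Beta(1, 25) density at the pooled MAF, which up-weights rare
variants. Under the null each Q_ρ is a mixture of 1-df chi-squares with
weights the eigenvalues of R_ρ^{1/2} A R_ρ^{1/2}, A = Cov(wU); ρ = 1 is
computed exactly as the 1-df burden test with variance 1ᵀA1.

**Tail probabilities.** Two methods: *integration* — Imhof's
characteristic-function inversion, with the oscillatory tail of the
inversion integral handled by Fourier-weight (QAWF) quadrature after
splitting the phase at the arctan transition scale (absolute tolerance
~1e-9; an error estimate above max(5e-9, 0.1 p) or a non-positive result
raises a distinct failure) — and *saddlepoint* — Kuonen's Lugannani-Rice
approximation with a bisection-guarded Newton solve of K′(ζ) = q. The
two-stage rule screens every window with integration and recomputes
windows with p ≤ 5×10⁻⁴, or whose integration failed, with the
saddlepoint; the result records which method produced it.

**Unified p.** The minimum per-ρ p-value is calibrated by an integral
that this package evaluates *exactly* under the Gaussian score model
rather than by the usual moment-matching shortcut: conditioning on the
burden component x = (1ᵀS)²/(1ᵀA1) ~ χ²₁, the SKAT component |S|² given x
is a noncentral chi-square mixture over the eigenvalues of
C = A − A11ᵀA/(1ᵀA1) with noncentralities linear in x, whose tail the
(noncentral) saddlepoint evaluates on 200 Gauss-Legendre nodes after the
t = √x substitution. The per-ρ thresholds invert the same saddlepoint
tail used to rank the statistics, so the event {min_ρ p_ρ ≤ T} is
represented without method mismatch. Against 0.5–2 million direct
Gaussian-score simulations this integral is accurate to ~0.3% relative,
where the moment-matching shortcut deviates by 2–8%. Eigenvalues below
1e-10 of the largest are treated as PSD noise; the unified p is clamped
to [min_ρ p_ρ, |grid| · min_ρ p_ρ].

Known approximation limits: the saddlepoint tail itself is accurate to a
few tenths of a percent at moderate p and underestimates very deep tails
by up to ~10% relative (1-df worst case ~3% at p = 0.05); the asymptotic
p of any score-based SKAT-O differs from the exact permutation null at
small n with binary traits (2–8% relative at n = 200), which is a
property of the Gaussian approximation, not of the implementation —
small-sample moment-adjusted variants are deliberately not implemented.

## Meta-analysis, λ, GATES

Dosage coefficients are pooled with inverse-variance weights
(w_k = 1/SE_k²; β_meta = Σw_kβ_k/Σw_k; SE_meta = (Σw_k)^{−1/2}); Cochran's
Q heterogeneity is reported, never filtered on. λ is the median
association χ²₁ statistic over 0.4549 (the χ²₁ median); zero p-values are
clipped to the smallest positive float with a warning. Genome-wide flags
use p ≤ 5×10⁻⁸ per method plus their conjunction.

GATES combines per-SNP p-values with p_GATES = min_j m_e p_(j)/m_e(j),
where m_e = m − Σ_{λ_i>1}(λ_i − 1) over the eigenvalues of the p-value
correlation matrix, obtained from genotype LD correlation r through the
published sixth-order polynomial (coefficients pinned in `meta.py`).
|r| = 1 is mapped to a p-value correlation of exactly 1 and the map is
clipped to [0, 1], so the perfect-LD limit returns min-p exactly and the
independence limit returns Simes. LD for replication-stage windows comes
from a user-supplied reference panel (in tests, the simulated genotypes).

## mQTL / eQTL / scan / enrichment

The mQTL/eQTL exposure is the window CpG dosage. Family-structured
cohorts use a two-stage scheme: stage 1 residualizes each probe on
technical fixed covariates with a chip/batch random intercept (REML;
conditional residuals subtract the BLUPs; fewer than two levels or
non-convergence falls back to OLS with a logged flag); stage 2 regresses
the residual on dosage with age/sex fixed and a family random intercept —
a random-intercept stand-in for a full kinship matrix, a documented
limitation. Unrelated cohorts use plain linear models. mQTL p-values are
Bonferroni-corrected by the number of probes within 1 Mb of the *nearest
window boundary*, inclusive (the anchor is a design choice; it is
conservative and well defined); eQTL p-values by the number of genes
tested in the run, never a hardcoded count.

The expression-methylation scan removes genes detected (value > 0, a
config knob since RNA-seq counts and array intensities differ) in fewer
than 10% of subjects, regresses the rest on the probe with covariates,
and returns genes at p < 0.005 as the enrichment foreground. Enrichment
is the upper-tail hypergeometric p per term against the background, with
Benjamini-Hochberg FDR across terms.

## Synthetic studies

The generator emulates the discovery design the pipeline targets:
24 case-control cohorts at ~50% cases with roughly a thousand subjects
each at desk scale, common CGSes (MAF defaults 0.05–0.5; the recovery
targets use 0.25–0.36), window log-odds effects of order −0.02 to 0.2 per
CpG dinucleotide, and well-imputed dosages. Specifics:

* **Sequence/variants** — i.i.d. nucleotides at GC 0.41; variants planted
  ≥ 3 bp apart so contexts never overlap; a configured fraction made CGS
  by construction (C placed left of a G effect allele, or G right of a C
  effect allele), with the effect allele assigned to REF or ALT at
  random; truth tables emitted.
* **Genotypes/dosages** — Hardy-Weinberg Binomial(2, MAF); imputed
  dosages are genotype + Gaussian noise clipped to [0, 2], the noise
  scale calibrated per variant by bisection so the realized post-clipping
  squared correlation with the genotype equals the emitted r² (r² = 1
  returns genotypes exactly).
* **Disease** — logit P = α + Σ_w β_w D_w + covariate terms, α tuned per
  cohort by root-finding to the configured case fraction; per-cohort β
  perturbations default to SD 0 so the fixed-effects meta-estimand equals
  the configured β. Age/sex/PCs are drawn independently of genotype by
  default (adjustment is exercised without confounding).
* **Omics** — methylation = 0.5 + γ·D + batch intercepts + small age term
  + N(0, 0.01); expression analogous with family intercepts and detection
  dropout (values set to 0). Injected γs are recorded in truth tables.
* Variants are independent by default (no LD); GATES takes explicit
  correlation inputs, and coalescent-realistic LD is a non-goal.

What passing tests on these data do **not** show: robustness to LD
between CGSes, population stratification, genotype-correlated covariates,
realistic 450K beta-value distributions, or kinship beyond a family
random intercept. They do show correct arithmetic, calibration under the
stated null, and unbiased recovery of planted effects.

## Problem sizes and numerical choices

The default test suite runs the statistical checks at these sizes:
annotation oracle exhaustively (576 context/allele cases); SKAT-O null
calibration on 10,000 windows (m = 4, n = 500, two-stage path; empirical
size and KS uniformity); a 100,000-permutation min-p oracle at n = 200,
m = 5 with a quantitative trait (binary traits at this n leave the
Gaussian score approximation 2–8% from the permutation null — see above);
method agreement checks at p ∈ [10⁻⁶, 10⁻²]; GATES bounds on 1,000 random
instances; parameter recovery over 50 replicates (dosage coefficients)
and 20 replicates (odds ratio). Smaller cross-checks (20k permutations,
50-seed power runs) appear in the unit suites. Determinism: every
simulation is a pure function of its seed; the pipeline's report files
are byte-identical across reruns of the same configuration.
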