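"""SKAT-O: optimal sequence kernel association test on score statistics.

The test statistic family is

    Q_rho = (1 - rho) * sum_j (w_j U_j)^2 + rho * (sum_j w_j U_j)^2,

a convex combination of the variance-component (SKAT, rho=0) and burden
(rho=1) statistics built from the per-variant scores U and their null
covariance V (the meta-analyzable sufficient statistics).  Under the null,
Q_rho is a mixture of 1-df chi-squares whose mixture weights are the
eigenvalues of R_rho^{1/2} W V W R_rho^{1/2}, with R_rho = (1-rho) I +
rho 11' and W = diag(w).  The unified p-value minimizes the per-rho
p-values over a grid and accounts for the minimization through a
one-dimensional integral over the conditional null distribution.

Mixture-of-chi-square tail probabilities are computed either by numerical
inversion of the characteristic function (Imhof's "integration" formula) or
by Kuonen's saddlepoint (Lugannani-Rice) approximation.  The two-stage rule
screens every window with the integration method and recomputes windows
with p <= 5e-4, or with no reported p, using the saddlepoint method.

Default per-variant weights are the Beta(1, 25) density evaluated at the
minor allele frequency, which up-weights rare variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import integrate, stats
from numpy.polynomial import legendre

logger = logging.getLogger(__name__)

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)
SCREEN_THRESHOLD = 5e-4
_EIG_REL_TOL = 1e-10  # eigenvalues below this fraction of the max are PSD noise


class QuadFormError(RuntimeError):
    """Numerical inversion of the quadratic-form distribution failed."""


# ---------------------------------------------------------------------------
# mixture-of-chi-square tail probabilities


def _imhof_tail(q: float, lambdas: np.ndarray) -> float:
    """P(sum lambda_i chi2_1 > q) by Imhof's characteristic-function inversion.

    The inversion integrand sin(theta(u)) / (u rho(u)) with
    theta(u) = 1/2 sum_i arctan(lambda_i u) - q u / 2 oscillates at
    asymptotic frequency q/2.  The head of the integral is handled by
    adaptive quadrature; beyond the arctan transition region the phase is
    split as sin(phi) cos(qu/2) - cos(phi) sin(qu/2) and each term is
    integrated with the oscillatory-weight (QAWF) rule, which sums the
    Fourier tail exactly instead of chasing cancelling oscillations.
    """
    scale = float(np.max(lambdas))
    lam = tuple(float(l) / scale for l in np.asarray(lambdas, dtype=float))
    q = float(q) / scale
    atan, sin, cos, prod = math.atan, math.sin, math.cos, math.prod

    def phi(u: float) -> float:
        return 0.5 * sum(atan(l * u) for l in lam)

    def envelope(u: float) -> float:
        return 1.0 / (u * prod((1.0 + (l * u) ** 2) ** 0.25 for l in lam))

    def integrand(u: float) -> float:
        return sin(phi(u) - 0.5 * q * u) * envelope(u)

    u0 = 1.0  # arctan transition scale once lambda_max is normalized to 1
    head, err_head = integrate.quad(integrand, 0.0, u0, epsabs=1e-10,
                                    epsrel=1e-8, limit=200)
    omega = 0.5 * q
    if omega > 0:
        cos_part, err_c = integrate.quad(
            lambda u: sin(phi(u)) * envelope(u), u0, np.inf,
            weight="cos", wvar=omega, epsabs=1e-11, limit=300)
        sin_part, err_s = integrate.quad(
            lambda u: cos(phi(u)) * envelope(u), u0, np.inf,
            weight="sin", wvar=omega, epsabs=1e-11, limit=300)
        tail, err_tail = cos_part - sin_part, err_c + err_s
    else:
        tail, err_tail = integrate.quad(integrand, u0, np.inf, epsabs=1e-10,
                                        epsrel=1e-8, limit=200)
    p = 0.5 + (head + tail) / np.pi
    err = (err_head + err_tail) / np.pi
    if not np.isfinite(p):
        raise QuadFormError("integration returned non-finite value")
    if err > max(5e-9, 0.1 * abs(p)):
        raise QuadFormError(f"integration error estimate {err:.2e} too large for p={p:.2e}")
    if p <= 0.0 or p > 1.0 + 1e-8:
        raise QuadFormError(f"integration p={p:.2e} outside (0, 1]")
    return min(p, 1.0)


def _saddlepoint_tail_vec(q: np.ndarray, lambdas: np.ndarray,
                          delta: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorized Kuonen saddlepoint tail P(sum lambda_i chi2_1(delta_i) > q_k).

    Handles central (delta None) and noncentral mixtures; the saddlepoint
    solves K'(zeta) = q on zeta < 1/(2 lambda_max) with a bisection-guarded
    Newton iteration vectorized over q, followed by the Lugannani-Rice tail
    formula.  ``delta`` may be per-q (shape (k, m)) noncentralities.
    """
    lam = np.atleast_2d(np.asarray(lambdas, dtype=float))  # (1, m) or (k, m)
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if delta is None:
        dl = np.zeros((1, lam.shape[1]))
    else:
        dl = np.atleast_2d(np.asarray(delta, dtype=float))
    lmax = lam.max(axis=1)  # per-row scale; padded zero entries are inert
    mean = np.sum(lam * (1.0 + dl), axis=1)

    lo = -1e8 / (2.0 * lmax) * np.ones_like(q)
    hi = (1.0 - 1e-12) / (2.0 * lmax) * np.ones_like(q)
    zeta = np.zeros_like(q)

    def cumulants(z):
        d = 1.0 - 2.0 * z[:, None] * lam
        k0 = np.sum(-0.5 * np.log(d) + z[:, None] * lam * dl / d, axis=1)
        k1 = np.sum(lam / d + lam * dl / d**2, axis=1)
        k2 = np.sum(2.0 * lam**2 / d**2 + 4.0 * lam**2 * dl / d**3, axis=1)
        return k0, k1, k2

    for _ in range(80):
        _, k1, k2 = cumulants(zeta)
        f = k1 - q
        lo = np.where(f < 0, zeta, lo)
        hi = np.where(f > 0, zeta, hi)
        nxt = zeta - f / k2
        bad = (nxt <= lo) | (nxt >= hi) | ~np.isfinite(nxt)
        nxt = np.where(bad, 0.5 * (lo + hi), nxt)
        if np.all(np.abs(nxt - zeta) <= 1e-13 * (1.0 + np.abs(zeta))):
            zeta = nxt
            break
        zeta = nxt

    k0, _, k2 = cumulants(zeta)
    w = np.sign(zeta) * np.sqrt(np.maximum(2.0 * (zeta * q - k0), 0.0))
    v = zeta * np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = w + np.log(v / w) / w
    p = stats.norm.sf(z)
    # near q = E[Q] the saddlepoint degenerates; use a normal approximation there
    tiny = np.abs(zeta) * (2.0 * lmax) < 1e-7
    if np.any(tiny):
        sd = np.sqrt(np.sum(2.0 * lam**2 * (1.0 + 2.0 * dl), axis=1))
        p = np.where(tiny, stats.norm.sf((q - mean) / np.maximum(sd, 1e-300)), p)
    return np.clip(p, 0.0, 1.0)


def qf_pvalue(q: float, lambdas: Sequence[float], method: str = "integration") -> float:
    """Tail probability P(sum_i lambda_i chi2_{1,i} > q).

    ``method='integration'`` uses Imhof's numerical inversion (raises
    :class:`QuadFormError` on non-convergence so a caller can fall back);
    ``method='saddlepoint'`` uses the Kuonen/Lugannani-Rice approximation.
    """
    lam = np.asarray(lambdas, dtype=float)
    if lam.size == 0 or np.any(lam < 0) or not np.any(lam > 0):
        raise ValueError("lambdas must be nonnegative with at least one positive entry")
    if q < 0:
        raise ValueError("q must be nonnegative")
    if q == 0.0:
        return 1.0
    if method == "integration":
        return _imhof_tail(q, lam)
    if method == "saddlepoint":
        return float(_saddlepoint_tail_vec(np.array([q]), lam)[0])
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# quantile inversion of the central-mixture saddlepoint tail


def _sp_quantiles(tail_prob: float, lam_sets: Sequence[np.ndarray]) -> np.ndarray:
    """q_i with saddlepoint-tail(q_i; lam_sets[i]) = tail_prob, all at once.

    Inverting the same tail approximation used to rank the per-rho
    statistics makes the events {p_rho <= T} and {Q_rho >= q_rho(T)}
    identical, so the omnibus integral sees no method mismatch.  Lambda
    sets of unequal size are zero-padded (zero weights are inert in the
    cumulant-generating function); the roots are found by a shared
    bracketed bisection, vectorized across sets.
    """
    k = len(lam_sets)
    m = max(len(l) for l in lam_sets)
    lam = np.zeros((k, m))
    for i, l in enumerate(lam_sets):
        lam[i, : len(l)] = l
    mean = lam.sum(axis=1)
    sd = np.sqrt(2.0 * np.sum(lam**2, axis=1))
    lmax = lam.max(axis=1)

    def tail_and_q(zeta: np.ndarray):
        # on the saddlepoint path q = K'(zeta), so the tail at that q is
        # available in closed form -- no inner root-find needed
        d = 1.0 - 2.0 * zeta[:, None] * lam
        k0 = np.sum(-0.5 * np.log(d), axis=1)
        q = np.sum(lam / d, axis=1)
        k2 = np.sum(2.0 * lam**2 / d**2, axis=1)
        w = np.sign(zeta) * np.sqrt(np.maximum(2.0 * (zeta * q - k0), 0.0))
        v = zeta * np.sqrt(k2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = w + np.log(v / w) / w
        p = stats.norm.sf(z)
        tiny = np.abs(zeta) * (2.0 * lmax) < 1e-9
        p = np.where(tiny, stats.norm.sf((q - mean) / sd), p)
        return p, q

    lo = -1e8 / (2.0 * lmax)
    hi = (1.0 - 1e-14) / (2.0 * lmax)
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        p, _ = tail_and_q(mid)
        above = p > tail_prob  # tail still too heavy: move toward larger q
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    _, q = tail_and_q(0.5 * (lo + hi))
    return q


# ---------------------------------------------------------------------------
# score statistics container and weights


@dataclass
class ScoreStats:
    """Per-window score vector U and its null covariance V for one cohort.

    U = G'(y - yhat_null) with G the effect-allele-oriented dosage matrix;
    V is Cov(U) under the covariates-only null model.  Summing U and V over
    cohorts yields the pooled statistics, which is how the meta-analysis
    combines evidence without sharing individual-level data.
    """

    window: object
    cohort_id: str
    U: np.ndarray
    V: np.ndarray
    mafs: np.ndarray
    n: int
    member_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        m = self.U.shape[0]
        if self.V.shape != (m, m) or self.mafs.shape[0] != m:
            raise ValueError("inconsistent score-statistic dimensions")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValueError("V must be symmetric")


def beta_maf_weights(mafs: Sequence[float], a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density variant weights (default Beta(1,25), up-weighting rare alleles)."""
    return stats.beta.pdf(np.asarray(mafs, dtype=float), a, b)


def meta_combine_scores(stats_list: Sequence[ScoreStats]) -> ScoreStats:
    """Pool per-cohort score statistics by summation (fixed-effects combination)."""
    if not stats_list:
        raise ValueError("no score statistics to combine")
    first = stats_list[0]
    for s in stats_list[1:]:
        if s.member_ids != first.member_ids:
            diff = set(s.member_ids) ^ set(first.member_ids)
            raise ValueError(f"member mismatch across cohorts: {sorted(diff)}")
    U = np.sum([s.U for s in stats_list], axis=0)
    V = np.sum([s.V for s in stats_list], axis=0)
    n = int(np.sum([s.n for s in stats_list]))
    # MAF from the pooled sample: n-weighted average of cohort MAFs
    w = np.array([s.n for s in stats_list], dtype=float)
    mafs = np.average([s.mafs for s in stats_list], axis=0, weights=w)
    return ScoreStats(
        window=first.window, cohort_id="meta", U=U, V=V, mafs=mafs, n=n,
        member_ids=list(first.member_ids),
    )


# ---------------------------------------------------------------------------
# SKAT-O


@dataclass
class SkatOResult:
    window: object
    p_by_rho: Dict[float, float]
    rho_opt: Optional[float]
    p_overall: float
    method_used: str
    weights: Optional[np.ndarray]
    m: int
    flag: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.flag is None and np.isfinite(self.p_overall)


def _trim_eigvals(vals: np.ndarray) -> np.ndarray:
    vals = np.asarray(vals, dtype=float)
    top = vals.max(initial=0.0)
    vals = vals[vals > _EIG_REL_TOL * top]
    return np.sort(vals)[::-1]


def _rho_kernel_eigvals(A: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of R_rho^{1/2} A R_rho^{1/2} for R_rho = (1-rho)I + rho 11'."""
    m = A.shape[0]
    if rho == 0.0:
        return _trim_eigvals(np.linalg.eigvalsh(A))
    ones = np.ones((m, 1))
    proj = ones @ ones.T / m
    r_half = np.sqrt(1.0 - rho) * (np.eye(m) - proj) + np.sqrt(1.0 - rho + m * rho) * proj
    return _trim_eigvals(np.linalg.eigvalsh(r_half @ A @ r_half))


def _tail(q: float, lambdas: np.ndarray, method: str) -> float:
    if method == "integration":
        return _imhof_tail(q, lambdas)
    return float(_saddlepoint_tail_vec(np.array([q]), lambdas)[0])


def skat_o_test(
    score_stats: ScoreStats,
    weights: Optional[np.ndarray] = None,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    method: str = "integration",
) -> SkatOResult:
    """SKAT-O over a rho grid with the Lee et al. unified minimum-p p-value."""
    U = score_stats.U
    V = score_stats.V
    m = U.shape[0]
    if weights is None:
        weights = beta_maf_weights(score_stats.mafs)
    w = np.asarray(weights, dtype=float)

    if not np.any(np.diag(V) > 0):
        return SkatOResult(score_stats.window, {}, None, np.nan, method, w, m, flag="no variance")

    S = w * U  # weighted scores
    A = (w[:, None] * V) * w[None, :]  # Cov(S) under the null

    if m == 1:
        # grid collapses: every Q_rho is S^2, a single-variant score test
        q = float(S[0] ** 2)
        lam = np.array([A[0, 0]])
        p = _tail(q, lam, method)
        p_by_rho = {float(r): p for r in rho_grid}
        return SkatOResult(score_stats.window, p_by_rho, float(rho_grid[0]), p, method, w, m)

    sum_s = float(S.sum())
    q_skat = float(np.sum(S**2))
    p_by_rho: Dict[float, float] = {}
    lambdas_by_rho: Dict[float, np.ndarray] = {}
    for rho in rho_grid:
        rho = float(rho)
        q_rho = (1.0 - rho) * q_skat + rho * sum_s**2
        if rho >= 1.0:
            lam = np.array([float(np.sum(A))])  # burden: 1-df with variance 1'A1
        else:
            lam = _rho_kernel_eigvals(A, rho)
        lambdas_by_rho[rho] = lam
        p_by_rho[rho] = _tail(q_rho, lam, method)

    rho_opt = min(p_by_rho, key=p_by_rho.get)
    n_rho = len(rho_grid)
    if n_rho == 1 or all(float(r) >= 1.0 for r in rho_grid):
        # nothing to minimize over: the unified p is the single p
        return SkatOResult(score_stats.window, p_by_rho, rho_opt,
                           p_by_rho[rho_opt], method, w, m)

    # The omnibus machinery below is saddlepoint-consistent throughout:
    # thresholds invert the same tail used to rank the statistics, so
    # {p_rho <= T} == {Q_rho >= qmin_rho} exactly.
    if method == "saddlepoint":
        p_sp = dict(p_by_rho)
    else:
        p_sp = {}
        for rho, lam in lambdas_by_rho.items():
            q_rho = (1.0 - rho) * q_skat + rho * sum_s**2
            p_sp[rho] = float(_saddlepoint_tail_vec(np.array([q_rho]), lam)[0])
    min_p = min(p_sp.values())
    min_p_report = p_by_rho[rho_opt]
    rho_keys = list(lambdas_by_rho)
    q_vals = _sp_quantiles(min_p, [lambdas_by_rho[r] for r in rho_keys])
    q_min = dict(zip(rho_keys, q_vals))

    # Exact unified p under the Gaussian score model: condition on the
    # burden component x = (1'S)^2 / (1'A1) ~ chi2_1.  Given x, the SKAT
    # component K = |S|^2 is a noncentral chi-square mixture over the
    # eigenvalues of C = A - A11'A / (1'A1), with noncentralities
    # proportional to x; Q_rho >= qmin_rho for some rho iff x exceeds the
    # burden cut or K exceeds the piecewise-linear envelope c(x).
    one_a = A @ np.ones(m)
    s2b = float(np.ones(m) @ one_a)
    rhos = np.asarray([float(r) for r in rho_grid])
    sub1 = rhos < 1.0
    q_min_arr = np.asarray([q_min[float(r)] for r in rhos])
    if s2b <= _EIG_REL_TOL * float(np.trace(A)):
        # burden direction has no variance: Q_rho = (1-rho) K for all rho
        with np.errstate(divide="ignore"):
            cut = np.min(q_min_arr[sub1] / (1.0 - rhos[sub1]))
        lam_a = _trim_eigvals(np.linalg.eigvalsh(A))
        p_overall = float(_saddlepoint_tail_vec(np.array([cut]), lam_a)[0])
    else:
        C = A - np.outer(one_a, one_a) / s2b
        vals, vecs = np.linalg.eigh(C)
        proj = (vecs.T @ one_a) ** 2 / s2b  # squared loadings of the burden mean
        keep = vals > _EIG_REL_TOL * max(vals.max(), 1e-300)
        lam_c = vals[keep]
        g = proj[keep] / lam_c  # noncentrality per unit x
        r2_coef = float(np.sum(proj[~keep]))  # deterministic-in-x remainder

        if np.any(~sub1):
            x_burden = float(np.min(q_min_arr[~sub1])) / s2b
        else:
            x_burden = np.inf
        x_cap = float(stats.chi2.isf(1e-16, 1))
        x_lim = min(x_burden, x_cap)
        nodes, gl_w = legendre.leggauss(200)
        t_max = np.sqrt(x_lim)
        t = 0.5 * t_max * (nodes + 1.0)
        gl_w = gl_w * 0.5 * t_max
        x = t**2
        with np.errstate(divide="ignore"):
            c_x = np.min((q_min_arr[sub1, None] - rhos[sub1, None] * s2b * x[None, :])
                         / (1.0 - rhos[sub1, None]), axis=0)
        thresh = c_x - r2_coef * x
        tail = np.ones_like(x)
        pos = thresh > 0
        if lam_c.size == 0:
            tail = (thresh <= 0).astype(float)
        elif np.any(pos):
            tail[pos] = _saddlepoint_tail_vec(
                thresh[pos], lam_c, delta=x[pos, None] * g[None, :])
        integrand = tail * 2.0 * stats.norm.pdf(t)
        p_overall = float(np.sum(gl_w * integrand))
        p_overall += float(stats.chi2.sf(x_burden, 1)) if np.isfinite(x_burden) \
            else float(stats.chi2.sf(x_cap, 1))

    # sanity clamps: the unified p is bounded below by the minimum per-rho p
    # and above by its Bonferroni bound over the grid
    p_overall = max(p_overall, min_p_report)
    p_overall = min(p_overall, min_p_report * n_rho, 1.0)
    return SkatOResult(score_stats.window, p_by_rho, rho_opt, p_overall, method, w, m)


def two_stage_window_pvalue(
    score_stats: ScoreStats,
    weights: Optional[np.ndarray] = None,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    screen_threshold: float = SCREEN_THRESHOLD,
) -> SkatOResult:
    """Screen with the integration method; recompute small or failed p-values
    with the saddlepoint method."""
    try:
        res = skat_o_test(score_stats, weights, rho_grid, method="integration")
        failed = not np.isfinite(res.p_overall) and res.flag is None
    except QuadFormError:
        res, failed = None, True
    if failed or (res is not None and res.ok and res.p_overall <= screen_threshold):
        try:
            return skat_o_test(score_stats, weights, rho_grid, method="saddlepoint")
        except QuadFormError:
            return SkatOResult(score_stats.window, {}, None, np.nan, "saddlepoint",
                               weights, score_stats.U.shape[0], flag="both methods failed")
    if res is None:
        return SkatOResult(score_stats.window, {}, None, np.nan, "integration",
                           weights, score_stats.U.shape[0], flag="both methods failed")
    return res
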