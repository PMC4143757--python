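"""Rare-variant set tests for family samples: famBT and famSKAT.

Both tests work inside the polygenic mixed model

    Y = X a + (genetic term) + gamma + eps,
    gamma ~ N(0, sG2 * Phi),  eps ~ N(0, sE2 * I).

famBT (weighted burden) collapses a set's dosage columns into one score
g = sum_j w_j G_j and tests its fixed effect beta (H0: beta = 0) — powerful
when the set's effects share a direction.  famSKAT treats per-variant
effects as random, beta ~ N(0, tau * I_q), and tests H0: tau = 0 with the
variance-component score statistic

    Q = r' Sigma^-1 G W W' G' Sigma^-1 r,      r = Y - X a_hat,

whose null distribution is a weighted sum of chi-square(1) variables with
weights the eigenvalues of W' G' P G W (P the null-model projection).  Tail
probabilities come from numerical inversion of the characteristic function
(Imhof's integral) with the Liu moment-matching approximation as fallback.

Both tests are score tests under the one shared covariates-only REML fit
(one variance-component fit per trait); a per-set REML Wald variant of the
burden test is available via ``method="wald"`` for cross-checking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .lmm import NullModelFit, fit_null
from .variants import DosageMatrix, VariantSet

__all__ = [
    "SetTestResult",
    "ChiSquareMixture",
    "burden_score",
    "fam_burden_test",
    "fam_skat_test",
    "fam_skat_quadratic",
    "mixture_pvalue",
    "run_set_tests",
]

log = logging.getLogger("famrv")

#: smallest p-value ever reported (exact zeros are never emitted)
P_FLOOR = np.finfo(float).tiny

#: relative eigenvalue cutoff for the famSKAT kernel rank
EIG_REL_TOL = 1e-10

#: Imhof results below this are considered at the limit of the integration's
#: absolute accuracy and are recomputed with the Liu approximation
IMHOF_MIN_P = 1e-13


class UndefinedTestError(ValueError):
    """The requested test is undefined for this set (e.g. constant burden)."""


@dataclass
class SetTestResult:
    """Outcome of one set-level test."""

    label: str
    method: str  # famBT | famSKAT
    q: int
    stat: float
    p: float
    pvalue_method: str = "chi2"
    beta: float | None = None
    trait: str = ""


@dataclass
class ChiSquareMixture:
    """Null distribution sum_k lambda_k chi2_1 and the observed value Q."""

    eigenvalues: np.ndarray
    q_obs: float

    def __post_init__(self) -> None:
        lam = np.sort(np.asarray(self.eigenvalues, dtype=float))[::-1]
        if lam.size == 0 or lam[0] <= 0:
            raise ValueError("mixture requires at least one positive eigenvalue")
        self.eigenvalues = lam[lam > 0]


# ---------------------------------------------------------------------------
# burden


def burden_score(g_cols: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Combined genotype score g = sum_j w_j G_j (length n)."""
    g_cols = np.atleast_2d(np.asarray(g_cols, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if g_cols.shape[1] != weights.size:
        raise ValueError("weights do not align with dosage columns")
    return g_cols @ weights


def fam_burden_test(
    fit: NullModelFit,
    g: np.ndarray,
    label: str = "",
    method: str = "score",
    y: np.ndarray | None = None,
    x: np.ndarray | None = None,
    phi: np.ndarray | None = None,
) -> SetTestResult:
    """Test H0: beta = 0 for the collapsed burden score ``g``.

    ``method="score"`` (default) uses the shared covariates-only null fit;
    ``method="wald"`` refits the full mixed model with g as a fixed effect
    (requires y, x and phi) and tests the Wald statistic.  Both are
    two-sided via chi-square(1).
    """
    g = np.asarray(g, dtype=float)
    if np.ptp(g) == 0:
        raise UndefinedTestError(f"set {label!r}: burden score is constant")
    if method == "score":
        score, cov = fit.project(fit.rotate(g[:, None]))
        u_, v_ = float(score[0]), float(cov[0, 0])
        if v_ <= 0:
            raise UndefinedTestError(f"set {label!r}: degenerate score variance")
        stat = u_ * u_ / v_
        beta = u_ / v_
    elif method == "wald":
        if y is None or x is None or phi is None:
            raise ValueError("wald burden test needs y, x and phi")
        xg = np.column_stack([x, g])
        full = fit_null(y, xg, phi, phi_eig=(fit.eigvals, fit.eigvecs))
        beta = float(full.alpha[-1])
        se2 = float(full.xtsx_inv[-1, -1])
        stat = beta * beta / se2
    else:
        raise ValueError(f"unknown burden method {method!r}")
    p = max(float(stats.chi2.sf(stat, 1)), P_FLOOR)
    return SetTestResult(label=label, method="famBT", q=1, stat=stat, p=p,
                         pvalue_method=f"chi2-{method}", beta=beta)


# ---------------------------------------------------------------------------
# famSKAT


def fam_skat_quadratic(
    fit: NullModelFit, g_cols: np.ndarray, weights: np.ndarray
) -> ChiSquareMixture:
    """Build the famSKAT statistic Q and its null chi-square mixture.

    Q = r' Sigma^-1 (GW)(GW)' Sigma^-1 r; the mixture weights are the
    eigenvalues of W' G' P G W, computed on the q x q scale after rotating
    into the basis that diagonalizes Sigma.  Eigenvalues below
    ``EIG_REL_TOL`` times the largest are dropped as numerical rank noise.
    """
    g_cols = np.atleast_2d(np.asarray(g_cols, dtype=float))
    gw = g_cols * np.asarray(weights, dtype=float)[None, :]
    score, cov = fit.project(fit.rotate(gw))
    q_obs = float(score @ score)
    lam = np.linalg.eigvalsh(cov)
    lam = lam[lam > EIG_REL_TOL * max(lam.max(), 0.0)] if lam.size else lam
    if lam.size == 0:
        raise UndefinedTestError("famSKAT kernel has rank 0 (constant variants)")
    return ChiSquareMixture(eigenvalues=lam, q_obs=q_obs)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


def _imhof_tail(lam: np.ndarray, q: float) -> tuple[float, float]:
    """P(sum lam_k chi2_1 > q) by characteristic-function inversion.

    Imhof's integral: p = 1/2 + (1/pi) * Int_0^inf sin(theta(u)) / (u rho(u)) du
    with theta(u) = (sum_k arctan(lam_k u) - q u) / 2 and
    rho(u) = prod_k (1 + lam_k^2 u^2)^(1/4).

    For large u the integrand oscillates with half-period 2*pi/q under a
    monotone envelope, so the integral is evaluated as a series of
    half-period segments (each integrated by composite 16-point
    Gauss-Legendre, with sub-panels keeping the slowly varying arctan phase
    resolved) and the eventually-alternating series is summed with repeated
    averaging (Euler transformation) of its partial sums.  Everything is
    vectorized; the returned ``(p, abserr)`` carries the acceleration's
    convergence estimate so callers can fall back when it is poor.
    """
    lam = np.asarray(lam, dtype=float)
    if q <= 0:
        return 1.0, 0.0
    half = 2.0 * np.pi / q  # half-period of the fast oscillation
    # sub-panels per segment so the arctan part moves < ~pi per panel
    j = int(np.ceil(half * 0.5 * lam.sum() / np.pi))
    if j > 4096:  # q astronomically far below E[Q]; p ~ 1
        return 1.0, np.inf
    n_seg = 64
    edges = np.linspace(0.0, n_seg * half, n_seg * j + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    hw = 0.5 * (edges[1] - edges[0])
    u = (mid[:, None] + hw * _GL_NODES[None, :]).ravel()  # panels x nodes
    theta = 0.5 * (np.arctan(np.multiply.outer(u, lam)).sum(axis=1) - q * u)
    log_rho = 0.25 * np.log1p(np.square(np.multiply.outer(u, lam))).sum(axis=1)
    f = np.sin(theta) * np.exp(-log_rho) / u
    panel = (f.reshape(-1, 16) @ _GL_WEIGHTS) * hw
    terms = panel.reshape(n_seg, j).sum(axis=1)
    s = np.cumsum(terms)
    # Euler acceleration of the (eventually alternating) partial sums
    a = s[n_seg // 2:]
    est = prev = float(a[-1])
    while a.size > 1:
        a = 0.5 * (a[1:] + a[:-1])
        prev, est = est, float(a[-1])
    err = abs(est - prev) + 1e-15
    p = 0.5 + est / np.pi
    return float(p), float(err)


def _liu_tail(lam: np.ndarray, q: float) -> float:
    """Liu-Tang-Zhang moment-matched (non)central chi-square tail."""
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        delta = 0.0
    t = (q - c1) / np.sqrt(2.0 * c2)
    x = t * np.sqrt(2.0 * (df + 2.0 * delta)) + df + delta
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def mixture_pvalue(mix: ChiSquareMixture) -> tuple[float, str]:
    """Upper-tail probability of the chi-square mixture at its observed Q.

    Imhof's characteristic-function inversion is exact up to integration
    error; when it fails, leaves (0, 1], or sits below its absolute-accuracy
    floor, the Liu moment-matching approximation is used instead.  The
    method actually applied is returned alongside p, and p is floored at
    the smallest positive double.
    """
    lam = mix.eigenvalues
    q = mix.q_obs
    if lam.size == 1:
        return max(float(stats.chi2.sf(q / lam[0], 1)), P_FLOOR), "exact-chi2"
    try:
        p, err = _imhof_tail(lam, q)
    except Exception:  # noqa: BLE001 — quad can fail on extreme inputs
        p, err = np.nan, np.inf
    if np.isfinite(p) and IMHOF_MIN_P < p <= 1.0 and err < 1e-6:
        return float(p), "imhof"
    p = _liu_tail(lam, q)
    log.debug("mixture_pvalue: Liu fallback (imhof p=%s)", p)
    return max(float(min(p, 1.0)), P_FLOOR), "liu"


def fam_skat_test(
    fit: NullModelFit, g_cols: np.ndarray, weights: np.ndarray, label: str = ""
) -> SetTestResult:
    """famSKAT variance-component score test of H0: tau = 0 for one set."""
    mix = fam_skat_quadratic(fit, g_cols, weights)
    p, how = mixture_pvalue(mix)
    return SetTestResult(
        label=label, method="famSKAT", q=int(np.atleast_2d(g_cols).shape[1]),
        stat=mix.q_obs, p=p, pvalue_method=how,
    )


# ---------------------------------------------------------------------------
# driver


def run_set_tests(
    fit: NullModelFit,
    dm: DosageMatrix,
    sets: list[VariantSet],
    methods: tuple[str, ...] = ("famBT", "famSKAT"),
    trait: str = "",
) -> pd.DataFrame:
    """Run the requested tests on every variant set; one row per set x method.

    Sets for which a test is undefined (all-constant burden / rank-0 kernel)
    are skipped with the reason logged.
    """
    rows = []
    for vs in sets:
        cols = dm.g[:, vs.indices]
        for method in methods:
            try:
                if method == "famBT":
                    res = fam_burden_test(
                        fit, burden_score(cols, vs.weights), label=vs.label
                    )
                elif method == "famSKAT":
                    res = fam_skat_test(fit, cols, vs.weights, label=vs.label)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except UndefinedTestError as exc:
                log.info("skipping %s for %s: %s", method, vs.label, exc)
                continue
            start, end = vs.span if vs.span else (None, None)
            rows.append(
                {
                    "set": vs.label,
                    "chrom": vs.chrom,
                    "start": start,
                    "end": end,
                    "q": vs.q,
                    "method": method,
                    "stat": res.stat,
                    "beta": res.beta,
                    "p": res.p,
                    "pvalue_method": res.pvalue_method,
                    "trait": trait,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["set", "chrom", "start", "end", "q", "method", "stat", "beta",
                 "p", "pvalue_method", "trait"],
    )
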