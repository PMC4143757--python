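"""Polygenic linear mixed model: REML null fit and single-marker score tests.

The null (covariates-only) model is

    Y = X a + gamma + eps,   gamma ~ N(0, sG2 * Phi),  eps ~ N(0, sE2 * I),

with Phi twice the kinship matrix.  Writing Phi = U D U' and rotating every
vector by U', the covariance becomes diagonal, so REML reduces to a
one-dimensional profile optimization over the heritability ratio
h2 = sG2 / (sG2 + sE2) after a single n x n eigendecomposition per trait.
The fitted covariance Sigma = sG2*Phi + sE2*I and its implied projection

    P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1

are cached in rotated form and reused by every score test, so a genome-wide
scan needs one variance-component fit per trait.

Boundary estimates (h2 = 0 or 1) are legitimate and flagged; with Phi = I
the two components are unidentifiable (only their sum is estimable) and the
fit is flagged as confounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["NullModelFit", "fit_null", "single_marker_test", "MarkerTestResult"]

H2_TOL = 1e-8  # convergence tolerance on the heritability ratio


class FitError(RuntimeError):
    """Null-model fitting failed (bad inputs or non-convergence)."""


@dataclass
class NullModelFit:
    """REML estimates and cached rotated quantities for score testing.

    Attributes
    ----------
    alpha : GLS covariate-effect estimates at the REML optimum.
    sigma_g2, sigma_e2 : variance components (polygenic, residual).
    h2 : sigma_g2 / (sigma_g2 + sigma_e2).
    reml_loglik : restricted log-likelihood at the optimum.
    boundary : True when h2 was estimated at 0 or 1.
    confounded : True when Phi carries no kinship contrast (Phi = c*I), in
        which case only the total variance is identified and h2 is set to 0.
    """

    alpha: np.ndarray
    sigma_g2: float
    sigma_e2: float
    h2: float
    reml_loglik: float
    boundary: bool
    confounded: bool
    # rotated cache: eigvecs U, eigvals d of Phi, and per-observation
    # variances s_i = sigma_g2*d_i + sigma_e2
    eigvecs: np.ndarray = field(repr=False)
    eigvals: np.ndarray = field(repr=False)
    s: np.ndarray = field(repr=False)
    xt: np.ndarray = field(repr=False)  # U'X
    resid_rot: np.ndarray = field(repr=False)  # U'(Y - X alpha)
    xtsx_inv: np.ndarray = field(repr=False)  # (X' Sigma^-1 X)^-1

    @property
    def n(self) -> int:
        return self.s.size

    def rotate(self, m: np.ndarray) -> np.ndarray:
        """U' m — move columns into the diagonalized-covariance basis."""
        return self.eigvecs.T @ m

    def sigma_inv_resid_rot(self) -> np.ndarray:
        """U' Sigma^-1 (Y - X alpha), i.e. rotated GLS residuals / s."""
        return self.resid_rot / self.s

    def project(self, cols_rot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For rotated columns B = U'C return (C' Sigma^-1 r, C' P C).

        These are the score vector and its null covariance for testing the
        columns of C as added fixed effects.
        """
        b = np.atleast_2d(cols_rot.T).T / np.sqrt(self.s)[:, None]
        a = self.xt / np.sqrt(self.s)[:, None]
        score = b.T @ (self.resid_rot / np.sqrt(self.s))
        ab = a.T @ b
        cov = b.T @ b - ab.T @ self.xtsx_inv @ ab
        return score, cov


def _eig_phi(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d, u = np.linalg.eigh(phi)
    if d.min() < -1e-6 * max(d.max(), 1.0):
        raise FitError(f"Phi is not positive semidefinite (min eig {d.min():.3g})")
    return np.maximum(d, 0.0), u


def fit_null(
    y: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray,
    phi_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> NullModelFit:
    """REML fit of the covariates-only polygenic model.

    ``phi_eig`` may supply a precomputed ``(eigvals, eigvecs)`` pair of Phi
    (e.g. when many traits or simulation replicates share one pedigree).
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if y.shape != (n,) or phi_eig is None and phi.shape != (n, n):
        raise FitError("dimension mismatch between Y, X and Phi")
    if np.linalg.matrix_rank(x) < p:
        raise FitError("covariate matrix X is rank-deficient")
    d, u = _eig_phi(np.asarray(phi, dtype=float)) if phi_eig is None else phi_eig
    yt = u.T @ y
    xt = u.T @ x

    confounded = bool(np.ptp(d) < 1e-8 * max(d.max(), 1.0))

    def neg_reml(h2: float) -> float:
        v = h2 * d + (1.0 - h2)  # Sigma = sigma2 * diag(v)
        if v.min() <= 0:
            return np.inf
        w = 1.0 / v
        xtwx = (xt * w[:, None]).T @ xt
        try:
            c = np.linalg.cholesky(xtwx)
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(xtwx, (xt * w[:, None]).T @ yt)
        r = yt - xt @ beta
        rss = float(r @ (w * r))
        if rss <= 0:
            return np.inf
        sigma2 = rss / (n - p)
        return 0.5 * (
            (n - p) * np.log(sigma2)
            + np.log(v).sum()
            + 2.0 * np.log(np.diag(c)).sum()
            + (n - p)
        )

    if confounded:
        h2 = 0.0
    else:
        res = optimize.minimize_scalar(
            neg_reml, bounds=(0.0, 1.0 - 1e-10), method="bounded",
            options={"xatol": H2_TOL},
        )
        if not res.success:
            raise FitError(f"REML optimization did not converge: {res.message}")
        h2 = float(res.x)
        # the bounded search can stall off a boundary optimum; check the edges
        for edge in (0.0, 1.0 - 1e-10):
            if neg_reml(edge) < neg_reml(h2):
                h2 = edge

    v = h2 * d + (1.0 - h2)
    w = 1.0 / v
    xtwx = (xt * w[:, None]).T @ xt
    xtwx_inv = np.linalg.inv(xtwx)
    alpha = xtwx_inv @ ((xt * w[:, None]).T @ yt)
    r = yt - xt @ alpha
    sigma2 = float(r @ (w * r)) / (n - p)
    sigma_g2 = h2 * sigma2
    sigma_e2 = (1.0 - h2) * sigma2
    boundary = h2 <= H2_TOL or h2 >= 1.0 - 1e-9

    return NullModelFit(
        alpha=alpha,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=h2,
        reml_loglik=-neg_reml(min(h2, 1.0 - 1e-10)),
        boundary=boundary,
        confounded=confounded,
        eigvecs=u,
        eigvals=d,
        s=sigma2 * v,
        xt=xt,
        resid_rot=r,
        xtsx_inv=xtwx_inv * sigma2,
    )


@dataclass
class MarkerTestResult:
    beta: float
    stat: float
    p: float


def single_marker_test(fit: NullModelFit, g_j: np.ndarray) -> MarkerTestResult:
    """Score test of one variant's additive effect under the null fit.

    The score U = g' Sigma^-1 r with null variance V = g' P g gives
    U^2 / V ~ chi2_1 two-sided; beta = U / V is the implied effect estimate.
    """
    g_j = np.asarray(g_j, dtype=float)
    if np.ptp(g_j) == 0:
        raise ValueError("monomorphic variant: single-marker test undefined")
    gr = fit.rotate(g_j[:, None])
    score, cov = fit.project(gr)
    u_ = float(score[0])
    v_ = float(cov[0, 0])
    if v_ <= 0:
        raise ValueError("degenerate score variance (variant in covariate span?)")
    stat = u_ * u_ / v_
    return MarkerTestResult(beta=u_ / v_, stat=stat, p=float(stats.chi2.sf(stat, 1)))
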