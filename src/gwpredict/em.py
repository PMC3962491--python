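"""EM-type variance-component estimation for marker ridge regression.

Two procedures are implemented.  The homoscedastic EM-REML alternates a
mixed-model solve at the current penalty lambda = sigma_e2/sigma_u2 with the
updates

    sigma_e2 <- (y'y - beta0 * 1'y - u'Z'y) / (N - 1)
    sigma_u2 <- (u'u + sigma_e2 * tr C_uu) / m,

where C_uu is the marker block of the inverse coefficient matrix; at
convergence the solve is the BLUP of the marker effects.  The "+" in the
sigma_u2 update is the conditional-expectation (Searle-style) EM form,
which keeps every iterate positive and the restricted likelihood
non-decreasing; the literal textbook variant with a "-" is available via
``FitConfig.em_update`` (floored at the variance floor).

The RMLV modification keeps sigma_e2 fixed at its stage-1 value and
re-estimates one variance per marker each round,

    sigma_l2 <- u_l^2 + sigma_e2 * C_ll        (q_l = 1),

so that markers with persistent signal keep a large variance (small
penalty) while the rest are shrunk towards zero.

Implementation notes: the intercept is absorbed by centering, which is
algebraically exact for this system; the marker block of the inverse
coefficient matrix then equals (Zc'Zc + Lam)^{-1} by the Schur complement.
The homoscedastic loop rides on one thin SVD of the centered dosage matrix
(per-iteration cost O(m)); the RMLV loop needs the diagonal of an inverse
each round, computed by Cholesky (dpotri) for m <= N and by the Woodbury
identity otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, lapack

from .datatypes import (
    FitConfig,
    FormatError,
    ModelFit,
    NumericalError,
    ShrinkageVector,
    VarianceComponents,
)
from .mme import _fit_arrays

_FLOOR_REL = 1e-12  # variance floor, relative to sigma_e2


@dataclass
class EMState:
    """Snapshot of one EM iteration (diagnostics / trace)."""

    sigma_e2: float
    sigma_l2: np.ndarray  # length 1 (homoscedastic) or m (RMLV)
    c_ll: float           # tr C_ll of the component(s) at this iterate
    q_l: int
    iteration: int
    delta: float


class ConvergenceWarning(UserWarning):
    pass


def restricted_log_likelihood(y, Z, sigma_u2: float, sigma_e2: float) -> float:
    """REML log-likelihood of (sigma_u2, sigma_e2) under V = su2*ZZ' + se2*I.

    The intercept (X = 1) is profiled out in the REML sense; the value is
    invariant to adding a constant to y.  Includes the -(N-1)/2 log(2*pi)
    constant.
    """
    if sigma_u2 <= 0 or sigma_e2 <= 0:
        raise FormatError("variances must be > 0")
    yv, Zd, _ = _fit_arrays(y, Z)
    n = yv.size
    V = sigma_u2 * (Zd @ Zd.T)
    V[np.arange(n), np.arange(n)] += sigma_e2
    try:
        c, low = cho_factor(V, lower=True)
    except LinAlgError as exc:
        raise NumericalError("singular covariance matrix") from exc
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    ones = np.ones(n)
    vi_1 = cho_solve((c, low), ones)
    vi_y = cho_solve((c, low), yv)
    xvx = ones @ vi_1
    ypy = yv @ vi_y - (ones @ vi_y) ** 2 / xvx
    return -0.5 * (logdet_v + np.log(xvx) + ypy + (n - 1) * np.log(2.0 * np.pi))


def _svd_setup(yv, Zd):
    ybar = yv.mean()
    zbar = Zd.mean(axis=0)
    Zc = Zd - zbar
    yc = yv - ybar
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    return ybar, zbar, yc, U.T @ yc, s, Vt


def em_homoscedastic_reml(
    y, Z, config: Optional[FitConfig] = None, keep_trace: bool = False
):
    """Homoscedastic EM-REML; returns (VarianceComponents, ModelFit[, trace]).

    The returned fit is the BLUP at the converged penalty
    lambda = sigma_e2 / sigma_u2 and sigma_g2 = m * sigma_u2.
    """
    cfg = config or FitConfig()
    yv, Zd, marker_ids = _fit_arrays(y, Z)
    n, m = Zd.shape
    if n < 3:
        raise FormatError(f"EM-REML needs N >= 3, got {n}")
    ybar, zbar, yc, uy, s, Vt = _svd_setup(yv, Zd)
    s2 = s**2
    r = s.size  # min(n, m); zero singular values handled via + lambda
    Zty = Zd.T @ yv
    ysum = yv.sum()
    yy = yv @ yv
    vary = yv.var(ddof=1) if n > 1 else 1.0
    sigma_e2 = 0.5 * vary if vary > 0 else 1.0
    sigma_u2 = sigma_e2 / m
    trace: List[EMState] = []
    converged = False
    it = 0
    u = np.zeros(m)
    beta0 = ybar
    lam = sigma_e2 / sigma_u2
    for it in range(1, cfg.em_max_iter + 1):
        lam = min(sigma_e2 / sigma_u2, cfg.lambda_cap)
        d = s2 + lam
        u = Vt.T @ (s * uy / d)
        tr_c = (1.0 / d).sum() + max(m - r, 0) / lam
        beta0 = ybar - zbar @ u
        se_new = (yy - beta0 * ysum - u @ Zty) / (n - 1)
        se_new = max(se_new, 1e-300)
        uu = u @ u
        if cfg.em_update == "plus":
            su_new = (uu + sigma_e2 * tr_c) / m
        else:
            su_new = (uu - sigma_e2 * tr_c) / m
        floor = _FLOOR_REL * se_new
        su_new = max(su_new, floor)
        delta = max(
            abs(se_new - sigma_e2) / (sigma_e2 + 1e-12),
            abs(su_new - sigma_u2) / (sigma_u2 + 1e-12),
        )
        sigma_e2, sigma_u2 = se_new, su_new
        if keep_trace:
            trace.append(EMState(sigma_e2, np.array([sigma_u2]), tr_c, m, it, delta))
        if delta < cfg.em_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"homoscedastic EM-REML did not converge in {cfg.em_max_iter} iterations "
            f"(last delta {delta:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    # final solve at the converged penalty
    lam = min(sigma_e2 / sigma_u2, cfg.lambda_cap)
    d = s2 + lam
    u = Vt.T @ (s * uy / d)
    beta0 = ybar - zbar @ u
    vc = VarianceComponents(sigma_e2=sigma_e2, sigma_g2=m * sigma_u2, sigma_u2=sigma_u2)
    fit = ModelFit(
        beta0=float(beta0),
        u_hat=u,
        lambdas=ShrinkageVector(np.full(m, lam)),
        varcomp=vc,
        method="BLUP",
        n_iter=it,
        converged=converged,
        marker_ids=marker_ids,
    )
    if keep_trace:
        return vc, fit, trace
    return vc, fit


def _chol_solve_and_inverse_diag(A: np.ndarray, b: np.ndarray):
    """Solve A x = b and return (x, diag(A^{-1})) for symmetric PD A."""
    c, info = lapack.dpotrf(A, lower=1)
    if info != 0:
        raise NumericalError(f"Cholesky factorization failed (info={info})")
    x, info = lapack.dpotrs(c, b, lower=1)
    if info != 0:
        raise NumericalError("triangular solve failed")
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise NumericalError("inverse from Cholesky failed")
    return x, inv.diagonal().copy()


def fit_rmlv(
    y, Z, config: Optional[FitConfig] = None, keep_trace: bool = False,
    constrain_equal: bool = False,
):
    """Two-stage RMLV fit; returns (VarianceComponents, ModelFit[, trace]).

    Stage 1 is the homoscedastic EM-REML, supplying the residual variance
    (held fixed throughout stage 2) and the common starting value of the
    per-marker variances.  ``constrain_equal`` forces the stage-2 updates to
    stay equal across markers (diagnostic: reproduces the homoscedastic
    fixed point with fixed residual variance).
    """
    cfg = config or FitConfig()
    yv, Zd, marker_ids = _fit_arrays(y, Z)
    n, m = Zd.shape
    if m == 0:
        raise FormatError("no markers")
    stage1 = em_homoscedastic_reml(yv, Zd, cfg, keep_trace=True)
    vc1, _, trace1 = stage1
    if cfg.rmlv_residual == "first_iteration":
        sigma_e2 = trace1[0].sigma_e2
    else:
        sigma_e2 = vc1.sigma_e2
    sigma_l2 = np.full(m, vc1.sigma_u2)
    floor = _FLOOR_REL * sigma_e2

    ybar = yv.mean()
    zbar = Zd.mean(axis=0)
    Zc = Zd - zbar
    yc = yv - ybar
    primal = m <= n
    if primal:
        G = Zc.T @ Zc
        Zcy = Zc.T @ yc
    trace: List[EMState] = []
    converged = False
    it = 0
    u = np.zeros(m)
    for it in range(1, cfg.rmlv_max_iter + 1):
        lam = np.minimum(sigma_e2 / sigma_l2, cfg.lambda_cap)
        if primal:
            A = G.copy()
            A[np.arange(m), np.arange(m)] += lam
            u, c_diag = _chol_solve_and_inverse_diag(A, Zcy)
        else:
            dinv = 1.0 / lam
            K = (Zc * dinv) @ Zc.T
            K[np.arange(n), np.arange(n)] += 1.0
            ch = cho_factor(K, lower=True)
            alpha = cho_solve(ch, yc)
            u = dinv * (Zc.T @ alpha)
            S = cho_solve(ch, Zc)
            c_diag = dinv - dinv**2 * np.einsum("ij,ij->j", Zc, S)
        new = u**2 + sigma_e2 * c_diag if cfg.em_update == "plus" else u**2 - sigma_e2 * c_diag
        if constrain_equal:
            new = np.full(m, (u @ u + sigma_e2 * c_diag.sum()) / m)
        new = np.maximum(new, floor)
        delta = np.max(np.abs(new - sigma_l2) / (sigma_l2 + 1e-12))
        sigma_l2 = new
        if keep_trace:
            trace.append(EMState(sigma_e2, sigma_l2.copy(), float(c_diag.sum()), 1, it, float(delta)))
        if delta < cfg.rmlv_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RMLV stage 2 did not converge in {cfg.rmlv_max_iter} iterations "
            f"(last delta {delta:.3e})",
            ConvergenceWarning,
            stacklevel=2,
        )
    lam = np.minimum(sigma_e2 / sigma_l2, cfg.lambda_cap)
    if primal:
        A = G.copy()
        A[np.arange(m), np.arange(m)] += lam
        u, _ = _chol_solve_and_inverse_diag(A, Zcy)
    else:
        dinv = 1.0 / lam
        K = (Zc * dinv) @ Zc.T
        K[np.arange(n), np.arange(n)] += 1.0
        u = dinv * (Zc.T @ cho_solve(cho_factor(K, lower=True), yc))
    beta0 = ybar - zbar @ u
    vc = VarianceComponents(
        sigma_e2=sigma_e2,
        sigma_g2=vc1.sigma_g2,
        sigma_u2=vc1.sigma_u2,
        sigma_l2=sigma_l2,
    )
    fit = ModelFit(
        beta0=float(beta0),
        u_hat=u,
        lambdas=ShrinkageVector(lam),
        varcomp=vc,
        method="RMLV",
        n_iter=it,
        converged=converged,
        marker_ids=marker_ids,
    )
    if keep_trace:
        return vc, fit, trace
    return vc, fit
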