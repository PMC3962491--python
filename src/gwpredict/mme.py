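"""Build and solve the mixed-model equations of marker ridge regression.

For the model y = 1*beta0 + Z u + e with per-marker penalties lambda_l the
symmetric (m+1) x (m+1) system is

    [ N     1'Z              ] [beta0]   [1'y ]
    [ Z'1   Z'Z + diag(lam)  ] [  u  ] = [Z'y ],

which is positive definite whenever all lambda_l > 0.  Two equivalent
solution paths are provided: a primal Cholesky solve of the full system,
and, for m >> N, a dual (kernel-form) solve obtained by absorbing the
intercept through centering and applying the Woodbury identity

    (Zc'Zc + Lam)^{-1} Zc' yc = Lam^{-1} Zc' (Zc Lam^{-1} Zc' + I)^{-1} yc.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .datatypes import (
    FormatError,
    GenotypeMatrix,
    ModelFit,
    NumericalError,
    PhenotypeVector,
    ShrinkageVector,
    align_phenotype,
)

_RESIDUAL_RTOL = 1e-8


def _fit_arrays(y, Z):
    """Coerce (y, Z) to aligned numpy arrays; align by id when both are typed."""
    marker_ids = None
    if isinstance(Z, GenotypeMatrix):
        Zd = Z.dosages
        marker_ids = Z.marker_ids
        yv = align_phenotype(Z, y) if isinstance(y, PhenotypeVector) else np.asarray(y, float).ravel()
    else:
        Zd = np.asarray(Z, dtype=float)
        yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float).ravel()
    if Zd.ndim != 2:
        raise FormatError("genotype matrix must be 2-D")
    if yv.size != Zd.shape[0]:
        raise FormatError(
            f"phenotype length {yv.size} does not match {Zd.shape[0]} genotype rows"
        )
    if not (np.all(np.isfinite(yv)) and np.all(np.isfinite(Zd))):
        raise FormatError("non-finite entries in phenotype or genotypes")
    return yv, Zd, marker_ids


def _solve_primal(yv, Zd, lam):
    n, m = Zd.shape
    A = np.empty((m + 1, m + 1))
    colsum = Zd.sum(axis=0)
    A[0, 0] = n
    A[0, 1:] = colsum
    A[1:, 0] = colsum
    A[1:, 1:] = Zd.T @ Zd
    A[np.arange(1, m + 1), np.arange(1, m + 1)] += lam
    rhs = np.concatenate(([yv.sum()], Zd.T @ yv))
    try:
        x = cho_solve(cho_factor(A, lower=True), rhs)
    except LinAlgError as exc:
        raise NumericalError(
            f"mixed-model equations not positive definite (cond ~ {np.linalg.cond(A):.3e})"
        ) from exc
    resid = np.linalg.norm(A @ x - rhs)
    if resid > _RESIDUAL_RTOL * max(np.linalg.norm(rhs), 1.0):
        raise NumericalError(
            f"ill-conditioned mixed-model equations: residual {resid:.3e} "
            f"(cond ~ {np.linalg.cond(A):.3e})"
        )
    return x[0], x[1:]


def _solve_dual(yv, Zd, lam):
    n = Zd.shape[0]
    ybar = yv.mean()
    zbar = Zd.mean(axis=0)
    Zc = Zd - zbar
    yc = yv - ybar
    d = 1.0 / lam
    K = (Zc * d) @ Zc.T
    K[np.arange(n), np.arange(n)] += 1.0
    try:
        alpha = cho_solve(cho_factor(K, lower=True), yc)
    except LinAlgError as exc:
        raise NumericalError("dual kernel matrix not positive definite") from exc
    u = d * (Zc.T @ alpha)
    beta0 = ybar - zbar @ u
    # residual of the primal system, computed without forming it
    colsum = Zd.sum(axis=0)
    r0 = n * beta0 + colsum @ u - yv.sum()
    r1 = colsum * beta0 + Zd.T @ (Zd @ u) + lam * u - Zd.T @ yv
    resid = np.sqrt(r0**2 + r1 @ r1)
    rhs_norm = np.linalg.norm(np.concatenate(([yv.sum()], Zd.T @ yv)))
    if resid > _RESIDUAL_RTOL * max(rhs_norm, 1.0):
        raise NumericalError(f"dual solve residual too large: {resid:.3e}")
    return beta0, u


def solve_mme(y, Z, lam, method: str = "auto", label: str = "ridge") -> ModelFit:
    """Solve the mixed-model equations for a given shrinkage vector.

    ``method`` selects the solution path: "primal" (full Cholesky),
    "dual" (kernel form, efficient for m >> N) or "auto".
    """
    yv, Zd, marker_ids = _fit_arrays(y, Z)
    lam_vec = lam.lambdas if isinstance(lam, ShrinkageVector) else np.asarray(lam, float).ravel()
    if lam_vec.size != Zd.shape[1]:
        raise FormatError(f"{lam_vec.size} penalties for {Zd.shape[1]} markers")
    if np.any(lam_vec <= 0) or not np.all(np.isfinite(lam_vec)):
        raise FormatError("penalties must be finite and > 0")
    if method == "auto":
        method = "dual" if Zd.shape[1] > 2 * Zd.shape[0] else "primal"
    if method == "primal":
        beta0, u = _solve_primal(yv, Zd, lam_vec)
    elif method == "dual":
        beta0, u = _solve_dual(yv, Zd, lam_vec)
    else:
        raise FormatError(f"unknown solver method {method!r}")
    return ModelFit(
        beta0=float(beta0),
        u_hat=u,
        lambdas=ShrinkageVector(lam_vec),
        method=label,
        marker_ids=marker_ids,
    )


def predict_genotypic_values(fit: ModelFit, Z_new) -> np.ndarray:
    """Predicted genotypic values beta0 + Z_new @ u_hat.

    ``Z_new`` must carry the training markers in the training order; a
    mismatch of marker ids raises, listing the offenders.
    """
    if isinstance(Z_new, GenotypeMatrix):
        Zd = Z_new.dosages
        if fit.marker_ids is not None:
            if list(Z_new.marker_ids) != list(fit.marker_ids):
                off = [
                    f"{a}!={b}"
                    for a, b in zip(Z_new.marker_ids, fit.marker_ids)
                    if a != b
                ] or ["marker count differs"]
                raise FormatError(f"marker mismatch with training fit: {off[:5]}")
    else:
        Zd = np.asarray(Z_new, dtype=float)
    if Zd.ndim != 2 or Zd.shape[1] != fit.u_hat.size:
        raise FormatError(
            f"prediction matrix has {Zd.shape[1] if Zd.ndim == 2 else '?'} markers, "
            f"fit has {fit.u_hat.size}"
        )
    return fit.beta0 + Zd @ fit.u_hat
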