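"""Scikit-learn style estimators for the five genome-wide prediction methods.

Every estimator fits the marker ridge model y = beta0 + Z u + e and differs
only in how the per-marker penalties lambda_l are constructed:

================  =============================================================
RIRRegressor      constant lambda = (1/hp2 - 1) * m from a heritability guess
BLUPRegressor     constant lambda = sigma_e2/sigma_u2 from homoscedastic EM-REML
RMLARegressor     ANOVA-weighted penalties scaled by REML variance components
RRWARegressor     ANOVA-weighted penalties scaled by a heritability guess
RMLVRegressor     per-marker variances from the fixed-residual EM modification
================  =============================================================

All estimators accept a plain (N, m) dosage array or a GenotypeMatrix, and
expose ``coef_`` (marker effects), ``intercept_``, ``lambdas_`` and the full
``model_fit_`` after fitting, so they compose with sklearn pipelines and
model selection.
"""

from __future__ import annotations

from typing import Optional

from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import anova, em, mme
from .datatypes import FitConfig, FormatError, VarianceComponents

METHODS = ("rir", "blup", "rmla", "rrwa", "rmlv")


class _MarkerRidgeBase(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing of the marker ridge estimators."""

    method_label = "ridge"

    def _set_fit(self, fit, varcomp=None):
        self.model_fit_ = fit
        self.coef_ = fit.u_hat
        self.intercept_ = fit.beta0
        self.lambdas_ = fit.lambdas.lambdas
        self.varcomp_ = varcomp if varcomp is not None else fit.varcomp
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.n_features_in_ = fit.u_hat.size
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return mme.predict_genotypic_values(self.model_fit_, X)


class RIRRegressor(_MarkerRidgeBase):
    """Ridge regression with a constant penalty from a preliminary heritability."""

    method_label = "RIR"

    def __init__(self, hp2: float = 0.5, lambda_cap: float = 1e12):
        self.hp2 = hp2
        self.lambda_cap = lambda_cap

    def fit(self, X, y):
        yv, Zd, _ = mme._fit_arrays(y, X)
        lam = anova.rir_shrinkage(self.hp2, Zd.shape[1], cap=self.lambda_cap)
        fit = mme.solve_mme(y, X, lam, label=self.method_label)
        fit.method = self.method_label
        return self._set_fit(fit)


class BLUPRegressor(_MarkerRidgeBase):
    """SNP-BLUP: homoscedastic marker variances estimated by EM-REML."""

    method_label = "BLUP"

    def __init__(
        self,
        em_tol: float = 1e-8,
        em_max_iter: int = 1000,
        lambda_cap: float = 1e12,
        em_update: str = "plus",
    ):
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.lambda_cap = lambda_cap
        self.em_update = em_update

    def _config(self) -> FitConfig:
        return FitConfig(
            em_tol=self.em_tol,
            em_max_iter=self.em_max_iter,
            lambda_cap=self.lambda_cap,
            em_update=self.em_update,
        )

    def fit(self, X, y):
        vc, fit = em.em_homoscedastic_reml(y, X, self._config())
        return self._set_fit(fit, vc)


class RMLARegressor(_MarkerRidgeBase):
    """ANOVA-weighted penalties scaled by EM-REML variance components."""

    method_label = "RMLA"

    def __init__(
        self,
        em_tol: float = 1e-8,
        em_max_iter: int = 1000,
        lambda_cap: float = 1e12,
        em_update: str = "plus",
    ):
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.lambda_cap = lambda_cap
        self.em_update = em_update

    def fit(self, X, y):
        cfg = FitConfig(
            em_tol=self.em_tol,
            em_max_iter=self.em_max_iter,
            lambda_cap=self.lambda_cap,
            em_update=self.em_update,
        )
        vc_reml, _ = em.em_homoscedastic_reml(y, X, cfg)
        summary = anova.single_marker_anova(y, X)
        sstar = anova.anova_variance_component(summary)
        lam = anova.rmla_shrinkage(
            vc_reml.sigma_e2, vc_reml.sigma_g2, sstar, cap=self.lambda_cap
        )
        fit = mme.solve_mme(y, X, lam, label=self.method_label)
        vc = VarianceComponents(
            sigma_e2=vc_reml.sigma_e2,
            sigma_g2=vc_reml.sigma_g2,
            sigma_u2=vc_reml.sigma_u2,
            sigma_l2=anova.partition_genetic_variance(vc_reml.sigma_g2, sstar)
            if sstar.sum() > 0
            else None,
            sigma_l2_star=sstar,
        )
        fit.varcomp = vc
        return self._set_fit(fit, vc)


class RRWARegressor(_MarkerRidgeBase):
    """ANOVA-weighted penalties scaled by a preliminary heritability."""

    method_label = "RRWA"

    def __init__(self, hp2: float = 0.5, lambda_cap: float = 1e12):
        self.hp2 = hp2
        self.lambda_cap = lambda_cap

    def fit(self, X, y):
        summary = anova.single_marker_anova(y, X)
        sstar = anova.anova_variance_component(summary)
        lam = anova.rrwa_shrinkage(self.hp2, sstar, cap=self.lambda_cap)
        fit = mme.solve_mme(y, X, lam, label=self.method_label)
        fit.varcomp = VarianceComponents(
            sigma_e2=0.0, sigma_g2=0.0, sigma_l2_star=sstar
        )
        return self._set_fit(fit)


class RMLVRegressor(_MarkerRidgeBase):
    """Fixed-residual EM with one variance per marker (strong selective shrinkage)."""

    method_label = "RMLV"

    def __init__(
        self,
        em_tol: float = 1e-8,
        em_max_iter: int = 1000,
        rmlv_tol: float = 1e-6,
        rmlv_max_iter: int = 500,
        lambda_cap: float = 1e12,
        em_update: str = "plus",
        rmlv_residual: str = "converged",
    ):
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.rmlv_tol = rmlv_tol
        self.rmlv_max_iter = rmlv_max_iter
        self.lambda_cap = lambda_cap
        self.em_update = em_update
        self.rmlv_residual = rmlv_residual

    def fit(self, X, y):
        cfg = FitConfig(
            em_tol=self.em_tol,
            em_max_iter=self.em_max_iter,
            rmlv_tol=self.rmlv_tol,
            rmlv_max_iter=self.rmlv_max_iter,
            lambda_cap=self.lambda_cap,
            em_update=self.em_update,
            rmlv_residual=self.rmlv_residual,
        )
        vc, fit = em.fit_rmlv(y, X, cfg)
        return self._set_fit(fit, vc)


def make_estimator(method: str, config: Optional[FitConfig] = None) -> _MarkerRidgeBase:
    """Instantiate an estimator by its lower-case method label."""
    cfg = config or FitConfig()
    method = method.lower()
    if method == "rir":
        return RIRRegressor(hp2=cfg.hp2, lambda_cap=cfg.lambda_cap)
    if method == "blup":
        return BLUPRegressor(
            em_tol=cfg.em_tol,
            em_max_iter=cfg.em_max_iter,
            lambda_cap=cfg.lambda_cap,
            em_update=cfg.em_update,
        )
    if method == "rmla":
        return RMLARegressor(
            em_tol=cfg.em_tol,
            em_max_iter=cfg.em_max_iter,
            lambda_cap=cfg.lambda_cap,
            em_update=cfg.em_update,
        )
    if method == "rrwa":
        return RRWARegressor(hp2=cfg.hp2, lambda_cap=cfg.lambda_cap)
    if method == "rmlv":
        return RMLVRegressor(
            em_tol=cfg.em_tol,
            em_max_iter=cfg.em_max_iter,
            rmlv_tol=cfg.rmlv_tol,
            rmlv_max_iter=cfg.rmlv_max_iter,
            lambda_cap=cfg.lambda_cap,
            em_update=cfg.em_update,
            rmlv_residual=cfg.rmlv_residual,
        )
    raise FormatError(f"unknown method {method!r}; choose from {METHODS}")


def fit_method(y, Z, method: str, config: Optional[FitConfig] = None):
    """Fit one method by label and return its ModelFit."""
    est = make_estimator(method, config)
    est.fit(Z, y)
    return est.model_fit_
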