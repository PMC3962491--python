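"""Single-marker ANOVA variance components and shrinkage-factor construction.

For every marker a random one-way ANOVA of the phenotype on the observed
dosage classes (0/1/2) gives mean squares MQM_l (between classes) and
MQE_l (within classes).  The moment estimator of the marker variance
component in the unbalanced one-way layout is

    sigma_l2* = (MQM_l - MQE_l) / [ (N - sum_i n_i^2 / N) / (a_l - 1) ],

truncated below at zero, with a_l the number of observed classes (the
classical printed form with a factor 1/2 in the denominator is the a = 3
special case; doubled-haploid data have a = 2).  The sigma_l2* are not a
partition of the genetic variance, but they serve as weights to spread the
total genetic variance over markers and hence to build marker-specific
ridge penalties:

    RIR    lambda_l = (1/hp2 - 1) * m                       (constant)
    RMLA   lambda_l = (sigma_e2/sigma_g2) * S / sigma_l2*   (S = sum sigma_l2*)
    RRWA   lambda_l = (1/hp2 - 1)        * S / sigma_l2*

RRWA equals RMLA when hp2 = sigma_g2 / (sigma_g2 + sigma_e2), and both
collapse to RIR when all sigma_l2* are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FormatError, GenotypeMatrix, PhenotypeVector, ShrinkageVector

DOSAGE_CLASSES = (0, 1, 2)


@dataclass
class AnovaSummary:
    """Per-marker one-way ANOVA mean squares and class layout."""

    mqm: np.ndarray          # between-class mean square per marker
    mqe: np.ndarray          # within-class mean square per marker
    class_counts: np.ndarray  # (m, 3) individuals per dosage class
    n_classes: np.ndarray    # observed classes per marker (1, 2 or 3)
    N: int

    def __post_init__(self):
        self.mqm = np.asarray(self.mqm, dtype=float).ravel()
        self.mqe = np.asarray(self.mqe, dtype=float).ravel()
        self.class_counts = np.asarray(self.class_counts, dtype=int)
        self.n_classes = np.asarray(self.n_classes, dtype=int).ravel()
        if not (self.class_counts.sum(axis=1) == self.N).all():
            raise FormatError("class counts of some marker do not sum to N")
        if np.any(self.mqe < -1e-9) or not np.isin(self.n_classes, (1, 2, 3)).all():
            raise FormatError("invalid ANOVA summary")


def _arrays(y, Z):
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float).ravel()
    Zd = Z.dosages if isinstance(Z, GenotypeMatrix) else np.asarray(Z, dtype=float)
    if isinstance(Z, GenotypeMatrix) and Z.imputed:
        Zd = np.rint(Zd)  # class assignment uses the nearest integer dosage
    if Zd.ndim != 2 or yv.size != Zd.shape[0]:
        raise FormatError("phenotype length does not match genotype rows")
    return yv, Zd


def single_marker_anova(y, Z) -> AnovaSummary:
    """One-way ANOVA of y on the dosage classes of every marker.

    Monomorphic markers (one observed class) get MQM = MQE = 0 by
    convention.  Raises when a polymorphic marker leaves no within-class
    degrees of freedom (N - a <= 0).
    """
    yv, Zd = _arrays(y, Z)
    N = yv.size
    if N < 3:
        raise FormatError(f"ANOVA needs N >= 3 individuals, got {N}")
    m = Zd.shape[1]
    counts = np.empty((m, 3), dtype=int)
    sums = np.empty((m, 3))
    for c in DOSAGE_CLASSES:
        mask = Zd == c
        counts[:, c] = mask.sum(axis=0)
        sums[:, c] = mask.T @ yv
    a = (counts > 0).sum(axis=1)
    bad = (a > 1) & (N - a <= 0)
    if bad.any():
        raise FormatError("degenerate data: no within-class degrees of freedom")
    ytot = yv.sum()
    yss = yv @ yv
    with np.errstate(divide="ignore", invalid="ignore"):
        group_term = np.where(counts > 0, sums**2 / np.maximum(counts, 1), 0.0).sum(axis=1)
    ss_between = np.maximum(group_term - ytot**2 / N, 0.0)
    ss_within = np.maximum(yss - group_term, 0.0)
    mqm = np.where(a > 1, ss_between / np.maximum(a - 1, 1), 0.0)
    mqe = np.where(a > 1, ss_within / np.maximum(N - a, 1), 0.0)
    return AnovaSummary(mqm, mqe, counts, a, N)


def anova_variance_component(s: AnovaSummary) -> np.ndarray:
    """Moment estimates sigma_l2* from an AnovaSummary, truncated at zero."""
    N = s.N
    denom_num = N - (s.class_counts.astype(float) ** 2).sum(axis=1) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = denom_num / np.maximum(s.n_classes - 1, 1)
        sstar = (s.mqm - s.mqe) / denom
    sstar = np.where((s.n_classes > 1) & (denom > 0), sstar, 0.0)
    return np.maximum(sstar, 0.0)


def partition_genetic_variance(sigma_g2: float, sstar: np.ndarray) -> np.ndarray:
    """Spread the total genetic variance over markers proportionally to sigma_l2*."""
    if sigma_g2 < 0 or not np.isfinite(sigma_g2):
        raise FormatError(f"sigma_g2 must be finite and >= 0, got {sigma_g2}")
    sstar = np.asarray(sstar, dtype=float).ravel()
    total = sstar.sum()
    if total <= 0:
        raise FormatError("all single-marker variance components are zero: no partition defined")
    return sigma_g2 * (sstar / total)


def _capped(lam: np.ndarray, cap: float) -> ShrinkageVector:
    return ShrinkageVector(np.minimum(lam, cap))


def _weight_ratio(sstar: np.ndarray) -> np.ndarray:
    """S / sigma_l2* computed scale-invariantly.

    Normalizing by the largest component makes the homoscedastic case exact
    (all ratios collapse to the integer m), so RRWA reduces to RIR without
    rounding noise.  Entries with sigma_l2* == 0 come back as +inf and are
    capped by the caller.
    """
    top = sstar.max()
    if top <= 0:
        raise FormatError("all single-marker variance components are zero")
    w = sstar / top
    total = w.sum()
    with np.errstate(divide="ignore"):
        return np.where(w > 0, total / np.maximum(w, 1e-300), np.inf)


def rir_shrinkage(hp2: float, m: int, cap: float = 1e12) -> ShrinkageVector:
    """Constant penalty lambda = (1/hp2 - 1) * m from a preliminary heritability."""
    if not (0 < hp2 < 1):
        raise FormatError(f"hp2 must be in (0, 1), got {hp2}")
    if m < 1:
        raise FormatError("need at least one marker")
    return _capped(np.full(m, (1.0 / hp2 - 1.0) * m), cap)


def rmla_shrinkage(
    sigma_e2: float, sigma_g2: float, sstar: np.ndarray, cap: float = 1e12
) -> ShrinkageVector:
    """REML-scaled ANOVA-weighted penalties lambda_l = (se2/sg2) * S / sstar_l."""
    if sigma_g2 <= 0:
        raise FormatError(f"sigma_g2 must be > 0, got {sigma_g2}")
    if sigma_e2 <= 0:
        raise FormatError(f"sigma_e2 must be > 0, got {sigma_e2}")
    sstar = np.asarray(sstar, dtype=float).ravel()
    ratio = _weight_ratio(sstar)
    lam = np.where(np.isfinite(ratio), (sigma_e2 / sigma_g2) * ratio, cap)
    return _capped(lam, cap)


def rrwa_shrinkage(hp2: float, sstar: np.ndarray, cap: float = 1e12) -> ShrinkageVector:
    """Heritability-scaled ANOVA-weighted penalties lambda_l = (1/hp2-1) * S / sstar_l."""
    if not (0 < hp2 < 1):
        raise FormatError(f"hp2 must be in (0, 1), got {hp2}")
    sstar = np.asarray(sstar, dtype=float).ravel()
    ratio = _weight_ratio(sstar)
    lam = np.where(np.isfinite(ratio), (1.0 / hp2 - 1.0) * ratio, cap)
    return _capped(lam, cap)
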