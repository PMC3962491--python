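"""Core data containers for genome-wide prediction.

The containers mirror the quantities of the marker ridge-regression model

    y = 1 * beta0 + Z u + e,

where ``Z`` is an N x m matrix of allele dosages (0/1/2), ``u`` the vector
of marker effects shrunk by per-marker penalties ``lambda_l``, and ``e``
the residual.  All containers validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


class GwpError(Exception):
    """Base class for package errors."""


class FormatError(GwpError, ValueError):
    """Malformed or invalid input data."""


class NumericalError(GwpError, RuntimeError):
    """A numerical routine failed or produced an untrustworthy result."""


def _check_unique(ids: Sequence[str], what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise FormatError(f"duplicate {what}: {sorted(dups)[:5]}")
    return ids


@dataclass
class GenotypeMatrix:
    """N x m matrix of biallelic marker dosages.

    Dosages count copies of one of the two alleles, so each cell is in
    {0, 1, 2}.  When ``imputed`` is true (mean-imputed missing cells) the
    values may be fractional but must stay within [0, 2].
    """

    dosages: np.ndarray
    individual_ids: list
    marker_ids: list
    imputed: bool = False

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise FormatError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if n < 2 or m < 1:
            raise FormatError(f"need at least 2 individuals and 1 marker, got {n}x{m}")
        self.individual_ids = _check_unique(self.individual_ids, "individual ids")
        self.marker_ids = _check_unique(self.marker_ids, "marker ids")
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise FormatError("id list lengths do not match matrix shape")
        if not np.all(np.isfinite(self.dosages)):
            raise FormatError("non-finite dosage values")
        if self.imputed:
            if self.dosages.min() < 0 or self.dosages.max() > 2:
                raise FormatError("imputed dosages must lie in [0, 2]")
        elif not np.isin(self.dosages, (0.0, 1.0, 2.0)).all():
            bad = np.argwhere(~np.isin(self.dosages, (0.0, 1.0, 2.0)))[0]
            raise FormatError(
                f"dosage not in {{0,1,2}} at individual "
                f"'{self.individual_ids[bad[0]]}', marker '{self.marker_ids[bad[1]]}'"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PhenotypeVector:
    """Vector of N phenotypic values paired with individual identifiers."""

    values: np.ndarray
    individual_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.individual_ids = _check_unique(self.individual_ids, "individual ids")
        if len(self.individual_ids) != self.values.size:
            raise FormatError("phenotype id list length does not match values")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("phenotype values must be finite (no missing values)")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GeneticMap:
    """Marker positions (Morgan) along labelled chromosomes.

    Positions must be strictly increasing within each chromosome; marker
    order is the file/genome order.
    """

    marker_ids: list
    chromosome: list
    position_morgan: np.ndarray

    def __post_init__(self):
        self.marker_ids = _check_unique(self.marker_ids, "marker ids")
        self.chromosome = [str(c) for c in self.chromosome]
        self.position_morgan = np.asarray(self.position_morgan, dtype=float).ravel()
        m = len(self.marker_ids)
        if len(self.chromosome) != m or self.position_morgan.size != m:
            raise FormatError("map column lengths differ")
        if np.any(self.position_morgan < 0) or not np.all(np.isfinite(self.position_morgan)):
            raise FormatError("map positions must be finite and non-negative")
        pos = self.position_morgan
        chrom = np.asarray(self.chromosome)
        for c in dict.fromkeys(self.chromosome):  # preserve appearance order
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.marker_ids)


@dataclass
class ShrinkageVector:
    """Per-marker ridge penalties lambda_l (diagonal of the penalty matrix)."""

    lambdas: np.ndarray

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float).ravel()
        if self.lambdas.size < 1:
            raise FormatError("empty shrinkage vector")
        if np.any(self.lambdas <= 0) or not np.all(np.isfinite(self.lambdas)):
            raise FormatError("shrinkage penalties must be finite and > 0")

    def __len__(self) -> int:
        return self.lambdas.size


@dataclass
class VarianceComponents:
    """Variance components of the marker model.

    ``sigma_u2`` is the homoscedastic per-marker variance (BLUP);
    ``sigma_l2`` the heteroscedastic per-marker variances; ``sigma_l2_star``
    the single-marker ANOVA moment estimates used as partition weights.
    """

    sigma_e2: float
    sigma_g2: float
    sigma_u2: Optional[float] = None
    sigma_l2: Optional[np.ndarray] = None
    sigma_l2_star: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("sigma_e2", "sigma_g2", "sigma_u2"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise FormatError(f"{name} must be finite and >= 0, got {v}")
        for name in ("sigma_l2", "sigma_l2_star"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float).ravel()
                if np.any(v < 0) or not np.all(np.isfinite(v)):
                    raise FormatError(f"{name} entries must be finite and >= 0")
                setattr(self, name, v)


@dataclass
class FitConfig:
    """Tuning parameters shared by the fitting methods.

    hp2            preliminary heritability guess in (0, 1), for RIR/RRWA
    em_tol         relative-change tolerance of the homoscedastic EM
    em_max_iter    iteration cap of the homoscedastic EM
    rmlv_tol       relative-change tolerance of the per-marker (RMLV) stage
    rmlv_max_iter  iteration cap of the RMLV stage
    lambda_cap     ceiling on any penalty (markers with zero variance get it)
    em_update      "plus" (standard EM-REML) or "minus" (literal printed form)
    rmlv_residual  "converged" or "first_iteration" stage-1 residual variance
    """

    hp2: float = 0.5
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    rmlv_tol: float = 1e-6
    rmlv_max_iter: int = 500
    lambda_cap: float = 1e12
    seed: int = 0
    em_update: str = "plus"
    rmlv_residual: str = "converged"

    def __post_init__(self):
        if not (0 < self.hp2 < 1):
            raise FormatError(f"hp2 must be in (0, 1), got {self.hp2}")
        if self.em_tol <= 0 or self.rmlv_tol <= 0:
            raise FormatError("tolerances must be > 0")
        if self.em_max_iter < 1 or self.rmlv_max_iter < 1:
            raise FormatError("iteration caps must be >= 1")
        if self.lambda_cap <= 0:
            raise FormatError("lambda_cap must be > 0")
        if self.em_update not in ("plus", "minus"):
            raise FormatError("em_update must be 'plus' or 'minus'")
        if self.rmlv_residual not in ("converged", "first_iteration"):
            raise FormatError("rmlv_residual must be 'converged' or 'first_iteration'")


@dataclass
class ModelFit:
    """Result of solving the mixed-model equations for one method."""

    beta0: float
    u_hat: np.ndarray
    lambdas: ShrinkageVector
    varcomp: Optional[VarianceComponents] = None
    method: str = "ridge"
    n_iter: int = 0
    converged: bool = True
    marker_ids: Optional[list] = None

    def __post_init__(self):
        self.u_hat = np.asarray(self.u_hat, dtype=float).ravel()
        if self.u_hat.size != len(self.lambdas):
            raise FormatError("u_hat and shrinkage vector lengths differ")
        if self.marker_ids is not None and len(self.marker_ids) != self.u_hat.size:
            raise FormatError("marker id list length does not match u_hat")


def align_phenotype(geno: GenotypeMatrix, pheno: PhenotypeVector) -> np.ndarray:
    """Return phenotype values reordered to the genotype individual order.

    The two id sets must match exactly; row order in either input is
    irrelevant, so permuting file rows cannot change a downstream fit.
    """
    idx = {pid: k for k, pid in enumerate(pheno.individual_ids)}
    missing = [i for i in geno.individual_ids if i not in idx]
    if missing:
        raise FormatError(f"individuals without phenotype: {missing[:5]}")
    extra = set(pheno.individual_ids) - set(geno.individual_ids)
    if extra:
        raise FormatError(f"phenotyped individuals missing from genotypes: {sorted(extra)[:5]}")
    return pheno.values[[idx[i] for i in geno.individual_ids]]
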