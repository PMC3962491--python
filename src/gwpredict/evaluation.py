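"""Cross-validation and effect-accuracy summaries.

Prediction accuracy is assessed by repeated random subsampling: each run
draws floor(train_fraction * N) individuals without replacement as the
training set, fits one method, predicts the held-out individuals and
records the Pearson correlation between observed and predicted phenotypic
values (default 100 runs at an 80/20 split).  Runs with zero-variance
predictions are flagged undefined and excluded from the mean.

Effect accuracy against a simulated truth is summarized three ways: the
mean squared error of the per-marker mean effect profile against a
zero-baseline truth profile (the per-allele QTL effect assigned to the
marker nearest each QTL, zero elsewhere), the summed estimated effects of
all markers within a window around each QTL, and the maximum absolute
estimated effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import FitConfig, FormatError, GeneticMap
from .estimators import make_estimator
from .mme import _fit_arrays


@dataclass
class CVResult:
    per_run_correlation: np.ndarray  # NaN marks an undefined run
    mean_correlation: float
    n_runs: int
    train_fraction: float
    method: str
    seed: Optional[int]
    n_undefined: int = 0

    def __post_init__(self):
        self.per_run_correlation = np.asarray(self.per_run_correlation, dtype=float)
        ok = self.per_run_correlation[~np.isnan(self.per_run_correlation)]
        if ok.size and (np.any(ok < -1 - 1e-12) or np.any(ok > 1 + 1e-12)):
            raise FormatError("correlations outside [-1, 1]")


def cross_validate(
    y,
    Z,
    method: str,
    config: Optional[FitConfig] = None,
    n_runs: int = 100,
    train_fraction: float = 0.8,
    rng=None,
) -> CVResult:
    """Repeated random-subsampling cross-validation of one method."""
    if not (0 < train_fraction < 1):
        raise FormatError("train_fraction must be in (0, 1)")
    cfg = config or FitConfig()
    seed = None
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = cfg.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    yv, Zd, _ = _fit_arrays(y, Z)
    n = yv.size
    n_train = int(np.floor(train_fraction * n))
    if n_train < 3:
        raise FormatError(f"training set of {n_train} individuals is too small")
    corrs = np.empty(n_runs)
    n_undef = 0
    for run in range(n_runs):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        assert tr.size + va.size == n and np.union1d(tr, va).size == n  # no leakage
        est = make_estimator(method, cfg)
        est.fit(Zd[tr], yv[tr])
        pred = est.predict(Zd[va])
        obs = yv[va]
        if np.std(pred) == 0 or np.std(obs) == 0:
            corrs[run] = np.nan
            n_undef += 1
            continue
        corrs[run] = np.corrcoef(obs, pred)[0, 1]
    defined = corrs[~np.isnan(corrs)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return CVResult(corrs, mean, n_runs, train_fraction, method, seed, n_undef)


@dataclass
class EffectAccuracy:
    profile_mse: float
    window_sums: dict            # qtl_id -> summed estimated effect in the window
    max_abs_effect: float
    missing_qtl: list = field(default_factory=list)


def effect_accuracy_summary(
    u_hat_mean: np.ndarray,
    truth: pd.DataFrame,
    gmap: GeneticMap,
    window_cM: float = 5.0,
) -> EffectAccuracy:
    """Summarize an effect profile against simulated QTL truth.

    ``truth`` needs columns qtl_id, chromosome, position_morgan and
    effect_per_allele (as produced by ``popsim.build_genome``).
    """
    u = np.asarray(u_hat_mean, dtype=float).ravel()
    if u.size != len(gmap):
        raise FormatError("effect vector length does not match the map")
    if len(truth) == 0:
        raise FormatError("empty truth table")
    chrom = np.asarray(gmap.chromosome)
    pos = gmap.position_morgan
    profile = np.zeros(u.size)
    window = window_cM / 100.0
    window_sums = {}
    missing = []
    for _, row in truth.iterrows():
        on_chr = np.flatnonzero(chrom == str(row["chromosome"]))
        if on_chr.size == 0:
            missing.append(row["qtl_id"])
            continue
        dist = np.abs(pos[on_chr] - row["position_morgan"])
        profile[on_chr[np.argmin(dist)]] += row["effect_per_allele"]
        in_window = on_chr[dist <= window + 1e-12]
        if in_window.size == 0:
            missing.append(row["qtl_id"])
            window_sums[row["qtl_id"]] = 0.0
        else:
            window_sums[row["qtl_id"]] = float(u[in_window].sum())
    mse = float(np.mean((u - profile) ** 2))
    return EffectAccuracy(mse, window_sums, float(np.max(np.abs(u))), missing)
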