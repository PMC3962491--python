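"""Doubled-haploid population simulator for genome-wide prediction studies.

The simulated design: two fully inbred parents (P1 carrying allele 1 at
every locus, including the favorable allele of each QTL; P2 carrying
allele 0) are crossed to an F1, which is randomly intermated for ``ngen``
non-overlapping generations (random pairs with replacement, selfing
excluded).  From the final generation, ``n_dh`` doubled-haploid (DH) lines
are derived, each by doubling one random gamete, so every DH line is fully
homozygous with marker dosages in {0, 2}.

Meiosis follows the Haldane model: per chromosome the crossover count is
Poisson with mean equal to the map length in Morgan, crossover positions
are uniform and there is no interference, giving recombination fraction
r = (1 - exp(-2d))/2 at map distance d.

The default genome has 10 chromosomes of 1.6 Morgan, markers on an even
grid (both telomeres included) at spacing ``marker_dist_cM``, and two QTL
per chromosome at 0.401 and 1.201 Morgan — off the marker grid for the
standard spacings of 1, 2 and 5 cM.  Each QTL has a per-allele effect
(default 2.5 trait units), so homozygous DH classes differ by 5.
Phenotypes add an i.i.d. normal residual whose variance is calibrated from
the empirical genotypic variance of the realized sample to hit the target
heritability h2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import FormatError, GeneticMap, GenotypeMatrix, PhenotypeVector
from .estimators import fit_method
from .datatypes import FitConfig


@dataclass
class SimConfig:
    """Design of one simulation study (defaults = the standard scenario)."""

    n_chr: int = 10
    chr_length_morgan: float = 1.6
    marker_dist_cM: float = 1.0
    qtl_positions_morgan: Sequence[float] = (0.401, 1.201)
    qtl_allele_effect: float = 2.5
    ngen: int = 3
    n_intermate: int = 1000
    n_dh: int = 600
    h2: float = 0.8
    n_reps: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.marker_dist_cM <= 0:
            raise FormatError("marker distance must be > 0")
        if self.ngen < 0 or self.n_dh < 2 or self.n_chr < 1:
            raise FormatError("invalid simulation design")
        if not (0 < self.h2 <= 1):
            raise FormatError("h2 must be in (0, 1]")
        for q in self.qtl_positions_morgan:
            if not (0 <= q <= self.chr_length_morgan):
                raise FormatError(f"QTL position {q} outside [0, {self.chr_length_morgan}]")


@dataclass
class Population:
    """A set of individuals as haplotype pairs over marker and QTL loci.

    ``haplotypes[c]`` has shape (n_individuals, 2, n_loci_c) with allele
    labels 0 (parent-2) and 1 (parent-1, favorable at QTL).
    """

    haplotypes: List[np.ndarray]
    positions: List[np.ndarray]      # per-chromosome locus positions (Morgan)
    is_qtl: List[np.ndarray]         # per-chromosome boolean masks
    chrom_names: List[str]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes[0].shape[0]

    def is_fully_homozygous(self) -> bool:
        return all((h[:, 0, :] == h[:, 1, :]).all() for h in self.haplotypes)

    def marker_dosages(self) -> np.ndarray:
        """(n, m) allele-1 counts at marker loci, chromosome by chromosome."""
        blocks = [
            h[:, :, ~q].sum(axis=1) for h, q in zip(self.haplotypes, self.is_qtl)
        ]
        return np.concatenate(blocks, axis=1)

    def qtl_allele_counts(self) -> np.ndarray:
        blocks = [
            h[:, :, q].sum(axis=1) for h, q in zip(self.haplotypes, self.is_qtl)
        ]
        return np.concatenate(blocks, axis=1)

    def marker_ids(self) -> list:
        out = []
        for name, pos, q in zip(self.chrom_names, self.positions, self.is_qtl):
            out.extend(f"{name}_m{j}" for j in range(int((~q).sum())))
        return out

    def individual_ids(self) -> list:
        return [f"DH{i + 1:04d}" for i in range(self.n_individuals)]

    def to_genotype_matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            self.marker_dosages().astype(float), self.individual_ids(), self.marker_ids()
        )


def _marker_grid(length: float, md_morgan: float) -> np.ndarray:
    k = int(np.floor(length / md_morgan + 1e-9))
    if abs(k * md_morgan - length) > 1e-9:
        warnings.warn(
            f"marker spacing {md_morgan} M does not divide chromosome length "
            f"{length} M; last marker at {k * md_morgan:.6g} M",
            stacklevel=3,
        )
    return np.arange(k + 1) * md_morgan


def _chrom_loci(cfg: SimConfig) -> Tuple[List[np.ndarray], List[np.ndarray], List[str]]:
    positions, is_qtl, names = [], [], []
    md = cfg.marker_dist_cM / 100.0
    for c in range(cfg.n_chr):
        markers = _marker_grid(cfg.chr_length_morgan, md)
        qtl = np.asarray(sorted(cfg.qtl_positions_morgan), dtype=float)
        pos = np.concatenate([markers, qtl])
        flag = np.concatenate([np.zeros(markers.size, bool), np.ones(qtl.size, bool)])
        order = np.argsort(pos, kind="stable")
        positions.append(pos[order])
        is_qtl.append(flag[order])
        names.append(f"chr{c + 1}")
    return positions, is_qtl, names


def build_genome(cfg: SimConfig) -> Tuple[GeneticMap, pd.DataFrame]:
    """Marker map and QTL truth table for a simulation design."""
    positions, is_qtl, names = _chrom_loci(cfg)
    mids, chroms, mpos = [], [], []
    qrows = []
    for name, pos, q in zip(names, positions, is_qtl):
        mk = pos[~q]
        mids.extend(f"{name}_m{j}" for j in range(mk.size))
        chroms.extend([name] * mk.size)
        mpos.extend(mk)
        for k, qp in enumerate(pos[q]):
            qrows.append(
                {
                    "qtl_id": f"{name}_q{k}",
                    "chromosome": name,
                    "position_morgan": qp,
                    "effect_per_allele": cfg.qtl_allele_effect,
                }
            )
    return GeneticMap(mids, chroms, np.asarray(mpos)), pd.DataFrame(qrows)


def simulate_meiosis(
    hap_pair: np.ndarray, positions: np.ndarray, length_morgan: float, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a haplotype pair under the Haldane crossover model."""
    start = int(rng.integers(2))
    n_cx = int(rng.poisson(length_morgan)) if length_morgan > 0 else 0
    if n_cx == 0:
        return hap_pair[start].copy()
    cx = np.sort(rng.uniform(0.0, length_morgan, n_cx))
    strand = (start + np.searchsorted(cx, positions, side="right")) % 2
    return hap_pair[strand, np.arange(positions.size)]


def simulate_population(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Intermate an F1 for ``ngen`` generations and derive ``n_dh`` DH lines."""
    if cfg.n_intermate < 2:
        raise FormatError("intermating population needs at least 2 individuals")
    positions, is_qtl, names = _chrom_loci(cfg)
    L = cfg.chr_length_morgan
    n_int = cfg.n_intermate
    # the F1 is genetically uniform: one haplotype from each inbred parent
    pop = [
        np.broadcast_to(
            np.stack([np.ones(p.size, np.uint8), np.zeros(p.size, np.uint8)]),
            (n_int, 2, p.size),
        ).copy()
        for p in positions
    ]
    for _ in range(cfg.ngen):
        p1 = rng.integers(n_int, size=n_int)
        p2 = (p1 + 1 + rng.integers(n_int - 1, size=n_int)) % n_int  # no selfing
        nxt = [np.empty_like(h) for h in pop]
        for c, (pos, hap) in enumerate(zip(positions, pop)):
            out = nxt[c]
            for j in range(n_int):
                out[j, 0] = simulate_meiosis(hap[p1[j]], pos, L, rng)
                out[j, 1] = simulate_meiosis(hap[p2[j]], pos, L, rng)
        pop = nxt
    parents = rng.integers(n_int, size=cfg.n_dh)
    dh = [np.empty((cfg.n_dh, 2, p.size), np.uint8) for p in positions]
    for c, (pos, hap) in enumerate(zip(positions, pop)):
        out = dh[c]
        for i in range(cfg.n_dh):
            g = simulate_meiosis(hap[parents[i]], pos, L, rng)
            out[i, 0] = g
            out[i, 1] = g
    return Population(dh, positions, is_qtl, names)


def genotypic_values(pop: Population, cfg: SimConfig) -> np.ndarray:
    """True genotypic values: favorable-allele count at QTL times the per-allele effect."""
    counts = pop.qtl_allele_counts()
    if counts.shape[1] == 0:
        raise FormatError("population carries no QTL loci")
    return counts.sum(axis=1) * cfg.qtl_allele_effect


def calibrate_phenotypes(
    g: np.ndarray,
    h2: float,
    rng: np.random.Generator,
    individual_ids: Optional[list] = None,
) -> Tuple[PhenotypeVector, float]:
    """Add normal residuals with variance var(g) * (1/h2 - 1).

    The genotypic variance is the empirical (sample) variance of the
    realized g, so the heritability is calibrated per replicate.
    """
    g = np.asarray(g, dtype=float).ravel()
    if not (0 < h2 <= 1):
        raise FormatError("h2 must be in (0, 1]")
    var_g = g.var(ddof=1)
    if var_g <= 0:
        raise FormatError("constant genotypic values: heritability undefined")
    sigma_e2 = var_g * (1.0 / h2 - 1.0)
    y = g + (rng.normal(0.0, np.sqrt(sigma_e2), g.size) if sigma_e2 > 0 else 0.0)
    ids = individual_ids or [f"DH{i + 1:04d}" for i in range(g.size)]
    return PhenotypeVector(y, ids), sigma_e2


@dataclass
class SimulationStudy:
    """Per-marker mean effect profiles over replicates, plus the truth table."""

    effects: pd.DataFrame        # marker, chromosome, position_morgan, one column/method
    truth: pd.DataFrame          # QTL table from build_genome
    n_reps_done: int
    n_failed: dict


def run_simulation_study(
    cfg: SimConfig,
    methods: Sequence[str],
    fit_config: Optional[FitConfig] = None,
) -> SimulationStudy:
    """Replicate the simulate-phenotype-fit loop and average marker effects.

    Substreams per replicate are spawned deterministically from
    ``cfg.seed``, so a fixed config gives a fixed output table.  A failing
    fit skips that method/replicate with a warning and is counted.
    """
    gmap, truth = build_genome(cfg)
    fc = fit_config or FitConfig(hp2=cfg.h2)
    m = len(gmap)
    sums = {meth: np.zeros(m) for meth in methods}
    counts = {meth: 0 for meth in methods}
    n_failed = {meth: 0 for meth in methods}
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
    for rep in range(cfg.n_reps):
        rng = np.random.default_rng(children[rep])
        pop = simulate_population(cfg, rng)
        g = genotypic_values(pop, cfg)
        pheno, _ = calibrate_phenotypes(g, cfg.h2, rng, pop.individual_ids())
        Z = pop.to_genotype_matrix()
        for meth in methods:
            try:
                fit = fit_method(pheno, Z, meth, fc)
            except Exception as exc:  # record and continue
                n_failed[meth] += 1
                warnings.warn(f"{meth} failed in replicate {rep}: {exc}", stacklevel=2)
                continue
            sums[meth] += fit.u_hat
            counts[meth] += 1
    data = {
        "marker": gmap.marker_ids,
        "chromosome": gmap.chromosome,
        "position_morgan": gmap.position_morgan,
    }
    for meth in methods:
        data[meth] = sums[meth] / max(counts[meth], 1)
    return SimulationStudy(pd.DataFrame(data), truth, cfg.n_reps, n_failed)


def plot_effect_profile(study: SimulationStudy, method: str, chromosome=None, ax=None):
    """Mean estimated effects along the genome with QTL positions marked."""
    import matplotlib.pyplot as plt

    df = study.effects
    truth = study.truth
    if chromosome is not None:
        df = df[df["chromosome"] == chromosome]
        truth = truth[truth["chromosome"] == chromosome]
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(df["position_morgan"], df[method], s=8, label=method)
    ax.scatter(
        truth["position_morgan"],
        np.zeros(len(truth)),
        marker="D",
        facecolors="none",
        edgecolors="red",
        label="QTL",
    )
    ax.set_xlabel("position [M]")
    ax.set_ylabel("mean estimated effect")
    ax.legend()
    return ax
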