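"""Readers and writers for genotype, phenotype, map and effect tables.

All tables are plain delimited text (tab by default).  The genotype table
has a header row of marker ids and one row per individual (first column the
individual id, remaining cells dosages 0/1/2).  The phenotype table has two
columns (id, value).  The map table has three columns (marker, chromosome,
position) with positions in centiMorgan or Morgan; positions are stored in
Morgan internally.  A minimal VCF importer converts diploid GT fields of
biallelic records into alternate-allele dosages.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    ModelFit,
    PhenotypeVector,
)

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def read_genotype_table(path, delimiter: str = "\t", impute_missing: bool = False) -> GenotypeMatrix:
    """Read a delimited genotype dosage table.

    Missing cells are rejected unless ``impute_missing`` is set, in which
    case they are replaced by the per-marker mean of the observed dosages
    (fractional values; the matrix is flagged ``imputed``).
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty genotype table")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    raw_missing = df.isna().to_numpy() | (df == "").to_numpy()
    unparsable = np.isnan(values) & ~raw_missing
    if unparsable.any():
        r, c = np.argwhere(unparsable)[0]
        raise FormatError(
            f"{path}: non-numeric dosage at row '{df.index[r]}', column '{df.columns[c]}'"
        )
    missing = np.isnan(values)
    imputed = False
    if missing.any():
        if not impute_missing:
            r, c = np.argwhere(missing)[0]
            raise FormatError(
                f"{path}: missing dosage at row '{df.index[r]}', column '{df.columns[c]}'"
            )
        col_means = np.nanmean(values, axis=0)
        if np.isnan(col_means).any():
            c = int(np.flatnonzero(np.isnan(col_means))[0])
            raise FormatError(f"{path}: marker '{df.columns[c]}' has no observed dosages")
        values = np.where(missing, col_means[None, :], values)
        imputed = True
    observed = values[~missing] if imputed else values
    bad = ~np.isin(observed, (0.0, 1.0, 2.0))
    if bad.any():
        full_bad = ~np.isin(values, (0.0, 1.0, 2.0)) & ~missing
        r, c = np.argwhere(full_bad)[0]
        raise FormatError(
            f"{path}: dosage {df.iloc[r, c]} not in {{0,1,2}} at row "
            f"'{df.index[r]}', column '{df.columns[c]}'"
        )
    return GenotypeMatrix(values, list(df.index), list(df.columns), imputed=imputed)


def write_genotype_table(geno: GenotypeMatrix, path, delimiter: str = "\t") -> None:
    d = geno.dosages
    if not geno.imputed:
        d = d.astype(int)
    df = pd.DataFrame(d, index=geno.individual_ids, columns=geno.marker_ids)
    df.to_csv(path, sep=delimiter, index_label="id")


def read_phenotype_table(path, delimiter: str = "\t") -> PhenotypeVector:
    """Read a two-column (id, value) phenotype table. Missing values error."""
    df = pd.read_csv(path, sep=delimiter, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: phenotype table needs two columns (id, value)")
    ids = df.iloc[:, 0].astype(str).tolist()
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        r = int(np.flatnonzero(np.isnan(vals))[0])
        raise FormatError(f"{path}: non-numeric or missing phenotype for id '{ids[r]}'")
    return PhenotypeVector(vals, ids)


def write_phenotype_table(pheno: PhenotypeVector, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame({"id": pheno.individual_ids, "value": pheno.values})
    df.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def read_genetic_map(path, delimiter: str = "\t", unit: str = "cM") -> GeneticMap:
    """Read a (marker, chromosome, position) table; ``unit`` is 'cM' or 'M'."""
    if unit not in ("cM", "M"):
        raise FormatError(f"map unit must be 'cM' or 'M', got {unit!r}")
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: map table needs three columns (marker, chrom, pos)")
    pos = pd.to_numeric(df.iloc[:, 2], errors="coerce").to_numpy(dtype=float)
    if np.isnan(pos).any():
        raise FormatError(f"{path}: non-numeric map position")
    if unit == "cM":
        pos = pos / 100.0
    return GeneticMap(df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].tolist(), pos)


def write_genetic_map(gmap: GeneticMap, path, delimiter: str = "\t", unit: str = "cM") -> None:
    pos = gmap.position_morgan * (100.0 if unit == "cM" else 1.0)
    df = pd.DataFrame(
        {"marker": gmap.marker_ids, "chrom": gmap.chromosome, f"pos_{unit}": pos}
    )
    df.to_csv(path, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def read_vcf_dosage(path, strict: bool = True, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Import diploid GT fields of a VCF as alternate-allele dosages 0/1/2.

    Multiallelic records are skipped (or rejected when ``skip_multiallelic``
    is false); records with missing GT raise in strict mode and are skipped
    otherwise.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    reader = VCF(str(path))
    samples = list(reader.samples)
    marker_ids: list = []
    columns: list = []
    for var in reader:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise FormatError(f"{path}: multiallelic record at {var.CHROM}:{var.POS}")
        dosages = np.empty(len(samples))
        ok = True
        for k, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                if strict:
                    raise FormatError(
                        f"{path}: missing GT at {var.CHROM}:{var.POS} sample {samples[k]}"
                    )
                ok = False
                break
            dosages[k] = sum(1 for a in alleles if a != 0)
        if not ok:
            continue
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        columns.append(dosages)
    if not columns:
        raise FormatError(f"{path}: no usable biallelic records")
    return GenotypeMatrix(np.column_stack(columns), samples, marker_ids)


class EffectTable(NamedTuple):
    beta0: float
    method: str
    table: pd.DataFrame


def write_effect_table(
    fit: ModelFit, gmap: Optional[GeneticMap], path, delimiter: str = "\t"
) -> None:
    """Write marker effects, penalties and per-marker variances.

    The intercept and method label go into ``#``-prefixed header lines so a
    written fit can be reloaded for prediction.  Effects are printed with 17
    significant digits (exact float64 round trip).
    """
    m = fit.u_hat.size
    if fit.marker_ids is not None:
        markers = list(fit.marker_ids)
    elif gmap is not None:
        markers = list(gmap.marker_ids)
    else:
        markers = [f"m{i}" for i in range(m)]
    if len(markers) != m:
        raise FormatError("marker id count does not match number of effects")
    cols = {"marker": markers}
    if gmap is not None:
        order = {mk: i for i, mk in enumerate(gmap.marker_ids)}
        missing = [mk for mk in markers if mk not in order]
        if missing:
            raise FormatError(f"markers absent from map: {missing[:5]}")
        idx = [order[mk] for mk in markers]
        cols["chromosome"] = [gmap.chromosome[i] for i in idx]
        cols["position_morgan"] = gmap.position_morgan[idx]
    cols["effect"] = fit.u_hat
    cols["lambda"] = fit.lambdas.lambdas
    if fit.varcomp is not None and fit.varcomp.sigma_l2 is not None:
        cols["sigma_l2"] = fit.varcomp.sigma_l2
    elif fit.varcomp is not None and fit.varcomp.sigma_u2 is not None:
        cols["sigma_l2"] = np.full(m, fit.varcomp.sigma_u2)
    else:
        cols["sigma_l2"] = np.full(m, np.nan)
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# intercept{delimiter}{_FLOAT_FMT % fit.beta0}\n")
        fh.write(f"# method{delimiter}{fit.method}\n")
        df.to_csv(fh, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def read_effect_table(path, delimiter: str = "\t") -> EffectTable:
    beta0 = None
    method = "ridge"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition(delimiter)
            if key.strip() == "intercept":
                beta0 = float(val)
            elif key.strip() == "method":
                method = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep=delimiter, float_precision="round_trip")
    if beta0 is None:
        raise FormatError(f"{path}: effect table lacks '# intercept' header")
    return EffectTable(beta0, method, df)
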