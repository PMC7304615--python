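"""Readers for phenotype tables and genotype dosage data.

Phenotypes come from a delimited text table (CSV/TSV auto-detected) with
a header and a sample-ID column.  Genotypes come either from a delimited
dosage matrix (rows = samples, columns = variants, values in [0, 2],
``NA`` allowed) or from a VCF whose GT fields are converted to additive
ALT-allele dosages.  Samples are always aligned by ID downstream, never
by row order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["read_phenotypes", "read_genotypes", "variant_report"]

logger = logging.getLogger(__name__)


def read_phenotypes(
    path,
    trait_column: str,
    covariate_columns: list[str],
    id_column: str | None = None,
) -> pd.DataFrame:
    """Read a phenotype/covariate table and prepare the analysis columns.

    Returns a DataFrame indexed by sample ID with the trait column, an
    ``intercept`` column of ones, and the covariates; categorical
    covariates are one-hot encoded with the first level as reference.
    Samples with any missing trait or covariate value are dropped
    (complete-case).
    """
    table = pd.read_csv(path, sep=None, engine="python")
    if id_column is None:
        id_column = table.columns[0]
    missing = [c for c in [id_column, trait_column, *covariate_columns] if c not in table.columns]
    if missing:
        raise ValueError(f"columns not found in {path}: {missing}")
    if table[id_column].duplicated().any():
        dupes = table[id_column][table[id_column].duplicated()].tolist()
        raise ValueError(f"duplicate sample IDs: {dupes}")
    table = table.set_index(table[id_column].astype(str))

    sub = table[[trait_column, *covariate_columns]].copy()
    sub[trait_column] = pd.to_numeric(sub[trait_column], errors="coerce")
    if sub[trait_column].isna().all():
        raise ValueError(f"trait column {trait_column!r} has no numeric values")
    n_before = len(sub)
    sub = sub.dropna()
    if len(sub) < n_before:
        logger.info("dropped %d incomplete sample(s)", n_before - len(sub))

    covar = sub[covariate_columns]
    if covariate_columns:
        categorical = [
            c for c in covariate_columns if not pd.api.types.is_numeric_dtype(covar[c])
        ]
        encoded = pd.get_dummies(covar, columns=categorical, drop_first=True, dtype=float)
        encoded = encoded.astype(float)
    else:
        encoded = pd.DataFrame(index=sub.index)

    out = pd.concat(
        [sub[[trait_column]].astype(float), pd.Series(1.0, index=sub.index, name="intercept"), encoded],
        axis=1,
    )
    return out


def _read_vcf_dosages(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%d", variant.CHROM, variant.POS
            )
            continue
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        dosage = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                dosage[i] = np.nan
            else:
                dosage[i] = float(sum(1 for a in alleles if a > 0))
        ids.append(vid)
        columns.append(dosage)
    return pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((len(samples), 0)),
        index=pd.Index([str(s) for s in samples], name="sample_id"),
        columns=ids,
    )


def read_genotypes(path) -> pd.DataFrame:
    """Read a genotype dosage matrix (samples x variants).

    Delimited text (first column = sample ID) or a VCF (``.vcf`` suffix;
    GT fields converted to additive ALT dosage, missing GT -> NaN,
    multi-allelic sites skipped with a warning).  Dosages outside
    ``[0, 2]`` are rejected.
    """
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        dosages = _read_vcf_dosages(path)
    else:
        table = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
        table = table.set_index(table.columns[0])
        table.index = table.index.astype(str)
        dosages = table.astype(float)
    values = dosages.to_numpy()
    with np.errstate(invalid="ignore"):
        if np.nanmin(values, initial=0.0) < 0 or np.nanmax(values, initial=0.0) > 2:
            raise ValueError(f"dosages outside [0, 2] in {path}")
    for vid, frac in variant_report(dosages)["missing_fraction"].items():
        if frac > 0:
            logger.info("variant %s: %.1f%% missing dosages", vid, 100 * frac)
    return dosages


def variant_report(dosages: pd.DataFrame) -> pd.DataFrame:
    """Per-variant missingness and zero-variance flags."""
    missing = dosages.isna().mean()
    variance = dosages.var(ddof=0)
    return pd.DataFrame(
        {
            "missing_fraction": missing,
            "zero_variance": (variance.fillna(0.0) == 0.0),
        }
    )
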