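"""Reading and writing phenotype tables, genotype matrices and reports.

Phenotypes travel as delimited text with a fixed header (units encoded in
the column names: cm, mmHg, mg/dL); genotypes either as a CSV of
minor-allele dosages (id x snp_id, values 0/1/2/NA) or as a biallelic
VCF.  VCF input is read-only; dosages are re-oriented to count the minor
allele *within the loaded sample* unless a counted allele is declared,
and the orientation chosen per SNP is reported so dominance groupings
stay auditable.
"""

from __future__ import annotations

import csv
import io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .genetics import GenotypeMatrix
from .trait_prep import TRAITS

PHENOTYPE_COLUMNS = (
    "id", *TRAITS, "sex", "age_years",
    "smoker", "excess_alcohol", "inactive", "unhealthy_diet",
    "med_htn", "med_chol", "med_diab",
)
_BOOL_COLUMNS = PHENOTYPE_COLUMNS[10:]
_NA = ("", "NA", "NaN", "nan", "na", "None")


def _sniff_sep(path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV/TSV (delimiter sniffed) into a typed table.

    Missing values ('NA', empty, ...) become NaN and are kept; structurally
    invalid rows (non-positive traits, out-of-range age) raise
    :class:`SchemaError` naming the offending ids.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA, keep_default_na=True, dtype={"id": str},
                     float_precision="round_trip")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype file lacks column(s): {missing}")
    df = df.set_index("id")
    for col in TRAITS + ("age_years",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in _BOOL_COLUMNS:
        df[col] = (
            df[col].map(
                {True: True, False: False, "True": True, "False": False,
                 1: True, 0: False, "1": True, "0": False,
                 "true": True, "false": False}
            )
        )
    bad = []
    for trait in TRAITS:
        bad.extend(df.index[df[trait].notna() & (df[trait] <= 0)])
    bad.extend(df.index[df["age_years"].notna() & (df["age_years"] < 18)])
    if bad:
        raise SchemaError(f"invalid trait/age values for id(s): {sorted(set(bad))}")
    return df


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, index=False)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Dosage CSV: id column + one 0/1/2/NA column per SNP."""
    out = genotypes.dosages.copy()
    out.index.name = "id"
    out.to_csv(path, na_rep="NA")


def read_genotypes(path, format: str = "csv", sample_ids=None,
                   counted_alleles: dict[str, str] | None = None):
    """Load a genotype matrix from CSV or VCF.

    Returns (GenotypeMatrix, orientation notes).  With ``sample_ids``
    given, samples are aligned to that order; unmatched ids on either
    side raise :class:`SchemaError` with counts.
    """
    if format == "csv":
        gm, notes = _read_genotypes_csv(path)
    elif format == "vcf":
        gm, notes = _read_genotypes_vcf(path, counted_alleles)
    else:
        raise ParameterError(f"unknown genotype format {format!r}")
    if sample_ids is not None:
        sample_ids = pd.Index(sample_ids)
        missing = sample_ids.difference(gm.dosages.index)
        extra = gm.dosages.index.difference(sample_ids)
        if len(missing) or len(extra):
            raise SchemaError(
                f"id mismatch between phenotype and genotype files: "
                f"{len(missing)} phenotype id(s) without genotypes, "
                f"{len(extra)} genotype id(s) without phenotypes"
            )
        gm = GenotypeMatrix(dosages=gm.dosages.loc[sample_ids], snps=gm.snps)
    return gm, notes


def _read_genotypes_csv(path):
    df = pd.read_csv(path, na_values=_NA, dtype={"id": str}, float_precision="round_trip")
    if "id" not in df.columns:
        raise SchemaError("genotype CSV needs an 'id' column")
    df = df.set_index("id")
    snps = pd.DataFrame({"gene": ""}, index=pd.Index(df.columns, name="snp_id"))
    return GenotypeMatrix(dosages=df.astype(float), snps=snps), []


def _read_genotypes_vcf(path, counted_alleles=None):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    notes = []
    counted_alleles = counted_alleles or {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multiallelic record {variant.CHROM}:{variant.POS}",
                stacklevel=2,
            )
            continue
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        alt_dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        obs = alt_dosage[~np.isnan(alt_dosage)]
        alt_freq = obs.sum() / (2 * obs.size) if obs.size else np.nan
        counted = counted_alleles.get(snp_id)
        if counted is not None:
            if counted == variant.ALT[0]:
                dosage, minor = alt_dosage, variant.ALT[0]
            elif counted == variant.REF:
                dosage, minor = 2.0 - alt_dosage, variant.REF
            else:
                raise ParameterError(
                    f"{snp_id}: declared allele {counted!r} is neither "
                    f"REF {variant.REF!r} nor ALT {variant.ALT[0]!r}"
                )
        elif alt_freq <= 0.5 or np.isnan(alt_freq):
            dosage, minor = alt_dosage, variant.ALT[0]
        else:
            dosage, minor = 2.0 - alt_dosage, variant.REF
        notes.append(f"{snp_id}: counting allele {minor} (ALT freq {alt_freq:.4g})")
        cols[snp_id] = dosage
        meta_rows.append(
            {"snp_id": snp_id, "gene": "", "ref_allele": variant.REF,
             "alt_allele": variant.ALT[0], "counted_allele": minor}
        )
    dosages = pd.DataFrame(cols, index=pd.Index(samples, name="id"))
    snps = pd.DataFrame(meta_rows).set_index("snp_id") if meta_rows else pd.DataFrame(
        {"gene": []}, index=pd.Index([], name="snp_id")
    )
    return GenotypeMatrix(dosages=dosages, snps=snps), notes


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("mets_score").to_csv(path, sep="\t", index_label="id")


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, float_precision="round_trip").set_index("id")
    return df["mets_score"]


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="id")
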