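"""File formats: dosage matrices, pedigrees, phenotypes, GWAS summaries.

Canonical dialect is tab-delimited text with sample/variant ids in
headers, 6 significant digits for reals and ``NA`` for missing values.
A simulated cohort round-trips through three dosage matrices (one per
role), a FAM-like pedigree table and a phenotype table, plus a YAML
provenance record of the generating configuration.  Optional plain-text
VCF export/ingestion (GT or DS) is provided for interoperability.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SimConfig, TrioCohort

logger = logging.getLogger(__name__)

__all__ = ["read_dosage_matrix", "write_dosage_matrix", "read_pedigree",
           "write_pedigree", "read_phenotypes", "write_phenotypes",
           "read_gwas_summary", "write_cohort", "read_cohort",
           "read_sim_config", "write_sim_config", "export_vcf", "read_vcf",
           "write_provenance"]

NA = "NA"
FLOAT_FMT = "%.6g"

GWAS_DEFAULT_COLUMNS = {
    "variant_id": "variant_id", "chromosome": "chromosome",
    "position": "position", "effect_allele": "effect_allele",
    "other_allele": "other_allele", "weight": "beta", "se": "se",
    "p_value": "p_value", "effect_allele_freq": "effect_allele_freq",
}


def write_dosage_matrix(path, dosages: pd.DataFrame) -> None:
    """Samples in rows (first column ``sample_id``), variant ids as header."""
    df = dosages.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep=NA)


def read_dosage_matrix(path, allow_imputed: bool = False) -> pd.DataFrame:
    """Read a delimited dosage matrix and validate the entries.

    Hard-call mode (default) accepts only {0, 1, 2}; ``allow_imputed``
    accepts any real dosage in [0, 2].  Non-numeric cells are reported
    with their row/column coordinates; duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dup[:5]}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"non-numeric dosage at sample {row!r}, "
                             f"variant {col!r}")
        df[col] = numeric
    x = df.to_numpy(dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages outside [0, 2]")
    if not allow_imputed and finite.size and np.any(finite != np.round(finite)):
        raise ValueError("non-integer dosage found; pass allow_imputed=True "
                         "for imputed dosages")
    return df


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    pedigree[["family_id", "child_id", "father_id", "mother_id"]].to_csv(
        path, sep="\t", index=False, na_rep=NA)


def read_pedigree(path) -> pd.DataFrame:
    """Read a FAM-like trio table, dropping incomplete trios with a warning.

    Columns: family_id, child_id, father_id, mother_id.  A child listed in
    two families is an error; a missing parent id drops the row (only
    complete mother-father-child trios are analysable).
    """
    ped = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA])
    required = ["family_id", "child_id", "father_id", "mother_id"]
    missing = [c for c in required if c not in ped.columns]
    if missing:
        raise ValueError(f"pedigree missing columns {missing}")
    incomplete = ped[required].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"dropping {int(incomplete.sum())} incomplete trio(s)",
                      stacklevel=2)
        ped = ped[~incomplete]
    if ped["child_id"].duplicated().any():
        dup = ped.loc[ped["child_id"].duplicated(), "child_id"].tolist()
        raise ValueError(f"child id(s) in more than one family: {dup[:5]}")
    return ped.reset_index(drop=True)


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", float_format=FLOAT_FMT, na_rep=NA)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])


def read_gwas_summary(path, column_map: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Read GWAS summary statistics into the canonical panel layout.

    ``column_map`` maps canonical names (variant_id, chromosome, position,
    effect_allele, other_allele, weight, se, p_value, effect_allele_freq)
    to the file's column names; unmapped canonical names fall back to the
    defaults.  Missing optional columns are tolerated; variant_id, alleles
    and weight are required.
    """
    cmap = dict(GWAS_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", na_values=[NA])
    out = {}
    for canon, source in cmap.items():
        if source in raw.columns:
            out[canon] = raw[source]
    for req in ("variant_id", "effect_allele", "other_allele", "weight"):
        if req not in out:
            raise ValueError(f"GWAS summary lacks required column for "
                             f"{req!r} (looked for {cmap[req]!r})")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# cohort round-trip

def _join_validated(ids: pd.Series, table: pd.DataFrame, what: str) -> None:
    absent = [i for i in ids if i not in table.index]
    if absent:
        raise KeyError(f"{what} id(s) absent from table: {absent[:5]}")


def write_cohort(cohort: TrioCohort, directory) -> None:
    """Write a cohort as dosage matrices + pedigree + phenotypes + config."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fam = np.asarray(cohort.family_id, dtype=object)
    ids = {"mother": np.char.add(fam.astype(str), "_M"),
           "father": np.char.add(fam.astype(str), "_F"),
           "child": np.char.add(fam.astype(str), "_C")}
    for role, dos in (("mother", cohort.dosage_mother),
                      ("father", cohort.dosage_father),
                      ("child", cohort.dosage_child)):
        df = pd.DataFrame(dos, index=ids[role], columns=cohort.variant_ids)
        write_dosage_matrix(d / f"dosages_{role}.tsv", df)
    write_pedigree(d / "pedigree.tsv", pd.DataFrame(
        {"family_id": fam, "child_id": ids["child"],
         "father_id": ids["father"], "mother_id": ids["mother"]}))
    write_phenotypes(d / "phenotypes.tsv", cohort.phenotypes)
    if cohort.covariates is not None and np.size(cohort.covariates):
        cov = pd.DataFrame(cohort.covariates, index=cohort.phenotypes.index)
        cov.columns = [f"cov{j}" for j in range(cov.shape[1])]
        write_phenotypes(d / "covariates.tsv", cov)
    if cohort.config is not None:
        write_sim_config(d / "config.yaml", cohort.config)


def read_cohort(directory) -> TrioCohort:
    """Round-trip reader for :func:`write_cohort` output.

    Validates that every pedigree member exists in its dosage matrix and
    that phenotype rows join to the pedigree.
    """
    d = Path(directory)
    ped = read_pedigree(d / "pedigree.tsv")
    dosages = {role: read_dosage_matrix(d / f"dosages_{role}.tsv",
                                        allow_imputed=True)
               for role in ("mother", "father", "child")}
    phenotypes = read_phenotypes(d / "phenotypes.tsv")
    for role, idcol in (("mother", "mother_id"), ("father", "father_id"),
                        ("child", "child_id")):
        _join_validated(ped[idcol], dosages[role], role)
    _join_validated(ped["family_id"], phenotypes, "family")
    variant_ids = list(dosages["child"].columns)
    cfg_path = d / "config.yaml"
    config = read_sim_config(cfg_path) if cfg_path.exists() else None
    cov_path = d / "covariates.tsv"
    covariates = (read_phenotypes(cov_path).loc[ped["family_id"]].to_numpy(float)
                  if cov_path.exists() else None)
    return TrioCohort(
        family_id=ped["family_id"].to_numpy(),
        variant_ids=variant_ids,
        dosage_mother=dosages["mother"].loc[ped["mother_id"]].to_numpy(),
        dosage_father=dosages["father"].loc[ped["father_id"]].to_numpy(),
        dosage_child=dosages["child"].loc[ped["child_id"]].to_numpy(),
        phenotypes=phenotypes.loc[ped["family_id"]],
        covariates=covariates,
        config=config)


def write_sim_config(path, config: SimConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_sim_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(**data)


def write_provenance(directory, config_echo: dict, seed: int) -> None:
    """Drop a provenance record (config echo, package version, seed)."""
    from . import __version__
    record = {"triomr_version": __version__, "seed": seed,
              "config": config_echo}
    with open(Path(directory) / "provenance.yaml", "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# VCF interoperability

_VCF_HEADER = """##fileformat=VCFv4.2
##source=triomr
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def export_vcf(path, dosages: pd.DataFrame,
               chromosome: str = "1", positions=None) -> None:
    """Write hard-call dosages as a minimal single-chromosome VCF (GT)."""
    x = dosages.to_numpy()
    if np.any(x != np.round(x)):
        raise ValueError("VCF GT export needs hard calls in {0, 1, 2}")
    positions = (list(range(1, dosages.shape[1] + 1))
                 if positions is None else list(positions))
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, dosages.index)) + "\n")
        for j, vid in enumerate(dosages.columns):
            calls = "\t".join(gt[int(v)] for v in x[:, j])
            fh.write(f"{chromosome}\t{positions[j]}\t{vid}\tA\tG\t.\tPASS\t.\t"
                     f"GT\t{calls}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read GT (or DS) fields of a VCF into a sample x variant dosage frame.

    Multiallelic records are rejected.  Uses cyvcf2 when available, else a
    plain-text parser sufficient for the files :func:`export_vcf` writes.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = vcf.samples
    ids, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        if "DS" in (rec.FORMAT or []):
            cols.append(np.asarray(rec.format("DS"), float).ravel())
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            cols.append(gts.sum(axis=1).astype(float))
    return pd.DataFrame(np.column_stack(cols) if cols else
                        np.empty((len(samples), 0)),
                        index=samples, columns=ids)


def _read_vcf_text(path) -> pd.DataFrame:
    samples, ids, rows = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            if "," in parts[4]:
                raise ValueError(f"multiallelic record at {parts[0]}:{parts[1]}")
            ids.append(parts[2])
            fmt = parts[8].split(":")
            idx = fmt.index("DS") if "DS" in fmt else fmt.index("GT")
            vals = []
            for cell in parts[9:]:
                fieldval = cell.split(":")[idx]
                if fmt[idx] == "DS":
                    vals.append(float(fieldval))
                else:
                    alleles = fieldval.replace("|", "/").split("/")
                    vals.append(float(sum(int(a) for a in alleles)))
            rows.append(vals)
    return pd.DataFrame(np.array(rows).T if rows else np.empty((len(samples), 0)),
                        index=samples, columns=ids)
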