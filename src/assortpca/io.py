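"""Readers and writers for the formats the pipeline touches.

Dialects (strict; malformed records raise, skips are counted and logged):

* PLINK text PED/MAP.  The MAP may carry two extra allele columns
  (``chrom id cM pos allele1 allele2``); dosage counts ``allele2``.  With a
  plain 4-column MAP, alleles are inferred per SNP as the lexicographically
  sorted observed symbols and the second one is counted.  ``0 0`` is missing.
* FAM-style pedigree TSV with optional ``generation``, ``site``, ``subpop``
  metadata columns appended after the six standard fields.
* VCF 4.2, GT-only, biallelic sites (multi-allelic sites skipped with a
  warning).  Backed by cyvcf2.
* PC-score TSV: a ``#eigenvalues`` header line, then ``sample_id`` + one
  column per component.  Round-trips to 12 significant digits.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    PEDIGREE_COLUMNS,
    FormatError,
    GenotypeMatrix,
    PCResult,
    PedigreeTable,
)

logger = logging.getLogger(__name__)

_VALID_ALLELES = set("ACGT012")
_SEX_FROM_CODE = {"1": "male", "2": "female", "0": "unknown"}
_CODE_FROM_SEX = {"male": "1", "female": "2", "unknown": "0"}


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_path) -> pd.DataFrame:
    """Read a 4- or 6-column PLINK MAP file into the SNP-map frame."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 4:
                chrom, snp_id, _cm, pos = fields
                a1 = a2 = ""
            elif len(fields) == 6:
                chrom, snp_id, _cm, pos, a1, a2 = fields
            else:
                raise FormatError(f"{map_path}:{lineno}: expected 4 or 6 fields, got {len(fields)}")
            try:
                pos = int(pos)
            except ValueError:
                raise FormatError(f"{map_path}:{lineno}: non-integer position {pos!r}") from None
            rows.append((chrom, snp_id, pos, a1, a2))
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "pos", "allele1", "allele2"])
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"{map_path}: duplicate SNP id {dup!r}")
    return df


def read_ped_map(ped_path, map_path) -> tuple[GenotypeMatrix, PedigreeTable]:
    """Read PLINK text PED + MAP into a genotype matrix and pedigree table.

    Allele pairs collapse to the count of ``allele2``; when the MAP carries
    no allele columns the counted allele is the lexicographically second
    observed symbol at that SNP.  ``0 0`` becomes missing; a half-missing
    pair is a hard error.
    """
    snp_map = read_map(map_path)
    m = len(snp_map)
    ped_rows = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for {m} SNPs, got {len(fields)}")
            fid, iid, pat, mat, sex_code, pheno = fields[:6]
            if sex_code not in _SEX_FROM_CODE:
                raise FormatError(f"{ped_path}:{lineno}: invalid sex code {sex_code!r}")
            ped_rows.append((fid, iid, pat, mat, _SEX_FROM_CODE[sex_code], pheno))
            alleles = fields[6:]
            for a in alleles:
                if a not in _VALID_ALLELES:
                    raise FormatError(f"{ped_path}:{lineno}: invalid allele symbol {a!r}")
            allele_rows.append(alleles)
    if not ped_rows:
        raise FormatError(f"{ped_path}: no samples")
    iids = [r[1] for r in ped_rows]
    if len(set(iids)) != len(iids):
        dup = next(i for i in iids if iids.count(i) > 1)
        raise FormatError(f"{ped_path}: duplicate individual id {dup!r}")

    alleles = np.array(allele_rows, dtype=object).reshape(len(ped_rows), m, 2)
    counted = snp_map["allele2"].to_numpy(dtype=object).copy()
    other = snp_map["allele1"].to_numpy(dtype=object).copy()
    for j in range(m):
        observed = sorted({a for a in alleles[:, j, :].ravel() if a != "0"})
        if len(observed) > 2:
            raise FormatError(f"{ped_path}: SNP {snp_map['snp_id'][j]!r} has >2 alleles {observed}")
        if counted[j] == "":
            # infer: counted allele = lexicographically second observed
            if len(observed) == 2:
                other[j], counted[j] = observed
            elif len(observed) == 1:
                other[j] = counted[j] = observed[0]

    dosages = np.full((len(ped_rows), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        miss = (col[:, 0] == "0") | (col[:, 1] == "0")
        half = miss & ~((col[:, 0] == "0") & (col[:, 1] == "0"))
        if half.any():
            i = int(np.flatnonzero(half)[0])
            raise FormatError(
                f"{ped_path}: sample {iids[i]!r} SNP {snp_map['snp_id'][j]!r}: half-missing genotype")
        known = {counted[j], other[j], ""}
        stray = {a for a in col.ravel() if a != "0"} - known
        if stray:
            raise FormatError(
                f"{ped_path}: SNP {snp_map['snp_id'][j]!r}: allele {sorted(stray)} not in map "
                f"({other[j]!r}/{counted[j]!r})")
        dosages[:, j] = (col == counted[j]).sum(axis=1)
        dosages[miss, j] = MISSING
    snp_map = snp_map.assign(allele1=other, allele2=counted)

    ped = pd.DataFrame(ped_rows, columns=["family_id", "individual_id", "father_id",
                                          "mother_id", "sex", "phenotype"])
    genotypes = GenotypeMatrix(dosages=dosages, sample_ids=np.array(iids, dtype=object),
                               snp_map=snp_map)
    return genotypes, PedigreeTable(ped)


def write_ped_map(genotypes: GenotypeMatrix, pedigree: PedigreeTable,
                  ped_path, map_path) -> None:
    """Write PLINK text PED and a 6-column MAP (alleles recorded)."""
    sm = genotypes.snp_map
    with open(map_path, "w") as fh:
        for _, row in sm.iterrows():
            a1 = row["allele1"] or "A"
            a2 = row["allele2"] or "G"
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\t{a1}\t{a2}\n")
    ped = pedigree.df.set_index("individual_id")
    a1 = sm["allele1"].where(sm["allele1"] != "", "A").to_numpy(dtype=object)
    a2 = sm["allele2"].where(sm["allele2"] != "", "G").to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            row = ped.loc[sid]
            lead = [row["family_id"], sid, row["father_id"], row["mother_id"],
                    _CODE_FROM_SEX[row["sex"]], row["phenotype"]]
            g = genotypes.dosages[i]
            pairs = np.empty((len(g), 2), dtype=object)
            pairs[g == 0] = np.stack([a1, a1], axis=1)[g == 0]
            pairs[g == 1] = np.stack([a1, a2], axis=1)[g == 1]
            pairs[g == 2] = np.stack([a2, a2], axis=1)[g == 2]
            pairs[g == MISSING] = ("0", "0")
            fh.write("\t".join(lead + list(pairs.ravel())) + "\n")


# ---------------------------------------------------------------------------
# FAM-style pedigree TSV
# ---------------------------------------------------------------------------

_FAM_HEADER = ["family_id", "individual_id", "father_id", "mother_id", "sex",
               "phenotype", "generation", "site", "subpop"]


def write_fam(pedigree: PedigreeTable, path) -> None:
    """Write the pedigree as a headered TSV (sex as PLINK codes 1/2/0)."""
    df = pedigree.df.copy()
    df["sex"] = df["sex"].map(_CODE_FROM_SEX)
    df[_FAM_HEADER].to_csv(path, sep="\t", index=False)


def read_fam(path) -> PedigreeTable:
    """Read a FAM-style TSV; accepts headerless 6+ column files too."""
    with open(path) as fh:
        first = fh.readline().split()
    if first[:2] == ["family_id", "individual_id"]:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    else:
        if len(first) < 6:
            raise FormatError(f"{path}: expected >= 6 columns, got {len(first)}")
        names = _FAM_HEADER[:len(first)]
        df = pd.read_csv(path, sep=r"\s+", dtype=str, header=None,
                         names=names, keep_default_na=False)
    bad = ~df["sex"].isin(_SEX_FROM_CODE)
    if bad.any():
        raise FormatError(f"{path}: invalid sex code {df.loc[bad, 'sex'].iloc[0]!r}")
    df["sex"] = df["sex"].map(_SEX_FROM_CODE)
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# VCF (minimal, GT-only)
# ---------------------------------------------------------------------------

def read_vcf_minimal(vcf_path) -> GenotypeMatrix:
    """Read a biallelic, GT-only VCF into a genotype matrix.

    Multi-allelic sites are skipped with a warning and counted; phased and
    unphased separators are both accepted; any missing allele makes the
    call missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = np.array(vcf.samples, dtype=object)
    rows, map_rows = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt-allele count, 3 = missing
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        map_rows.append((v.CHROM, v.ID or f"{v.CHROM}:{v.POS}", v.POS, v.REF, v.ALT[0]))
    if n_skipped:
        warnings.warn(f"{vcf_path}: skipped {n_skipped} multi-allelic site(s)")
        logger.warning("read_vcf_minimal: skipped %d multi-allelic sites", n_skipped)
    if not rows:
        raise FormatError(f"{vcf_path}: no usable biallelic sites")
    dosages = np.stack(rows, axis=1)
    snp_map = pd.DataFrame(map_rows, columns=["chrom", "snp_id", "pos", "allele1", "allele2"])
    return GenotypeMatrix(dosages=dosages, sample_ids=samples, snp_map=snp_map)


# ---------------------------------------------------------------------------
# PC-score TSV
# ---------------------------------------------------------------------------

def write_scores(pc_result: PCResult, path) -> None:
    """Write scores with an eigenvalue header line (12 significant digits)."""
    k = pc_result.n_components_retained
    with open(path, "w") as fh:
        fh.write("#eigenvalues\t" + "\t".join(f"{v:.12g}" for v in pc_result.eigenvalues) + "\n")
        fh.write("sample_id\t" + "\t".join(f"PC{i}" for i in range(1, k + 1)) + "\n")
        for sid, row in zip(pc_result.sample_ids, pc_result.scores):
            fh.write(str(sid) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_scores(path) -> PCResult:
    """Read a PC-score TSV written by :func:`write_scores`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#eigenvalues":
            raise FormatError(f"{path}: missing #eigenvalues header")
        eigenvalues = np.array([float(v) for v in header[1:]])
        cols = fh.readline().rstrip("\n").split("\t")
        if len(cols) < 2 or cols[0] != "sample_id":
            raise FormatError(f"{path}: malformed column header (need sample_id + >=1 PC)")
        k = len(cols) - 1
        if len(eigenvalues) < k:
            raise FormatError(f"{path}: {len(eigenvalues)} eigenvalues for {k} score columns")
        ids, scores = [], []
        for lineno, line in enumerate(fh, 3):
            fields = line.rstrip("\n").split("\t")
            if fields == [""]:
                continue
            if len(fields) != k + 1:
                raise FormatError(f"{path}:{lineno}: expected {k + 1} fields, got {len(fields)}")
            ids.append(fields[0])
            scores.append([float(v) for v in fields[1:]])
    return PCResult(sample_ids=np.array(ids, dtype=object),
                    scores=np.array(scores, dtype=float),
                    eigenvalues=eigenvalues)


# ---------------------------------------------------------------------------
# VCF writing (optional convenience for the simulator's export)
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields only."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    sm = genotypes.snp_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(sm["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.sample_ids)) + "\n")
        for j, row in sm.iterrows():
            ref = row["allele1"] or "A"
            alt = row["allele2"] or "G"
            calls = "\t".join(gt[int(g)] for g in genotypes.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{ref}\t{alt}"
                     f"\t.\t.\t.\tGT\t{calls}\n")
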