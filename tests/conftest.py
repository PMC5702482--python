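import numpy as np
import pandas as pd
import pytest

from assortpca.types import GenotypeMatrix, PedigreeTable


def make_genotypes(dosages, sample_ids=None, chrom=None, pos=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix around a plain dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    snp_map = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["1"] * m,
        "snp_id": [f"snp{j}" for j in range(m)],
        "pos": pos if pos is not None else (np.arange(m) + 1) * 100,
        "allele1": "A",
        "allele2": "G",
    })
    return GenotypeMatrix(dosages=dosages, sample_ids=np.array(sample_ids, dtype=object),
                          snp_map=snp_map)


def make_pedigree(rows) -> PedigreeTable:
    """rows: (fid, iid, father, mother, sex[, generation, site, subpop])."""
    full = []
    for r in rows:
        r = list(r) + [""] * (8 - len(r))
        full.append((r[0], r[1], r[2], r[3], r[4], "-9", r[5], r[6], r[7]))
    return PedigreeTable(pd.DataFrame(full, columns=[
        "family_id", "individual_id", "father_id", "mother_id", "sex",
        "phenotype", "generation", "site", "subpop"]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
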