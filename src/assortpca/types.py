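"""Core containers shared across the pipeline.

Conventions
-----------
* Dosages are stored as ``int8`` counts of ``allele2`` (0, 1, 2) with the
  dedicated sentinel :data:`MISSING` (= -1) for no-calls.  Missing values
  never participate in arithmetic; callers mask explicitly.
* Positions are 1-based (PLINK/VCF convention).
* Sex is one of ``"male"``, ``"female"``, ``"unknown"`` in memory; file
  readers/writers translate the numeric PLINK codes.
* The pedigree missing-parent sentinel is the string ``"0"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: In-memory marker for a missing dosage.  Never used in arithmetic.
MISSING: int = -1

#: Missing-parent sentinel in pedigree records.
NO_PARENT: str = "0"

SEXES = ("male", "female", "unknown")

SNP_MAP_COLUMNS = ["chrom", "snp_id", "pos", "allele1", "allele2"]

PEDIGREE_COLUMNS = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "phenotype",
    "generation",
    "site",
    "subpop",
]


class FormatError(ValueError):
    """A malformed record in an input file (never silently coerced)."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with its SNP map and sample identifiers.

    Parameters
    ----------
    dosages
        ``(n_samples, n_snps)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    sample_ids
        Unique sample identifiers, one per row.
    snp_map
        Per-SNP metadata frame with columns
        ``chrom, snp_id, pos, allele1, allele2``; ``snp_id`` unique.
        Dosage counts ``allele2``.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_map) != m:
            raise ValueError(f"{len(self.snp_map)} map rows for {m} SNP columns")
        missing_cols = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise ValueError(f"snp_map lacks columns {missing_cols}")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if self.snp_map["snp_id"].duplicated().any():
            dups = self.snp_map.loc[self.snp_map["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate SNP ids: {sorted(set(dups))[:5]}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages outside {0,1,2,MISSING}")

    # -- conveniences -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the SNP columns in ``index`` (kept order)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            sample_ids=self.sample_ids.copy(),
            snp_map=self.snp_map.iloc[index].reset_index(drop=True),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            sample_ids=self.sample_ids[index],
            snp_map=self.snp_map.copy(),
        )


@dataclass
class PedigreeTable:
    """Per-individual pedigree records (one row per individual).

    The backing frame has the columns in :data:`PEDIGREE_COLUMNS`; optional
    metadata columns (generation, site, subpop) hold ``""`` when absent.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in PEDIGREE_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col != "phenotype" else "-9"
        df = df[PEDIGREE_COLUMNS].astype(str)
        if df.duplicated(subset=["family_id", "individual_id"]).any():
            raise ValueError("individual_id not unique within family")
        bad_sex = ~df["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValueError(f"invalid sex values: {sorted(df.loc[bad_sex, 'sex'].unique())}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def individual_ids(self) -> np.ndarray:
        return self.df["individual_id"].to_numpy(dtype=object)

    def sex_of(self) -> dict:
        return dict(zip(self.df["individual_id"], self.df["sex"]))


@dataclass
class PCResult:
    """Principal-component scores and eigenvalues.

    ``scores`` has one column per retained component (PC1..PCk);
    ``eigenvalues`` may be longer than ``k`` so that variance-explained
    summaries over a wider top-K window remain computable.
    """

    sample_ids: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if len(self.sample_ids) != self.scores.shape[0]:
            raise ValueError("sample_ids / scores row mismatch")
        if len(self.eigenvalues) < self.scores.shape[1]:
            raise ValueError("fewer eigenvalues than score columns")
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(1.0, abs(self.eigenvalues[0]))):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_components_retained(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i}" for i in range(1, self.n_components_retained + 1)]
        out = pd.DataFrame(self.scores, columns=cols)
        out.insert(0, "sample_id", self.sample_ids)
        return out

    def scores_for(self, ids) -> np.ndarray:
        """Score rows for the given ids, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[i] for i in ids]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} has no PC scores") from None
        return self.scores[idx, :]


@dataclass
class SpousePairSet:
    """Ordered (male, female) spouse pairs with stratum tags.

    Backed by a frame with columns ``male_id, female_id, generation,
    site_male, site_female, n_common_children``.  No individual appears in
    more than one pair.
    """

    df: pd.DataFrame

    COLUMNS = ["male_id", "female_id", "generation", "site_male", "site_female", "n_common_children"]

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = 0 if col == "n_common_children" else ""
        df = df[self.COLUMNS]
        members = list(df["male_id"]) + list(df["female_id"])
        if len(members) != len(set(members)):
            raise ValueError("an individual appears in more than one pair")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_pairs(self) -> int:
        return len(self.df)


@dataclass
class NullSummary:
    """Per-PC summary of the random-pairing null distribution."""

    pcs: list
    mean_r: np.ndarray
    quantile_low: np.ndarray
    quantile_high: np.ndarray
    n_replicates: int
    n_pairs_per_replicate: int
    seed: int
    replicate_r: np.ndarray = field(repr=False, default=None)  # (reps, pcs)

    def __post_init__(self) -> None:
        self.mean_r = np.asarray(self.mean_r, dtype=float)
        self.quantile_low = np.asarray(self.quantile_low, dtype=float)
        self.quantile_high = np.asarray(self.quantile_high, dtype=float)
        if not (len(self.pcs) == len(self.mean_r) == len(self.quantile_low) == len(self.quantile_high)):
            raise ValueError("per-PC summary arrays must align with pcs")
        if np.any(self.quantile_low > self.quantile_high + 1e-12):
            raise ValueError("quantile_low above quantile_high")
        for arr in (self.quantile_low, self.quantile_high):
            if np.any(np.abs(arr) > 1.0 + 1e-12):
                raise ValueError("quantiles outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pc": self.pcs,
                "mean_r": self.mean_r,
                "quantile_low": self.quantile_low,
                "quantile_high": self.quantile_high,
                "n_replicates": self.n_replicates,
                "n_pairs_per_replicate": self.n_pairs_per_replicate,
            }
        )
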