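"""SNP selection: call-rate and MAF filters, then windowed LD pruning.

Both filters use strict ``>`` at the boundary, so a SNP sitting exactly at
the threshold is removed.  Pruning is the greedy PLINK-style scheme: within
each window of ``prune_window`` SNPs, remove the later SNP of every kept
pair with dosage r-squared above ``max_r2``, then slide the window start by
``prune_step`` positions in map order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCParams:
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    prune_window: int = 50
    prune_step: int = 5
    max_r2: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.min_call_rate < 1.0:
            raise ValueError("min_call_rate must be in (0, 1)")
        if not 0.0 < self.min_maf < 1.0:
            raise ValueError("min_maf must be in (0, 1)")
        if not self.prune_window >= self.prune_step >= 1:
            raise ValueError("need prune_window >= prune_step >= 1")
        if not 0.0 < self.max_r2 < 1.0:
            raise ValueError("max_r2 must be in (0, 1)")


def call_rate(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-SNP fraction of samples with a non-missing call."""
    return (genotypes.dosages != MISSING).mean(axis=0)


def call_rate_filter(genotypes: GenotypeMatrix, min_call_rate: float = 0.95) -> np.ndarray:
    """Indices of SNPs with call rate strictly above the threshold."""
    kept = np.flatnonzero(call_rate(genotypes) > min_call_rate)
    logger.info("call_rate_filter: kept %d / %d SNPs (> %.3g)",
                len(kept), genotypes.n_snps, min_call_rate)
    return kept


def minor_allele_freq(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-SNP MAF over non-missing dosages; NaN if all entries missing."""
    d = genotypes.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0)
    total = np.where(observed, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, total / (2.0 * n_obs), np.nan)
    return np.minimum(p, 1.0 - p)


def maf_filter(genotypes: GenotypeMatrix, min_maf: float = 0.05) -> np.ndarray:
    """Indices of SNPs with MAF strictly above the threshold.

    SNPs with no observed calls count as removed (logged).
    """
    maf = minor_allele_freq(genotypes)
    n_blank = int(np.isnan(maf).sum())
    if n_blank:
        logger.info("maf_filter: %d SNP(s) with zero observed calls removed", n_blank)
    with np.errstate(invalid="ignore"):
        kept = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) > min_maf)
    logger.info("maf_filter: kept %d / %d SNPs (> %.3g)", len(kept), genotypes.n_snps, min_maf)
    return kept


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over samples non-missing in both; returns NaN if the overlap
    has fewer than two samples or either vector is constant on it.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    xs -= xs.mean()
    ys -= ys.mean()
    denom = np.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0.0:
        return float("nan")
    r = (xs @ ys) / denom
    return float(min(r * r, 1.0))


def _window_r2(block: np.ndarray) -> np.ndarray:
    """Pairwise r^2 among the SNP columns of ``block`` (pairwise-complete)."""
    obs = (block != MISSING).astype(float)
    vals = np.where(block != MISSING, block, 0).astype(float)
    n = obs.T @ obs                      # pairwise overlap counts
    s = vals.T @ obs                     # sum of x over joint-observed samples
    sx = s
    sy = s.T
    sxy = vals.T @ vals
    sxx = (vals * vals).T @ obs
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = (cov * cov) / (vx * vy)
    r2[~np.isfinite(r2)] = np.nan
    r2[n < 2] = np.nan
    return r2


def ld_prune(genotypes: GenotypeMatrix, params: QCParams = QCParams()) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept SNP indices in map order.

    SNPs must already be ordered by (chromosome, position).  Undefined
    r-squared (constant SNP or tiny overlap) never causes a removal.
    Chromosomes are pruned independently.
    """
    m = genotypes.n_snps
    keep = np.ones(m, dtype=bool)
    chroms = genotypes.snp_map["chrom"].to_numpy()
    n_undefined = 0
    for chrom in dict.fromkeys(chroms):           # preserve order
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            window = idx[start:start + params.prune_window]
            live = window[keep[window]]
            if len(live) > 1:
                r2 = _window_r2(genotypes.dosages[:, live])
                n_undefined += int(np.isnan(r2[np.triu_indices(len(live), 1)]).sum())
                local = np.ones(len(live), dtype=bool)
                for a in range(len(live)):
                    if not local[a]:
                        continue
                    for b in range(a + 1, len(live)):
                        if local[b] and r2[a, b] > params.max_r2:
                            local[b] = False     # drop the later SNP
                keep[live[~local]] = False
            if start + params.prune_window >= len(idx):
                break
            start += params.prune_step
    if n_undefined:
        logger.info("ld_prune: %d undefined r2 pair(s) treated as 0", n_undefined)
    kept = np.flatnonzero(keep)
    logger.info("ld_prune: kept %d / %d SNPs (window=%d step=%d r2>%.3g)",
                len(kept), m, params.prune_window, params.prune_step, params.max_r2)
    return kept


def run_qc(genotypes: GenotypeMatrix, params: QCParams = QCParams()) -> tuple[GenotypeMatrix, dict]:
    """Full QC pipeline: call rate -> MAF -> LD prune.

    Returns the filtered matrix and a report dict of per-stage in/out counts
    with the kept SNP ids.
    """
    report = {"n_input": genotypes.n_snps}
    kept_cr = call_rate_filter(genotypes, params.min_call_rate)
    g1 = genotypes.take_snps(kept_cr)
    report["n_after_call_rate"] = g1.n_snps
    kept_maf = maf_filter(g1, params.min_maf)
    g2 = g1.take_snps(kept_maf)
    report["n_after_maf"] = g2.n_snps
    kept_ld = ld_prune(g2, params)
    g3 = g2.take_snps(kept_ld)
    report["n_after_prune"] = g3.n_snps
    report["kept_snp_ids"] = list(g3.snp_map["snp_id"])
    return g3, report
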