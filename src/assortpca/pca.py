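"""Genome-wide PCA with Patterson normalization (smartpca-core behaviour).

The normalized matrix X (samples x SNPs) has entries
``(g - 2 p_j) / sqrt(p_j (1 - p_j))`` with ``p_j`` the observed mean dosage
over 2, and missing entries imputed as 0 after centering.  Scores and
eigenvalues come from the sample-sample covariance ``X X^T / n_snps``.
No iterative outlier removal is performed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.linalg

from .types import MISSING, GenotypeMatrix, PCResult

logger = logging.getLogger(__name__)


def informative_snps(genotypes: GenotypeMatrix) -> np.ndarray:
    """Indices of SNPs that are neither monomorphic nor all-missing."""
    d = genotypes.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0)
    total = np.where(observed, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = total / (2.0 * n_obs)
    ok = (n_obs > 0) & (p > 0.0) & (p < 1.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("informative_snps: dropping %d monomorphic/all-missing SNP(s)", n_dropped)
    return np.flatnonzero(ok)


def patterson_normalize(genotypes: GenotypeMatrix) -> np.ndarray:
    """Center by 2p and scale by sqrt(p(1-p)); missing entries become 0.

    Requires monomorphic and all-missing SNPs to be dropped first (see
    :func:`informative_snps`); finding one here is a logic error.
    """
    d = genotypes.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0)
    total = np.where(observed, d, 0).sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError("all-missing SNP present; drop uninformative SNPs first")
    p = total / (2.0 * n_obs)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("monomorphic SNP present; drop uninformative SNPs first")
    scale = np.sqrt(p * (1.0 - p))
    x = (d.astype(float) - 2.0 * p) / scale
    x[~observed] = 0.0
    return x


def run_pca(x: np.ndarray, k: int = 8, n_eigenvalues: int = 30,
            sample_ids=None) -> PCResult:
    """Top-k PCA of the sample-sample covariance ``x x^T / n_snps``.

    ``scores`` are the principal-component projections (eigenvector times
    singular value); deterministic up to column sign.  Up to
    ``max(k, n_eigenvalues)`` leading eigenvalues are retained so wider
    variance summaries stay available.  ``k`` beyond the matrix rank is
    truncated with a warning.
    """
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    max_rank = min(n - 1, m)
    if k > max_rank:
        warnings.warn(f"k={k} exceeds usable rank {max_rank}; truncating")
        k = max_rank
    if m < k:
        raise ValueError("fewer SNPs than requested components")
    n_eig = min(max(k, n_eigenvalues), max_rank)

    cov = (x @ x.T) / m
    evals, evecs = scipy.linalg.eigh(cov, subset_by_index=[n - n_eig, n - 1])
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # projection scale: singular value = sqrt(eigenvalue * n_snps)
    scores = evecs[:, :k] * np.sqrt(evals[:k] * m)
    if sample_ids is None:
        sample_ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    return PCResult(sample_ids=sample_ids, scores=scores, eigenvalues=evals)


def pca_from_genotypes(genotypes: GenotypeMatrix, k: int = 8,
                       n_eigenvalues: int = 30) -> PCResult:
    """Drop uninformative SNPs, normalize, and run PCA in one call."""
    g = genotypes.take_snps(informative_snps(genotypes))
    x = patterson_normalize(g)
    return run_pca(x, k=k, n_eigenvalues=n_eigenvalues, sample_ids=g.sample_ids)


def variance_explained_topk(eigenvalues: np.ndarray, k: int, top: int = 30) -> float:
    """Fraction of the top-``top`` eigenvalue mass captured by the first ``k``."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if top < k:
        raise ValueError("top must be >= k")
    if len(eigenvalues) < top:
        warnings.warn(f"only {len(eigenvalues)} eigenvalues available for top={top}; using all")
        top = len(eigenvalues)
        k = min(k, top)
    denom = eigenvalues[:top].sum()
    if denom <= 0.0:
        raise ValueError("non-positive eigenvalue sum")
    return float(eigenvalues[:k].sum() / denom)


def orient_signs(pc_result: PCResult, anchor_ids, conventions: dict) -> PCResult:
    """Flip PC signs so an anchor group's mean score meets stated conventions.

    ``conventions`` maps 1-based PC index to ``"negative"`` or ``"positive"``.
    An anchor mean of exactly zero triggers a warning and no flip.
    """
    anchor_ids = list(anchor_ids)
    if not anchor_ids:
        raise ValueError("anchor group is empty")
    anchor = pc_result.scores_for(anchor_ids)
    scores = pc_result.scores.copy()
    for pc, wanted in conventions.items():
        if wanted not in ("negative", "positive"):
            raise ValueError(f"convention for PC{pc} must be 'negative' or 'positive'")
        j = pc - 1
        if j >= scores.shape[1]:
            raise ValueError(f"PC{pc} not present (k={scores.shape[1]})")
        mean = anchor[:, j].mean()
        if mean == 0.0:
            warnings.warn(f"anchor mean on PC{pc} is exactly 0; no flip applied")
            continue
        flip = (mean > 0.0) if wanted == "negative" else (mean < 0.0)
        if flip:
            scores[:, j] = -scores[:, j]
            logger.info("orient_signs: flipped PC%d", pc)
    return PCResult(sample_ids=pc_result.sample_ids, scores=scores,
                    eigenvalues=pc_result.eigenvalues)


def scree_table(eigenvalues: np.ndarray) -> pd.DataFrame:
    """(component, eigenvalue, cumulative fraction) rows for scree plotting."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    total = eigenvalues.sum()
    cum = np.cumsum(eigenvalues) / total
    return pd.DataFrame({
        "component": np.arange(1, len(eigenvalues) + 1),
        "eigenvalue": eigenvalues,
        "cumulative_fraction": cum,
    })
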