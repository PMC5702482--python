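"""Per-PC spouse correlations with Fisher-z confidence intervals and
t-distribution p-values.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import PCResult, SpousePairSet

logger = logging.getLogger(__name__)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation.

    Raises on length mismatch or n < 3; returns NaN (with a log line) when
    either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0.0:
        logger.warning("pearson_r undefined: constant input")
        return float("nan")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a correlation.

    ``z = atanh(r)`` is treated as normal with standard error
    ``1/sqrt(n-3)``; endpoints are ``tanh(z -/+ q/sqrt(n-3))`` with ``q``
    the two-sided normal quantile for ``level``.
    """
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher CI")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if abs(r) >= 1.0:
        if abs(r) > 1.0:
            raise ValueError("|r| > 1")
        import warnings
        warnings.warn("|r| = 1: degenerate confidence interval")
        return (r, r)
    z = math.atanh(r)
    half = sps.norm.ppf(1.0 - (1.0 - level) / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value from ``t = r sqrt(n-2) / sqrt(1-r^2)``, df = n-2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        if abs(r) > 1.0:
            raise ValueError("|r| > 1")
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def correlation_row(x: np.ndarray, y: np.ndarray, level: float = 0.95) -> dict:
    """n, r, CI and p-value for one paired score vector; NaNs when n < 4."""
    n = len(x)
    r = pearson_r(x, y) if n >= 3 else float("nan")
    if n >= 4 and np.isfinite(r) and abs(r) < 1.0:
        lo, hi = fisher_ci(r, n, level)
        p = correlation_pvalue(r, n)
    elif np.isfinite(r) and abs(r) == 1.0:
        lo = hi = r
        p = 0.0
    else:
        lo = hi = p = float("nan")
    return {"n_pairs": n, "r": r, "ci_low": lo, "ci_high": hi, "p_value": p}


def spouse_pc_table(strata: dict, scores: PCResult, pcs=None,
                    level: float = 0.95) -> pd.DataFrame:
    """Correlation table over strata x PCs.

    ``strata`` maps stratum name to a :class:`SpousePairSet`; ``pcs`` is a
    1-based index set, default PC1..PC6 (capped at the retained components).
    Male scores form the x vector by convention.  Strata with fewer than 4
    pairs still get a row, with undefined CI/p and a flag.
    """
    if pcs is None:
        pcs = list(range(1, min(6, scores.n_components_retained) + 1))
    rows = []
    for name, pair_set in strata.items():
        df = pair_set.df if isinstance(pair_set, SpousePairSet) else pair_set
        mx = scores.scores_for(list(df["male_id"]))
        fy = scores.scores_for(list(df["female_id"]))
        for pc in pcs:
            if pc > scores.n_components_retained:
                raise ValueError(f"PC{pc} not in the score table")
            if len(df) >= 3:
                row = correlation_row(mx[:, pc - 1], fy[:, pc - 1], level)
            else:
                row = {"n_pairs": len(df), "r": float("nan"), "ci_low": float("nan"),
                       "ci_high": float("nan"), "p_value": float("nan")}
            rows.append({"stratum": name, "pc": pc, **row,
                         "flag": "" if len(df) >= 4 else "too_few_pairs"})
    return pd.DataFrame(rows)
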