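"""Random within-ethnicity pairing null for spouse PC correlations.

Each replicate independently shuffles the male and female members of every
ethnicity group, matches them positionally, pools all groups' pairs, and
records per-PC Pearson correlations.  The replicate distribution is
summarized by its mean and the empirical 2.5/97.5 percentiles (linear
interpolation between order statistics).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import pearson_r
from .types import NullSummary, PCResult, SpousePairSet

logger = logging.getLogger(__name__)


def _group_pools(candidates: pd.DataFrame) -> dict:
    """Per-ethnicity (male ids, female ids) pools; unknown sex excluded."""
    n_unknown = int((~candidates["sex"].isin(["male", "female"])).sum())
    if n_unknown:
        logger.info("random_pairing: excluding %d candidate(s) of unknown sex", n_unknown)
    pools = {}
    for label, grp in candidates.groupby("ethnicity", sort=True):
        males = grp.loc[grp["sex"] == "male", "individual_id"].to_numpy(dtype=object)
        females = grp.loc[grp["sex"] == "female", "individual_id"].to_numpy(dtype=object)
        if len(males) == 0 or len(females) == 0:
            logger.warning("random_pairing: group %r has a single sex; contributes no pairs", label)
            continue
        pools[label] = (males, females)
    return pools


def random_pairing(candidates: pd.DataFrame, rng: np.random.Generator) -> SpousePairSet:
    """One random heterosexual within-group matching.

    ``candidates`` needs columns ``individual_id, sex, ethnicity``.  Within
    each group the males and females are shuffled independently and matched
    positionally; ``min(n_male, n_female)`` pairs per group, leftovers
    dropped (logged).
    """
    pools = _group_pools(candidates)
    rows = []
    for label in sorted(pools):
        males, females = pools[label]
        males = males[rng.permutation(len(males))]
        females = females[rng.permutation(len(females))]
        n = min(len(males), len(females))
        for i in range(n):
            rows.append((males[i], females[i], label))
    df = pd.DataFrame(rows, columns=["male_id", "female_id", "generation"])
    return SpousePairSet(df)


def null_distribution(candidates: pd.DataFrame, scores: PCResult, pcs=None,
                      n_replicates: int = 1000, seed: int = 0) -> NullSummary:
    """Replicate random pairings and summarize per-PC correlations.

    Aborts with a configuration error if any replicate pools fewer than 4
    pairs.  Fully reproducible from ``seed``.
    """
    if pcs is None:
        pcs = list(range(1, min(6, scores.n_components_retained) + 1))
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    pools = _group_pools(candidates)
    if not pools:
        raise ValueError("no ethnicity group with both sexes; null is not computable")
    n_pairs = sum(min(len(m), len(f)) for m, f in pools.values())
    if n_pairs < 4:
        raise ValueError(f"only {n_pairs} pooled pairs per replicate; need >= 4")

    pos = {s: i for i, s in enumerate(scores.sample_ids)}
    # pre-resolve score row indices per group for speed
    indexed = {}
    for label, (males, females) in pools.items():
        try:
            im = np.array([pos[i] for i in males])
            if_ = np.array([pos[i] for i in females])
        except KeyError as exc:
            raise KeyError(f"candidate {exc.args[0]!r} has no PC scores") from None
        indexed[label] = (im, if_)

    cols = np.array(pcs) - 1
    sc = scores.scores[:, cols]
    rng = np.random.default_rng(seed)
    rep_r = np.empty((n_replicates, len(pcs)))
    for b in range(n_replicates):
        xs, ys = [], []
        for label in sorted(indexed):
            im, if_ = indexed[label]
            pm = im[rng.permutation(len(im))]
            pf = if_[rng.permutation(len(if_))]
            n = min(len(pm), len(pf))
            xs.append(sc[pm[:n]])
            ys.append(sc[pf[:n]])
        x = np.vstack(xs)
        y = np.vstack(ys)
        for j in range(len(pcs)):
            rep_r[b, j] = pearson_r(x[:, j], y[:, j])

    return NullSummary(
        pcs=list(pcs),
        mean_r=rep_r.mean(axis=0),
        quantile_low=np.percentile(rep_r, 2.5, axis=0),
        quantile_high=np.percentile(rep_r, 97.5, axis=0),
        n_replicates=n_replicates,
        n_pairs_per_replicate=n_pairs,
        seed=seed,
        replicate_r=rep_r,
    )


def compare_observed_to_null(observed: pd.DataFrame, null: NullSummary) -> pd.DataFrame:
    """Per-PC observed-vs-null verdicts.

    ``observed`` is a correlation table (one stratum) with columns
    ``pc`` and ``r``.  Adds the null mean/interval, an ``exceeds_null`` flag
    (observed r above the 97.5th percentile) and the empirical exceedance
    proportion (fraction of replicates >= observed).
    """
    obs = observed.set_index("pc")["r"]
    rows = []
    for j, pc in enumerate(null.pcs):
        if pc not in obs.index:
            raise ValueError(f"PC{pc} present in the null but not in the observed table")
        r_obs = float(obs.loc[pc])
        exceed_prop = float(np.mean(null.replicate_r[:, j] >= r_obs)) \
            if null.replicate_r is not None else float("nan")
        rows.append({
            "pc": pc,
            "observed_r": r_obs,
            "null_mean_r": float(null.mean_r[j]),
            "null_quantile_low": float(null.quantile_low[j]),
            "null_quantile_high": float(null.quantile_high[j]),
            "exceeds_null": bool(r_obs > null.quantile_high[j]),
            "exceedance_proportion": exceed_prop,
        })
    extra = set(obs.index) - set(null.pcs)
    if extra:
        raise ValueError(f"PCs {sorted(extra)} present in the observed table but not in the null")
    return pd.DataFrame(rows)
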