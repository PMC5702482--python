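"""Spouse-pair identification from pedigrees and PC-quadrant labelling.

A spouse pair is a (father, mother) couple named by at least one in-common
child; both members must be genotyped and carry consistent sexes.  When an
individual parents children with several partners, the pair with the most
in-common children wins (ties broken by lexicographically smaller partner
id) so no individual ever appears in two pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import NO_PARENT, PCResult, PedigreeTable, SpousePairSet

logger = logging.getLogger(__name__)


def find_spouse_pairs(pedigree: PedigreeTable, genotyped_ids) -> tuple[SpousePairSet, dict]:
    """Extract spouse pairs named by in-common children.

    Returns the pair set plus a report dict counting each exclusion reason.
    The result is a pure function of the pedigree contents: input row order
    never matters.
    """
    genotyped = set(genotyped_ids)
    df = pedigree.df
    info = df.set_index("individual_id")[["sex", "generation", "site"]]
    sex_of = info["sex"].to_dict()
    report = {
        "n_children_seen": 0,
        "n_missing_parent_field": 0,
        "n_parent_not_in_pedigree": 0,
        "n_sex_inconsistent": 0,
        "n_pairs_candidate": 0,
        "n_pair_not_genotyped": 0,
        "n_remarriage_conflicts": 0,
    }

    counts: dict = {}
    for father, mother in zip(df["father_id"], df["mother_id"]):
        if father == NO_PARENT and mother == NO_PARENT:
            continue
        report["n_children_seen"] += 1
        if father == NO_PARENT or mother == NO_PARENT:
            report["n_missing_parent_field"] += 1
            continue
        if father not in sex_of or mother not in sex_of:
            report["n_parent_not_in_pedigree"] += 1
            continue
        if sex_of[father] == "female" or sex_of[mother] == "male":
            report["n_sex_inconsistent"] += 1
            logger.warning("rejecting child record: father %r sex=%s, mother %r sex=%s",
                           father, sex_of[father], mother, sex_of[mother])
            continue
        counts[(father, mother)] = counts.get((father, mother), 0) + 1

    report["n_pairs_candidate"] = len(counts)
    candidates = []
    for (father, mother), n in counts.items():
        if father not in genotyped or mother not in genotyped:
            report["n_pair_not_genotyped"] += 1
            continue
        candidates.append((father, mother, n))
    # deterministic remarriage resolution: most children first, then ids
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    used: set = set()
    rows = []
    for father, mother, n in candidates:
        if father in used or mother in used:
            report["n_remarriage_conflicts"] += 1
            logger.warning("remarriage conflict: dropping pair (%r, %r)", father, mother)
            continue
        used.update((father, mother))
        gen_f = info.at[father, "generation"]
        gen_m = info.at[mother, "generation"]
        if gen_f != gen_m and gen_m:
            logger.warning("pair (%r, %r): generation mismatch %r vs %r; using father's",
                           father, mother, gen_f, gen_m)
        rows.append((father, mother, gen_f, info.at[father, "site"],
                     info.at[mother, "site"], n))
    rows.sort(key=lambda t: (t[0], t[1]))
    pair_set = SpousePairSet(pd.DataFrame(rows, columns=SpousePairSet.COLUMNS))
    logger.info("find_spouse_pairs: %d pairs (%s)", len(pair_set), report)
    return pair_set, report


def restrict_to_scores(pairs: SpousePairSet, scores: PCResult) -> SpousePairSet:
    """Keep only pairs where both members have PC scores."""
    have = set(scores.sample_ids)
    df = pairs.df
    ok = df["male_id"].isin(have) & df["female_id"].isin(have)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("restrict_to_scores: dropped %d pair(s) lacking scores", n_dropped)
    return SpousePairSet(df[ok])


def assign_quadrant_labels(pc_result: PCResult) -> pd.Series:
    """PC1/PC2 quadrant ethnicity labels.

    ``East`` iff PC1 < 0 and PC2 < 0; ``North`` iff PC1 > 0 and PC2 < 0;
    everything else (including a score of exactly 0 on a deciding PC) is
    ``unassigned``.  Scores must already be sign-oriented.
    """
    if pc_result.n_components_retained < 2:
        raise ValueError("need at least 2 PCs for quadrant labels")
    pc1 = pc_result.scores[:, 0]
    pc2 = pc_result.scores[:, 1]
    labels = np.full(len(pc1), "unassigned", dtype=object)
    labels[(pc1 < 0) & (pc2 < 0)] = "East"
    labels[(pc1 > 0) & (pc2 < 0)] = "North"
    n_zero = int(((pc1 == 0) | (pc2 == 0)).sum())
    if n_zero:
        logger.info("assign_quadrant_labels: %d sample(s) with an exact 0 score left unassigned",
                    n_zero)
    return pd.Series(labels, index=pc_result.sample_ids, name="ethnicity")


def stratify_pairs(pairs: SpousePairSet, by: str = "generation") -> dict:
    """Split pairs into disjoint subsets by a stratum tag.

    ``by`` is ``"generation"`` or ``"site"`` (site uses the shared site when
    both members agree, else ``"mixed"``).  Unknown/empty values land in an
    ``"unknown"`` bucket with a warning.
    """
    df = pairs.df
    if by == "generation":
        key = df["generation"].to_numpy(dtype=object)
    elif by == "site":
        key = np.where(df["site_male"] == df["site_female"],
                       df["site_male"], "mixed").astype(object)
    else:
        raise ValueError(f"unknown stratification {by!r}")
    key = np.where(pd.Series(key).isin(["", "nan"]), "unknown", key)
    if (key == "unknown").any():
        logger.warning("stratify_pairs: %d pair(s) with unknown %s", int((key == "unknown").sum()), by)
    out = {}
    for value in dict.fromkeys(key):
        out[str(value)] = SpousePairSet(df[key == value])
    assert sum(len(s) for s in out.values()) == len(pairs)
    return out


def exclude_site(pairs: SpousePairSet, site: str) -> SpousePairSet:
    """Pairs with neither member enrolled at ``site``."""
    df = pairs.df
    ok = (df["site_male"] != site) & (df["site_female"] != site)
    return SpousePairSet(df[ok])
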