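"""Forward simulation of a two-generation, multi-subpopulation cohort.

Subpopulation allele frequencies are drawn under the Balding-Nichols model
(Beta distribution around a shared ancestral frequency, spread set by F_ST),
founders are sampled in Hardy-Weinberg proportions, spouse pairs are formed
with a tunable endogamy probability, and offspring genotypes follow Mendelian
transmission at unlinked SNPs.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .types import MISSING, NO_PARENT, GenotypeMatrix, PedigreeTable, SpousePairSet

logger = logging.getLogger(__name__)

#: n_children_per_couple: either a fixed count or an inclusive (low, high)
#: range sampled uniformly per couple.
ChildLaw = Union[int, Tuple[int, int]]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``endogamy_founder`` / ``endogamy_offspring`` give the probability that a
    pairing event is within-subpopulation in each generation.
    """

    n_subpops: int = 2
    n_founder_couples_per_pop: int = 100
    n_snps: int = 1000
    fst: float = 0.01
    ancestral_freq_range: Tuple[float, float] = (0.1, 0.9)
    endogamy_founder: float = 1.0
    endogamy_offspring: float = 1.0
    n_children_per_couple: ChildLaw = 2
    missing_rate: float = 0.0
    seed: int = 0
    #: what a non-endogamous pairing event does: "between" forces two
    #: distinct subpops; "random" draws the partner from the whole pool
    #: (endogamy=0 then means panmixia).
    exogamy: str = "between"

    def __post_init__(self) -> None:
        if self.n_subpops < 1 or self.n_founder_couples_per_pop < 1 or self.n_snps < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        for name in ("endogamy_founder", "endogamy_offspring", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.missing_rate >= 1.0:
            raise ValueError("missing_rate must be < 1")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if self.exogamy not in ("between", "random"):
            raise ValueError("exogamy must be 'between' or 'random'")
        law = self.n_children_per_couple
        if isinstance(law, int):
            if law < 0:
                raise ValueError("n_children_per_couple must be >= 0")
        else:
            lo_c, hi_c = law
            if lo_c < 0 or hi_c < lo_c:
                raise ValueError("invalid n_children_per_couple range")


@dataclass
class CohortDataset:
    """A simulated cohort plus its ground truth.

    ``truth_pairs`` records every mating with generation and a
    ``within_group`` flag; ``truth_subpop`` maps individual id to the true
    subpopulation label.
    """

    genotypes: GenotypeMatrix
    pedigree: PedigreeTable
    truth_pairs: pd.DataFrame
    truth_subpop: pd.Series
    config: SimConfig = None


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def sample_subpop_freqs(p_anc: np.ndarray, fst: float, rng: np.random.Generator,
                        n_subpops: int) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies.

    Each subpopulation's frequency at SNP j is drawn from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
    ``F p (1-p)``.  ``fst == 0`` returns the ancestral frequencies unchanged.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if np.any(p_anc <= 0.0) or np.any(p_anc >= 1.0):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    if fst == 0.0:
        return np.tile(p_anc, (n_subpops, 1))
    scale = (1.0 - fst) / fst
    a = p_anc * scale
    b = (1.0 - p_anc) * scale
    return rng.beta(a, b, size=(n_subpops, len(p_anc)))


def simulate_founders(freqs: np.ndarray, n_per_pop: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw founder dosages, subpop labels and balanced sexes.

    Dosage of individual i from subpop k at SNP j ~ Binomial(2, freqs[k, j]).
    Returns ``(dosages, subpop_index, sex)`` with sexes alternating
    male/female within each subpopulation (exact balance for even counts).
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0.0) or np.any(freqs > 1.0):
        raise ValueError("frequencies must be in [0, 1]")
    n_subpops, n_snps = freqs.shape
    dosages = np.empty((n_subpops * n_per_pop, n_snps), dtype=np.int8)
    subpop = np.repeat(np.arange(n_subpops), n_per_pop)
    for k in range(n_subpops):
        block = rng.binomial(2, freqs[k], size=(n_per_pop, n_snps))
        dosages[k * n_per_pop:(k + 1) * n_per_pop] = block.astype(np.int8)
    sex = np.where(np.arange(n_subpops * n_per_pop) % 2 == 0, "male", "female").astype(object)
    return dosages, subpop, sex


def mate_generation(ids: np.ndarray, subpop: np.ndarray, sex: np.ndarray,
                    endogamy: float, rng: np.random.Generator,
                    exogamy: str = "between") -> pd.DataFrame:
    """Pair males and females with a tunable within-subpopulation probability.

    Each pairing event is within-subpop with probability ``endogamy``;
    otherwise the partner comes from a distinct subpop (``exogamy="between"``,
    the default) or uniformly from the whole remaining pool
    (``exogamy="random"``, making ``endogamy=0`` panmictic).  Sampling is
    without replacement; individuals left without a feasible partner are
    dropped (count logged).

    Returns a frame with columns ``male_id, female_id, within_group``.
    """
    if not 0.0 <= endogamy <= 1.0:
        raise ValueError("endogamy must be in [0, 1]")
    if exogamy not in ("between", "random"):
        raise ValueError("exogamy must be 'between' or 'random'")
    ids = np.asarray(ids, dtype=object)
    subpop = np.asarray(subpop)
    sex = np.asarray(sex, dtype=object)
    males = [i for i in range(len(ids)) if sex[i] == "male"]
    females = [i for i in range(len(ids)) if sex[i] == "female"]
    if not males or not females:
        raise ValueError("need at least one male and one female")

    # female pools keyed by subpop, consumed without replacement
    pools: dict = {}
    for i in females:
        pools.setdefault(subpop[i], []).append(i)
    for pool in pools.values():
        rng.shuffle(pool)

    order = list(males)
    rng.shuffle(order)
    rows = []
    dropped = 0
    def pop_weighted(keys) -> int:
        # uniform over the remaining individuals across the given pools
        sizes = np.array([len(pools[k]) for k in keys])
        k = keys[int(rng.choice(len(keys), p=sizes / sizes.sum()))]
        return pools[k].pop()

    for m in order:
        want_within = rng.random() < endogamy
        own = subpop[m]
        same = pools.get(own, [])
        other_keys = [k for k in pools if k != own and pools[k]]
        if want_within:
            if not same:
                dropped += 1
                continue
            f = same.pop()
        elif exogamy == "random":
            all_keys = ([own] if same else []) + other_keys
            if not all_keys:
                dropped += 1
                continue
            f = pop_weighted(all_keys)
        else:
            if not other_keys:
                dropped += 1
                continue
            f = pop_weighted(other_keys)
        rows.append((ids[m], ids[f], subpop[m] == subpop[f]))
    leftover_f = sum(len(p) for p in pools.values())
    if dropped or leftover_f:
        logger.info("mate_generation: dropped %d males, %d females unmatched", dropped, leftover_f)
    return pd.DataFrame(rows, columns=["male_id", "female_id", "within_group"])


def breed_offspring(pairs: pd.DataFrame, dosages: np.ndarray, ids: np.ndarray,
                    n_children_law: ChildLaw, rng: np.random.Generator,
                    id_prefix: str = "c") -> tuple[np.ndarray, pd.DataFrame]:
    """Mendelian offspring at unlinked SNPs.

    Per child and SNP, one allele is drawn from each parent independently:
    ``child = Bernoulli(g_father/2) + Bernoulli(g_mother/2)``.

    Returns ``(child_dosages, child_frame)`` where ``child_frame`` has
    columns ``individual_id, father_id, mother_id, sex``.
    """
    pos = {s: i for i, s in enumerate(ids)}
    fathers, mothers, child_ids, sexes = [], [], [], []
    counter = 0
    for male, female in zip(pairs["male_id"], pairs["female_id"]):
        if male not in pos or female not in pos:
            raise KeyError(f"pair references unknown individual: {male!r}/{female!r}")
        if isinstance(n_children_law, int):
            n_children = n_children_law
        else:
            lo, hi = n_children_law
            n_children = int(rng.integers(lo, hi + 1))
        for _ in range(n_children):
            child_ids.append(f"{id_prefix}{counter}")
            fathers.append(male)
            mothers.append(female)
            sexes.append("male" if rng.random() < 0.5 else "female")
            counter += 1
    if not child_ids:
        return (np.empty((0, dosages.shape[1]), dtype=np.int8),
                pd.DataFrame(columns=["individual_id", "father_id", "mother_id", "sex"]))
    gf = dosages[[pos[f] for f in fathers], :].astype(float)
    gm = dosages[[pos[m] for m in mothers], :].astype(float)
    if np.any(gf < 0) or np.any(gm < 0):
        raise ValueError("parents must be fully genotyped before breeding")
    child = rng.binomial(1, gf / 2.0) + rng.binomial(1, gm / 2.0)
    frame = pd.DataFrame(
        {"individual_id": child_ids, "father_id": fathers, "mother_id": mothers, "sex": sexes}
    )
    return child.astype(np.int8), frame


def apply_missingness(genotypes: GenotypeMatrix, missing_rate: float,
                      rng: np.random.Generator) -> GenotypeMatrix:
    """Mask each entry independently with probability ``missing_rate``."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if missing_rate == 0.0:
        return genotypes
    dosages = genotypes.dosages.copy()
    mask = rng.random(dosages.shape) < missing_rate
    dosages[mask] = MISSING
    return GenotypeMatrix(dosages=dosages, sample_ids=genotypes.sample_ids,
                          snp_map=genotypes.snp_map)


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------

def _default_snp_map(n_snps: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "pos": np.arange(1, n_snps + 1) * 1000,
            "allele1": "A",
            "allele2": "G",
        }
    )


def simulate_cohort(config: SimConfig) -> CohortDataset:
    """Run the full two-generation simulation.

    Founders pair with ``endogamy_founder`` and produce genotyped offspring;
    offspring pair with ``endogamy_offspring``.  Each offspring couple gets a
    single ungenotyped pedigree-only child row so that spouse identification
    by in-common children works for both generations.
    """
    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(child) for name, child in zip(
        ("freqs", "founders", "mate_f", "breed", "mate_o", "missing", "anchor"),
        ss.spawn(7))}

    lo, hi = config.ancestral_freq_range
    p_anc = rngs["freqs"].uniform(lo, hi, size=config.n_snps)
    freqs = sample_subpop_freqs(p_anc, config.fst, rngs["freqs"], config.n_subpops)

    n_per_pop = 2 * config.n_founder_couples_per_pop
    f_dosages, f_subpop, f_sex = simulate_founders(freqs, n_per_pop, rngs["founders"])
    f_ids = np.array([f"f{i}" for i in range(len(f_subpop))], dtype=object)
    pop_label = np.array([f"pop{k}" for k in f_subpop], dtype=object)

    founder_pairs = mate_generation(f_ids, f_subpop, f_sex, config.endogamy_founder,
                                    rngs["mate_f"], exogamy=config.exogamy)
    o_dosages, o_frame = breed_offspring(founder_pairs, f_dosages, f_ids,
                                         config.n_children_per_couple, rngs["breed"],
                                         id_prefix="o")

    subpop_of = dict(zip(f_ids, f_subpop))
    # child subpop label: father's subpop (exogamous children are admixed in
    # truth; the discrete label is only used for offspring mating choices)
    o_subpop = np.array([subpop_of[f] for f in o_frame["father_id"]], dtype=int) \
        if len(o_frame) else np.array([], dtype=int)
    o_ids = o_frame["individual_id"].to_numpy(dtype=object) if len(o_frame) else np.array([], dtype=object)
    o_sex = o_frame["sex"].to_numpy(dtype=object) if len(o_frame) else np.array([], dtype=object)

    if len(o_ids) and (o_sex == "male").any() and (o_sex == "female").any():
        offspring_pairs = mate_generation(o_ids, o_subpop, o_sex,
                                          config.endogamy_offspring, rngs["mate_o"],
                                          exogamy=config.exogamy)
    else:
        offspring_pairs = pd.DataFrame(columns=["male_id", "female_id", "within_group"])

    snp_map = _default_snp_map(config.n_snps)
    all_dosages = np.vstack([f_dosages, o_dosages]) if len(o_ids) else f_dosages
    all_ids = np.concatenate([f_ids, o_ids])
    genotypes = GenotypeMatrix(dosages=all_dosages, sample_ids=all_ids, snp_map=snp_map)
    genotypes = apply_missingness(genotypes, config.missing_rate, rngs["missing"])

    # pedigree rows: founders, offspring, plus one pedigree-only grandchild
    # per offspring couple (enables in-common-children spouse discovery)
    site = np.where(np.arange(len(f_ids)) % 4 < 2, "siteA", "siteB").astype(object)
    site_of = dict(zip(f_ids, site))
    rows = []
    for i, fid in enumerate(f_ids):
        rows.append(("fam0", fid, NO_PARENT, NO_PARENT, f_sex[i], "-9",
                     "founder", site[i], pop_label[i]))
    for i in range(len(o_ids)):
        rows.append(("fam0", o_ids[i], o_frame["father_id"].iloc[i],
                     o_frame["mother_id"].iloc[i], o_sex[i], "-9",
                     "offspring", site_of[o_frame["father_id"].iloc[i]],
                     f"pop{o_subpop[i]}"))
    for j, (male, female) in enumerate(zip(offspring_pairs.get("male_id", []),
                                           offspring_pairs.get("female_id", []))):
        rows.append(("fam0", f"g{j}", male, female, "unknown", "-9",
                     "grandchild", "", ""))
    pedigree = PedigreeTable(pd.DataFrame(rows, columns=[
        "family_id", "individual_id", "father_id", "mother_id", "sex",
        "phenotype", "generation", "site", "subpop"]))

    founder_pairs = founder_pairs.assign(generation="founder")
    offspring_pairs = offspring_pairs.assign(generation="offspring")
    truth_pairs = pd.concat([founder_pairs, offspring_pairs], ignore_index=True)
    truth_subpop = pd.Series(
        {**{i: f"pop{k}" for i, k in zip(f_ids, f_subpop)},
         **{i: f"pop{k}" for i, k in zip(o_ids, o_subpop)}},
        name="subpop", dtype=object)
    return CohortDataset(genotypes=genotypes, pedigree=pedigree,
                         truth_pairs=truth_pairs, truth_subpop=truth_subpop,
                         config=config)


def truth_pair_set(cohort: CohortDataset, generation: str) -> SpousePairSet:
    """Ground-truth spouse pairs of one generation as a :class:`SpousePairSet`."""
    sub = cohort.truth_pairs[cohort.truth_pairs["generation"] == generation]
    site_of = dict(zip(cohort.pedigree.df["individual_id"], cohort.pedigree.df["site"]))
    return SpousePairSet(pd.DataFrame({
        "male_id": sub["male_id"].to_numpy(),
        "female_id": sub["female_id"].to_numpy(),
        "generation": generation,
        "site_male": [site_of.get(i, "") for i in sub["male_id"]],
        "site_female": [site_of.get(i, "") for i in sub["female_id"]],
        "n_common_children": 0,
    }))
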