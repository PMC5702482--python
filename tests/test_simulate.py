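import numpy as np
import pandas as pd
import pytest

from assortpca.simulate import (
    SimConfig,
    apply_missingness,
    breed_offspring,
    mate_generation,
    sample_subpop_freqs,
    simulate_cohort,
    simulate_founders,
    truth_pair_set,
)
from assortpca.types import MISSING

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# subpopulation frequency model
# ---------------------------------------------------------------------------

class TestSubpopFreqs:
    def test_fst_zero_returns_ancestral_unchanged(self, rng):
        p = np.array([0.2, 0.5, 0.8])
        out = sample_subpop_freqs(p, 0.0, rng, n_subpops=3)
        assert out.shape == (3, 3)
        assert np.array_equal(out, np.tile(p, (3, 1)))

    def test_degenerate_ancestral_freq_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_subpop_freqs(np.array([0.0, 0.5]), 0.1, rng, 2)
        with pytest.raises(ValueError):
            sample_subpop_freqs(np.array([1.0]), 0.1, rng, 2)

    def test_fst_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_subpop_freqs(np.array([0.5]), 1.0, rng, 2)

    def test_beta_variance_matches_closed_form(self, rng):
        # Var(p_sub) = F * p * (1 - p); p=0.3, F=0.01 -> 0.0021
        p = np.full(50_000, 0.3)
        draws = sample_subpop_freqs(p, 0.01, rng, n_subpops=1)[0]
        assert draws.var() == pytest.approx(0.01 * 0.3 * 0.7, rel=0.05)
        assert draws.mean() == pytest.approx(0.3, abs=0.002)


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

class TestFounders:
    def test_fixed_frequency_one_gives_all_hom(self, rng):
        freqs = np.array([[1.0, 0.0]])
        d, subpop, sex = simulate_founders(freqs, 10, rng)
        assert np.all(d[:, 0] == 2)
        assert np.all(d[:, 1] == 0)

    def test_binomial_moments(self, rng):
        freqs = np.full((1, 200), 0.5)
        d, _, _ = simulate_founders(freqs, 10_000, rng)
        assert d.mean() == pytest.approx(1.0, abs=0.01)
        assert (d == 1).mean() == pytest.approx(0.5, abs=0.01)

    def test_sexes_balanced_per_pop(self, rng):
        freqs = np.full((3, 5), 0.5)
        _, subpop, sex = simulate_founders(freqs, 100, rng)
        for k in range(3):
            males = (sex[subpop == k] == "male").sum()
            assert males == 50

    def test_hudson_fst_recovery(self, rng):
        # independent oracle: Hudson's estimator as ratio of averages
        fst = 0.05
        p_anc = rng.uniform(0.1, 0.9, size=2000)
        freqs = sample_subpop_freqs(p_anc, fst, rng, n_subpops=2)
        d, subpop, _ = simulate_founders(freqs, 200, rng)
        n1 = n2 = 2 * 200  # allele counts
        p1 = d[subpop == 0].mean(axis=0) / 2.0
        p2 = d[subpop == 1].mean(axis=0) / 2.0
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst_hat = num.sum() / den.sum()
        assert fst_hat == pytest.approx(fst, abs=0.01)


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------

def _toy_candidates(n_per_pop=200, n_pops=2):
    n = n_per_pop * n_pops
    ids = np.array([f"i{i}" for i in range(n)], dtype=object)
    subpop = np.repeat(np.arange(n_pops), n_per_pop)
    sex = np.where(np.arange(n) % 2 == 0, "male", "female").astype(object)
    return ids, subpop, sex


class TestMating:
    def test_full_endogamy_pairs_within(self, rng):
        ids, subpop, sex = _toy_candidates()
        pairs = mate_generation(ids, subpop, sex, 1.0, rng)
        assert len(pairs) == 200
        assert pairs["within_group"].all()

    def test_zero_endogamy_pairs_between(self, rng):
        ids, subpop, sex = _toy_candidates(n_pops=3)
        pairs = mate_generation(ids, subpop, sex, 0.0, rng)
        assert len(pairs) > 0
        assert not pairs["within_group"].any()

    def test_half_endogamy_rate(self, rng):
        ids, subpop, sex = _toy_candidates(n_per_pop=5000, n_pops=2)
        pairs = mate_generation(ids, subpop, sex, 0.5, rng)
        n = len(pairs)
        se = np.sqrt(0.25 / n)
        assert abs(pairs["within_group"].mean() - 0.5) < 3 * se

    def test_random_exogamy_zero_endogamy_is_panmictic(self, rng):
        # partner uniform over the pool: within-group share ~ pool share (1/2)
        ids, subpop, sex = _toy_candidates(n_per_pop=5000, n_pops=2)
        pairs = mate_generation(ids, subpop, sex, 0.0, rng, exogamy="random")
        assert abs(pairs["within_group"].mean() - 0.5) < 3 * np.sqrt(0.25 / len(pairs))

    def test_invalid_endogamy_rejected(self, rng):
        ids, subpop, sex = _toy_candidates(4)
        with pytest.raises(ValueError):
            mate_generation(ids, subpop, sex, 1.5, rng)

    def test_single_sex_rejected(self, rng):
        ids = np.array(["a", "b"], dtype=object)
        with pytest.raises(ValueError):
            mate_generation(ids, np.zeros(2, int), np.array(["male", "male"], dtype=object),
                            0.5, rng)

    def test_no_individual_reused(self, rng):
        ids, subpop, sex = _toy_candidates(101, 3)
        pairs = mate_generation(ids, subpop, sex, 0.7, rng)
        members = list(pairs["male_id"]) + list(pairs["female_id"])
        assert len(members) == len(set(members))


# ---------------------------------------------------------------------------
# offspring
# ---------------------------------------------------------------------------

class TestBreeding:
    def test_homozygous_parents_deterministic(self, rng):
        dosages = np.array([[2, 0], [2, 0]], dtype=np.int8)
        ids = np.array(["dad", "mom"], dtype=object)
        pairs = pd.DataFrame({"male_id": ["dad"], "female_id": ["mom"]})
        child, frame = breed_offspring(pairs, dosages, ids, 50, rng)
        assert np.all(child[:, 0] == 2)
        assert np.all(child[:, 1] == 0)
        assert list(frame["father_id"].unique()) == ["dad"]

    def test_het_by_het_punnett_ratios(self, rng):
        dosages = np.array([[1], [1]], dtype=np.int8)
        ids = np.array(["dad", "mom"], dtype=object)
        pairs = pd.DataFrame({"male_id": ["dad"], "female_id": ["mom"]})
        child, _ = breed_offspring(pairs, dosages, ids, 40_000, rng)
        freqs = np.bincount(child[:, 0], minlength=3) / 40_000
        assert freqs == pytest.approx([0.25, 0.5, 0.25], abs=0.01)

    def test_unknown_parent_id_rejected(self, rng):
        dosages = np.array([[1]], dtype=np.int8)
        pairs = pd.DataFrame({"male_id": ["dad"], "female_id": ["ghost"]})
        with pytest.raises(KeyError):
            breed_offspring(pairs, dosages, np.array(["dad"], dtype=object), 1, rng)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

class TestMissingness:
    def test_rate_zero_unchanged(self, rng):
        g = make_genotypes([[0, 1], [2, 1]])
        out = apply_missingness(g, 0.0, rng)
        assert np.array_equal(out.dosages, g.dosages)

    def test_rate_half_masks_half(self, rng):
        g = make_genotypes(np.ones((200, 500), dtype=np.int8))
        out = apply_missingness(g, 0.5, rng)
        frac = (out.dosages == MISSING).mean()
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_small_rate_keeps_most_snps_above_call_rate(self, rng):
        from assortpca.qc import call_rate_filter
        g = make_genotypes(np.ones((500, 300), dtype=np.int8))
        out = apply_missingness(g, 0.04, rng)
        kept = call_rate_filter(out, 0.95)
        assert len(kept) > 0.5 * g.n_snps


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

def _mendelian_feasible(child, gf, gm):
    """Can (gf, gm) produce dosage child with one allele from each parent?"""
    af = {0: (0,), 1: (0, 1), 2: (1,)}
    return any(a + b == child for a in af[gf] for b in af[gm])


class TestCohort:
    CFG = SimConfig(n_subpops=2, n_founder_couples_per_pop=20, n_snps=60,
                    fst=0.05, endogamy_founder=0.8, endogamy_offspring=0.5,
                    n_children_per_couple=2, missing_rate=0.0, seed=11)

    def test_mendelian_consistency_everywhere(self):
        cohort = simulate_cohort(self.CFG)
        g = cohort.genotypes
        pos = {s: i for i, s in enumerate(g.sample_ids)}
        ped = cohort.pedigree.df
        offspring = ped[ped["generation"] == "offspring"]
        assert len(offspring) > 0
        for _, row in offspring.iterrows():
            c = g.dosages[pos[row["individual_id"]]]
            f = g.dosages[pos[row["father_id"]]]
            m = g.dosages[pos[row["mother_id"]]]
            for j in range(g.n_snps):
                assert _mendelian_feasible(int(c[j]), int(f[j]), int(m[j]))

    def test_parents_exist_and_sexes_differ(self):
        cohort = simulate_cohort(self.CFG)
        ped = cohort.pedigree.df
        known = set(ped["individual_id"])
        child_rows = ped[ped["father_id"] != "0"]
        assert child_rows["father_id"].isin(known).all()
        assert child_rows["mother_id"].isin(known).all()
        sex_of = dict(zip(ped["individual_id"], ped["sex"]))
        for _, pair in cohort.truth_pairs.iterrows():
            assert sex_of[pair["male_id"]] == "male"
            assert sex_of[pair["female_id"]] == "female"

    def test_determinism_bit_identical(self):
        a = simulate_cohort(self.CFG)
        b = simulate_cohort(self.CFG)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.pedigree.df, b.pedigree.df)
        pd.testing.assert_frame_equal(a.truth_pairs, b.truth_pairs)

    def test_endogamy_truth_flags_match_parameter(self):
        cfg = SimConfig(n_subpops=2, n_founder_couples_per_pop=2000, n_snps=5,
                        fst=0.05, endogamy_founder=0.7, endogamy_offspring=1.0,
                        n_children_per_couple=0, seed=5)
        cohort = simulate_cohort(cfg)
        founder = cohort.truth_pairs[cohort.truth_pairs["generation"] == "founder"]
        rate = founder["within_group"].mean()
        se = np.sqrt(0.7 * 0.3 / len(founder))
        assert abs(rate - 0.7) < 3 * se

    def test_truth_pair_set_matches_generation(self):
        cohort = simulate_cohort(self.CFG)
        founders = truth_pair_set(cohort, "founder")
        n_truth = (cohort.truth_pairs["generation"] == "founder").sum()
        assert len(founders) == n_truth

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(fst=1.0)
        with pytest.raises(ValueError):
            SimConfig(endogamy_founder=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_snps=0)
        with pytest.raises(ValueError):
            SimConfig(ancestral_freq_range=(0.0, 0.9))
        with pytest.raises(ValueError):
            SimConfig(exogamy="nope")
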