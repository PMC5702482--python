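import numpy as np
import pytest

from assortpca.qc import (
    QCParams,
    call_rate_filter,
    dosage_r2,
    ld_prune,
    maf_filter,
    minor_allele_freq,
    run_qc,
)
from assortpca.types import MISSING

from conftest import make_genotypes


def brute_force_window_check(genotypes, kept, params):
    """Oracle: max r^2 over kept pairs co-occurring in any scanned window."""
    kept = set(kept.tolist())
    worst = 0.0
    m = genotypes.n_snps
    start = 0
    while start < m:
        window = [j for j in range(start, min(start + params.prune_window, m)) if j in kept]
        for a in range(len(window)):
            for b in range(a + 1, len(window)):
                r2 = dosage_r2(genotypes.dosages[:, window[a]], genotypes.dosages[:, window[b]])
                if np.isfinite(r2):
                    worst = max(worst, r2)
        if start + params.prune_window >= m:
            break
        start += params.prune_step
    return worst


class TestCallRate:
    def test_96_of_100_kept_at_095(self):
        d = np.ones((100, 1), dtype=np.int8)
        d[:4, 0] = MISSING  # call rate 0.96 > 0.95
        assert call_rate_filter(make_genotypes(d), 0.95).tolist() == [0]

    def test_no_missing_all_kept(self, rng):
        d = rng.integers(0, 3, size=(20, 8)).astype(np.int8)
        assert len(call_rate_filter(make_genotypes(d), 0.95)) == 8

    def test_exactly_at_threshold_removed(self):
        d = np.ones((100, 1), dtype=np.int8)
        d[:5, 0] = MISSING  # exactly 0.95 -> strict > removes it
        assert len(call_rate_filter(make_genotypes(d), 0.95)) == 0

    def test_idempotent(self, rng):
        d = rng.integers(0, 3, size=(50, 30)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        g = make_genotypes(d)
        kept = call_rate_filter(g, 0.95)
        g2 = g.take_snps(kept)
        assert len(call_rate_filter(g2, 0.95)) == g2.n_snps


class TestMaf:
    def test_half_frequency_kept(self):
        d = np.array([[0], [1], [1], [2]], dtype=np.int8)  # p = 0.5
        assert maf_filter(make_genotypes(d), 0.05).tolist() == [0]

    def test_monomorphic_removed(self):
        d = np.zeros((10, 1), dtype=np.int8)
        assert len(maf_filter(make_genotypes(d), 0.05)) == 0

    def test_hand_computed_maf(self):
        d = np.array([[0], [0], [1], [1]], dtype=np.int8)  # p = 0.25
        g = make_genotypes(d)
        assert minor_allele_freq(g)[0] == pytest.approx(0.25)
        assert maf_filter(g, 0.05).tolist() == [0]

    def test_all_missing_snp_removed(self):
        d = np.full((6, 1), MISSING, dtype=np.int8)
        assert len(maf_filter(make_genotypes(d), 0.05)) == 0

    def test_exactly_at_threshold_removed(self):
        # p = 0.05 exactly: 2 alt alleles over 40
        d = np.zeros((20, 1), dtype=np.int8)
        d[0, 0] = 2
        assert len(maf_filter(make_genotypes(d), 0.05)) == 0


class TestDosageR2:
    def test_identical_vectors(self):
        x = np.array([0, 1, 2, 1], dtype=np.int8)
        assert dosage_r2(x, x) == pytest.approx(1.0)

    def test_sign_free(self):
        x = np.array([0, 1, 2, 1], dtype=np.int8)
        assert dosage_r2(x, 2 - x) == pytest.approx(1.0)

    def test_hand_case_matches_corrcoef_oracle(self):
        x = np.array([0, 1, 2, 1], dtype=np.int8)
        y = np.array([0, 0, 2, 2], dtype=np.int8)
        expected = float(np.corrcoef(x, y)[0, 1]) ** 2  # = 0.5
        assert dosage_r2(x, y) == pytest.approx(expected)
        assert dosage_r2(x, y) == pytest.approx(0.5)

    def test_pairwise_complete_overlap(self):
        x = np.array([0, 1, 2, MISSING, 2], dtype=np.int8)
        y = np.array([0, 1, MISSING, 2, 2], dtype=np.int8)
        expected = float(np.corrcoef([0, 1, 2], [0, 1, 2])[0, 1]) ** 2
        assert dosage_r2(x, y) == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        assert np.isnan(dosage_r2(np.array([1, 1, 1], dtype=np.int8),
                                  np.array([0, 1, 2], dtype=np.int8)))

    def test_tiny_overlap_undefined(self):
        x = np.array([0, MISSING, MISSING], dtype=np.int8)
        y = np.array([1, 1, 2], dtype=np.int8)
        assert np.isnan(dosage_r2(x, y))


def _planted_block_genotypes(rng, n=80, m=200, n_blocks=8):
    """Independent SNPs with planted correlated blocks (noised copies)."""
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    starts = rng.choice(m - 6, size=n_blocks, replace=False)
    for s in starts:
        src = d[:, s].copy()
        for off in range(1, 4):
            noisy = src.copy()
            flip = rng.random(n) < 0.08
            noisy[flip] = rng.integers(0, 3, size=flip.sum())
            d[:, s + off] = noisy
    return make_genotypes(d)


class TestLdPrune:
    def test_independent_snps_untouched(self, rng):
        p = rng.uniform(0.2, 0.8, size=60)
        d = rng.binomial(2, p, size=(500, 60)).astype(np.int8)
        g = make_genotypes(d)
        kept = ld_prune(g, QCParams(max_r2=0.30))
        assert len(kept) >= 58  # independence => removals exceptional

    def test_adjacent_duplicate_drops_later_copy(self, rng):
        d = rng.integers(0, 3, size=(50, 5)).astype(np.int8)
        d[:, 3] = d[:, 2]
        kept = ld_prune(make_genotypes(d), QCParams())
        assert 2 in kept and 3 not in kept

    def test_planted_blocks_pass_brute_force_checker(self, rng):
        params = QCParams(prune_window=50, prune_step=5, max_r2=0.30)
        for trial in range(5):
            g = _planted_block_genotypes(np.random.default_rng(100 + trial))
            kept = ld_prune(g, params)
            assert brute_force_window_check(g, kept, params) <= 0.30
            assert len(kept) < g.n_snps  # the planted blocks forced removals

    def test_constant_snp_never_causes_removal(self, rng):
        d = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
        d[:, 2] = 1
        kept = ld_prune(make_genotypes(d), QCParams())
        assert 2 in kept

    def test_idempotent(self, rng):
        g = _planted_block_genotypes(rng)
        params = QCParams()
        kept = ld_prune(g, params)
        again = ld_prune(g.take_snps(kept), params)
        assert len(again) == len(kept)

    def test_chromosomes_pruned_independently(self, rng):
        d = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
        d[:, 1] = d[:, 0]  # duplicates but on different chromosomes
        g = make_genotypes(d, chrom=["1", "2", "2", "3"])
        kept = ld_prune(g, QCParams())
        assert kept.tolist() == [0, 1, 2, 3]


class TestRunQc:
    def test_pipeline_order_and_counts(self, rng):
        p = rng.uniform(0.2, 0.8, size=100)
        d = rng.binomial(2, p, size=(200, 100)).astype(np.int8)
        d[:, 10] = 0                      # monomorphic -> MAF stage
        d[:20, 11] = MISSING              # call rate 0.90 -> call-rate stage
        d[:, 13] = d[:, 12]               # duplicate -> prune stage
        g = make_genotypes(d)
        out, report = run_qc(g, QCParams())
        assert report["n_input"] == 100
        assert report["n_after_call_rate"] == 99
        assert report["n_after_maf"] == 98
        assert report["n_after_prune"] <= 97
        assert out.n_snps == report["n_after_prune"]
        assert "snp11" not in report["kept_snp_ids"]
        assert "snp10" not in report["kept_snp_ids"]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            QCParams(min_call_rate=1.5)
        with pytest.raises(ValueError):
            QCParams(prune_window=2, prune_step=5)
        with pytest.raises(ValueError):
            QCParams(max_r2=0.0)
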