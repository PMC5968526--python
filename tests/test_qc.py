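import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flockgen.qc import QCConfig, apply_qc, genotype_r2, hwe_exact_test, ld_prune

from conftest import make_dataset, random_dataset


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Full enumeration with exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    probs = {}
    for het in range(min(n_A, 2 * n - n_A) % 2, min(n_A, 2 * n - n_A) + 1, 2):
        aa = (n_A - het) // 2
        bb = n - aa - het
        probs[het] = Fraction(
            2**het * math.factorial(n),
            math.factorial(aa) * math.factorial(het) * math.factorial(bb),
        )
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)


class TestHWEExact:
    def test_two_homozygotes(self):
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3, abs=1e-12)

    def test_modal_configuration_gives_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_matches_enumeration_oracle_all_small_tables(self):
        """Every genotype table with 2n <= 30, against exact enumeration."""
        for n in range(1, 16):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    expected = hwe_oracle(n_AA, n_Aa, n_aa)
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    assert abs(got - expected) < 1e-12, (n_AA, n_Aa, n_aa)

    def test_probabilities_sum_to_one(self):
        # the least extreme configuration has the modal het count -> p = 1
        for n_A, n in [(10, 10), (7, 8), (15, 15)]:
            hets = range(n_A % 2, min(n_A, 2 * n - n_A) + 1, 2)
            total = 0.0
            seen = set()
            for h in hets:
                aa = (n_A - h) // 2
                p = hwe_exact_test(aa, h, n - aa - h)
                seen.add(h)
            assert seen  # enumeration covered

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_allele_relabeling_invariance(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(hwe_exact_test(b, h, a), abs=1e-12)


class TestGenotypeR2:
    def test_identical_vectors(self):
        x = np.array([0, 1, 2, 1], dtype=np.int8)
        assert genotype_r2(x, x) == pytest.approx(1.0)

    def test_constant_vector_flagged(self):
        assert math.isnan(genotype_r2(np.array([1, 1, 1]), np.array([0, 1, 2])))

    def test_matches_pearson_oracle(self):
        x = np.array([0, 1, 2, 0], dtype=np.int8)
        y = np.array([0, 1, 2, 2], dtype=np.int8)
        r = np.corrcoef(x.astype(float), y.astype(float))[0, 1]
        assert genotype_r2(x, y) == pytest.approx(r * r, abs=1e-12)

    def test_pairwise_complete_only(self):
        x = np.array([0, 1, 2, -1], dtype=np.int8)
        y = np.array([0, 1, 2, 0], dtype=np.int8)
        assert genotype_r2(x, y) == pytest.approx(1.0)


def ld_prune_oracle(dataset, config):
    """Independent re-statement of the window/step/removal rule."""
    maf = dataset.maf()
    keep = {s.snp_id for s in dataset.snps}
    by_chrom = {}
    for j, s in enumerate(dataset.snps):
        by_chrom.setdefault(s.chromosome, []).append(j)
    for idx in by_chrom.values():
        start = 0
        while True:
            window = idx[start:start + config.ld_window_snps]
            while True:
                kept = [j for j in window if dataset.snps[j].snp_id in keep]
                removed = False
                for a, b in itertools.combinations(kept, 2):
                    r2 = genotype_r2(dataset.dosages[:, a], dataset.dosages[:, b])
                    if not math.isnan(r2) and r2 > config.ld_r2_max:
                        victim = a if maf[a] < maf[b] else b
                        keep.discard(dataset.snps[victim].snp_id)
                        removed = True
                        break
                if not removed:
                    break
            if start + config.ld_window_snps >= len(idx):
                break
            start += config.ld_step_snps
    return [s.snp_id for s in dataset.snps if s.snp_id in keep]


class TestLDPrune:
    def test_duplicate_columns_one_survives(self, rng):
        col = rng.integers(0, 3, size=8)
        other = rng.integers(0, 3, size=8)
        ds = make_dataset(np.column_stack([col, col, other]))
        kept = ld_prune(ds, QCConfig(ld_window_snps=3, ld_step_snps=1))
        assert sum(k in kept for k in ("snp0", "snp1")) == 1

    def test_uncorrelated_all_kept(self, rng):
        ds = random_dataset(rng, n=40, L=6)
        cfg = QCConfig(ld_window_snps=6, ld_step_snps=2, ld_r2_max=0.99)
        assert ld_prune(ds, cfg) == ds.snp_ids

    def test_matches_brute_force_oracle(self, rng):
        cfg = QCConfig(ld_window_snps=4, ld_step_snps=2, ld_r2_max=0.5)
        for _ in range(10):
            base = rng.integers(0, 3, size=(12, 7)).astype(np.int8)
            # plant correlation: copies with noise
            base[:, 2] = base[:, 0]
            base[:, 5] = np.clip(base[:, 4] + (rng.random(12) < 0.2), 0, 2)
            ds = make_dataset(base)
            assert ld_prune(ds, cfg) == ld_prune_oracle(ds, cfg)

    def test_no_kept_pair_above_threshold_within_window(self, rng):
        ds = random_dataset(rng, n=15, L=30)
        cfg = QCConfig(ld_window_snps=10, ld_step_snps=3, ld_r2_max=0.4)
        kept = set(ld_prune(ds, cfg))
        idx = [j for j, s in enumerate(ds.snps) if s.snp_id in kept]
        for start in range(0, len(ds.snps), cfg.ld_step_snps):
            window = [j for j in range(start, min(start + cfg.ld_window_snps, ds.n_snps))
                      if j in idx]
            for a, b in itertools.combinations(window, 2):
                r2 = genotype_r2(ds.dosages[:, a], ds.dosages[:, b])
                assert math.isnan(r2) or r2 <= cfg.ld_r2_max


class TestApplyQC:
    def test_low_maf_snp_dropped(self, rng):
        d = rng.integers(0, 3, size=(20, 3)).astype(np.int8)
        d[:, 1] = 0
        d[0, 1] = 1  # MAF = 1/40 = 0.025 < 0.05
        ds = make_dataset(d)
        out, report = apply_qc(ds, QCConfig(hwe_enabled=False))
        assert "snp1" not in out.snp_ids
        frame = report.to_frame().set_index("filter")
        assert frame.loc["maf", "items_removed"] >= 1

    def test_high_missingness_sample_dropped(self, rng):
        d = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        d[0, :3] = -1  # 15% missing > 10%
        ds = make_dataset(d)
        out, _ = apply_qc(ds, QCConfig(hwe_enabled=False, maf_min=0.0))
        assert "S0" not in out.sample_ids

    def test_clean_fixture_unchanged(self, rng):
        ds = random_dataset(rng, n=30, L=10)
        cfg = QCConfig(hwe_enabled=False, maf_min=0.0, ld_r2_max=1.0)
        out, report = apply_qc(ds, cfg)
        assert out == ds
        assert all(r == 0 for _, r, _ in report.steps)

    def test_idempotent(self, rng):
        ds = random_dataset(rng, n=25, L=40)
        cfg = QCConfig()
        once, _ = apply_qc(ds, cfg)
        twice, report2 = apply_qc(once, cfg)
        assert twice == once

    def test_non_autosomal_dropped(self, rng):
        d = rng.integers(0, 3, size=(10, 2)).astype(np.int8)
        ds_x = make_dataset(d, chromosome="27")  # beyond sheep autosomes
        with pytest.raises(ValueError, match="no autosomal"):
            apply_qc(ds_x, QCConfig())

    def test_score_masking(self, rng):
        ds = random_dataset(rng, n=10, L=4)
        scores = pd.DataFrame(
            [{"sample_id": "S0", "snp_id": "snp0", "gc": 0.2, "gt": 0.9}]
        )
        cfg = QCConfig(hwe_enabled=False, maf_min=0.0, snp_call_rate_min=0.0,
                       sample_call_rate_min=0.0)
        out, report = apply_qc(ds, cfg, scores=scores)
        assert report.steps[0] == ("genotype_scores", 1, int((out.dosages != -1).sum()))

    def test_hwe_skipped_when_disabled(self, rng):
        # an extreme heterozygote excess fails exact HWE at 1e-6
        d = np.ones((40, 2), dtype=np.int8)
        d[:, 1] = rng.integers(0, 3, size=40)
        ds = make_dataset(d)
        cfg_on = QCConfig(maf_min=0.0, ld_r2_max=1.01)
        out_on, _ = apply_qc(ds, cfg_on)
        assert "snp0" not in out_on.snp_ids
        cfg_off = QCConfig(maf_min=0.0, hwe_enabled=False, ld_r2_max=1.01)
        out_off, _ = apply_qc(ds, cfg_off)
        assert "snp0" in out_off.snp_ids
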