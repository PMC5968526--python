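"""Diversity statistics against naive loop-based oracles."""

import math

import numpy as np
import pytest

from flockgen.dataset import MISSING
from flockgen.diversity import (
    allelic_richness,
    fst_matrix,
    heterozygosity,
    nei_distance,
    wc_fst,
)

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# oracles: direct transcriptions of the defining formulas, loops only
# ---------------------------------------------------------------------------

def pop_rows(ds, pop):
    return [i for i, s in enumerate(ds.samples) if s.population_id == pop]


def he_ho_oracle(ds, pop):
    he, ho, used = [], [], 0
    for j in range(ds.n_snps):
        col = [ds.dosages[i, j] for i in pop_rows(ds, pop)]
        col = [x for x in col if x != MISSING]
        n = len(col)
        if n < 2:
            continue
        p = sum(col) / (2 * n)
        he.append((2 * n / (2 * n - 1)) * (1 - p * p - (1 - p) ** 2))
        ho.append(sum(1 for x in col if x == 1) / n)
    return sum(ho) / len(ho), sum(he) / len(he)


def ar_oracle(ds, pop, g):
    vals = []
    for j in range(ds.n_snps):
        col = [ds.dosages[i, j] for i in pop_rows(ds, pop) if ds.dosages[i, j] != MISSING]
        N = 2 * len(col)
        nb = sum(col)
        total = 0.0
        for Ni in (nb, N - nb):
            total += 1.0 - math.comb(N - Ni, g) / math.comb(N, g)
        vals.append(total)
    return sum(vals) / len(vals)


def wc_oracle(ds, pa, pb):
    num = den = 0.0
    for j in range(ds.n_snps):
        stats = []
        for pop in (pa, pb):
            col = [ds.dosages[i, j] for i in pop_rows(ds, pop) if ds.dosages[i, j] != MISSING]
            n = len(col)
            stats.append((n, sum(col) / (2 * n), sum(1 for x in col if x == 1) / n))
        (n1, p1, h1), (n2, p2, h2) = stats
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        if a + b + c != 0:
            num += a
            den += a + b + c
    return num / den


def nei_oracle(ds, pa, pb):
    jx = jy = jxy = 0.0
    for j in range(ds.n_snps):
        ps = []
        for pop in (pa, pb):
            col = [ds.dosages[i, j] for i in pop_rows(ds, pop) if ds.dosages[i, j] != MISSING]
            ps.append(sum(col) / (2 * len(col)))
        p, q = ps
        jx += p * p + (1 - p) ** 2
        jy += q * q + (1 - q) ** 2
        jxy += p * q + (1 - p) * (1 - q)
    return -math.log(jxy / math.sqrt(jx * jy))


class TestHeterozygosity:
    def test_two_opposite_homozygotes(self):
        ds = make_dataset([[0], [2]])
        table = heterozygosity(ds).frame
        assert table.loc["POP1", "H_E"] == pytest.approx(2 / 3, abs=1e-12)

    def test_monomorphic_locus_contributes_zero(self):
        ds = make_dataset([[0, 1], [0, 1]])
        table = heterozygosity(ds).frame
        # locus 0: H_E = 0; locus 1: n=2, p=.5 -> 2/3; mean = 1/3
        assert table.loc["POP1", "H_E"] == pytest.approx(1 / 3, abs=1e-12)

    def test_all_heterozygous_ho_is_one(self):
        ds = make_dataset([[1, 1], [1, 1], [1, 1]])
        assert heterozygosity(ds).frame.loc["POP1", "H_O"] == 1.0

    def test_matches_oracle(self, rng):
        for _ in range(10):
            ds = random_dataset(rng, n=10, L=20, missing_rate=0.05, n_pops=2)
            table = heterozygosity(ds).frame
            for pop in ("POP1", "POP2"):
                ho, he = he_ho_oracle(ds, pop)
                assert table.loc[pop, "H_O"] == pytest.approx(ho, abs=1e-12)
                assert table.loc[pop, "H_E"] == pytest.approx(he, abs=1e-12)


class TestAllelicRichness:
    def test_combinatorial_example(self):
        # allele counts (3,1) out of 4, g=2 -> 1.5
        ds = make_dataset([[1], [0]])  # B count 1 of 4 alleles
        table = allelic_richness(ds, g=2)
        assert table.frame.loc["POP1", "A_R"] == pytest.approx(1.5, abs=1e-12)

    def test_monomorphic_is_one(self):
        ds = make_dataset([[0], [0], [0]])
        assert allelic_richness(ds, g=2).frame.loc["POP1", "A_R"] == pytest.approx(1.0)

    def test_full_depth_counts_observed_alleles(self):
        ds = make_dataset([[1], [0]])
        assert allelic_richness(ds, g=4).frame.loc["POP1", "A_R"] == pytest.approx(2.0)

    def test_monotone_in_g(self, rng):
        ds = random_dataset(rng, n=10, L=15)
        vals = [allelic_richness(ds, g=g).frame.loc["POP1", "A_R"] for g in range(2, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_g_below_two_rejected(self, rng):
        ds = random_dataset(rng, n=5, L=5)
        with pytest.raises(ValueError):
            allelic_richness(ds, g=1)

    def test_matches_oracle(self, rng):
        for _ in range(5):
            ds = random_dataset(rng, n=10, L=20, n_pops=2)
            table = allelic_richness(ds, g=6).frame
            for pop in ("POP1", "POP2"):
                assert table.loc[pop, "A_R"] == pytest.approx(
                    ar_oracle(ds, pop, 6), abs=1e-12
                )


class TestWCFst:
    def test_fixed_opposite_alleles(self):
        ds = make_dataset([[2]] * 5 + [[0]] * 5, populations=["A"] * 5 + ["B"] * 5)
        assert wc_fst(ds, "A", "B") == pytest.approx(1.0)

    def test_identical_populations_near_zero(self, rng):
        d = rng.binomial(2, 0.4, size=(100, 300)).astype(np.int8)
        ds = make_dataset(d, populations=["A"] * 50 + ["B"] * 50)
        theta = wc_fst(ds, "A", "B")
        assert abs(theta) < 0.01  # small negative values permitted

    def test_component_example(self):
        # p1=0.8 (32/16/2), p2=0.2 (2/16/32)
        d = [[2]] * 32 + [[1]] * 16 + [[0]] * 2 + [[0]] * 32 + [[1]] * 16 + [[2]] * 2
        ds = make_dataset(d, populations=["A"] * 50 + ["B"] * 50)
        assert wc_fst(ds, "A", "B") == pytest.approx(wc_oracle(ds, "A", "B"), abs=1e-12)

    def test_symmetry_and_oracle(self, rng):
        for _ in range(5):
            ds = random_dataset(rng, n=10, L=20, n_pops=2)
            t1 = wc_fst(ds, "POP1", "POP2")
            assert t1 == wc_fst(ds, "POP2", "POP1")
            assert t1 == pytest.approx(wc_oracle(ds, "POP1", "POP2"), abs=1e-12)

    def test_matrix_symmetric_zero_diagonal(self, rng):
        ds = random_dataset(rng, n=12, L=30, n_pops=3)
        m = fst_matrix(ds)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        d = [[0], [1], [2], [0], [1], [2]]
        ds = make_dataset(d, populations=["A"] * 3 + ["B"] * 3)
        assert nei_distance(ds, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_fixed_opposite_infinite(self):
        ds = make_dataset([[2], [2], [0], [0]], populations=["A", "A", "B", "B"])
        with pytest.warns(UserWarning):
            assert nei_distance(ds, "A", "B") == math.inf

    def test_matches_oracle(self, rng):
        for _ in range(5):
            ds = random_dataset(rng, n=10, L=10, n_pops=2)
            assert nei_distance(ds, "POP1", "POP2") == pytest.approx(
                nei_oracle(ds, "POP1", "POP2"), abs=1e-12
            )
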