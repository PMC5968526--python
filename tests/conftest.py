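import numpy as np
import pytest

from flockgen.dataset import GenotypeDataset, SampleRecord, SNPRecord


def make_dataset(dosages, populations=None, chromosome="1", positions=None,
                 alleles=("A", "G"), id_prefix="S"):
    """Small-dataset helper used across the suite."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    populations = populations or ["POP1"] * n
    positions = positions or [(j + 1) * 10_000 for j in range(L)]
    samples = [SampleRecord(f"{id_prefix}{i}", populations[i]) for i in range(n)]
    snps = [
        SNPRecord(f"snp{j}", chromosome, positions[j], alleles[0], alleles[1])
        for j in range(L)
    ]
    return GenotypeDataset(samples, snps, dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dataset(rng, n=10, L=20, missing_rate=0.0, n_pops=1, id_prefix="S"):
    """Random polymorphic dataset (every SNP 0 < p < 1, even after missing)."""
    while True:
        d = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        if missing_rate:
            mask = rng.random((n, L)) < missing_rate
            d[mask] = -1
        obs = d != -1
        s = np.where(obs, d, 0).sum(axis=0)
        tot = 2 * obs.sum(axis=0)
        if np.all(obs.sum(axis=0) >= 2) and np.all(s > 0) and np.all(s < tot):
            pops = [f"POP{1 + i * n_pops // n}" for i in range(n)]
            return make_dataset(d, populations=pops, id_prefix=id_prefix)


def canonical_minor_b(ds):
    """Flip dosage columns so allele B is the minor allele (the coding the
    PLINK reader produces)."""
    d = ds.dosages.copy()
    p = ds.allele_b_freq()
    for j in np.where(p > 0.5)[0]:
        nm = d[:, j] != -1
        d[nm, j] = 2 - d[nm, j]
    return ds.__class__(ds.samples, ds.snps, d)
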