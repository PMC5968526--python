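"""Per-population diversity and between-population differentiation.

Statistics: observed/unbiased expected heterozygosity (Nei's small-sample
correction), rarefied allelic richness (Hurlbert rarefaction at a common
allele draw g), the Weir & Cockerham (1984) theta estimator of FST with
multi-locus ratio-of-averages combining, and Nei's (1972) standard genetic
distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .dataset import MISSING, GenotypeDataset


@dataclass
class DiversityTable:
    frame: pd.DataFrame  # index: population_id; columns: n_samples, H_O, H_E, A_R
    rarefaction_g: int | None = None

    def to_tsv(self, sink) -> None:
        self.frame.to_csv(sink, sep="\t")


@dataclass
class FstMatrix:
    population_ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.population_ids, columns=self.population_ids)

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t")

    def to_phylip(self, sink) -> None:
        close = False
        if isinstance(sink, str):
            sink, close = open(sink, "w"), True
        try:
            sink.write(f"{len(self.population_ids)}\n")
            for pid, row in zip(self.population_ids, self.values):
                sink.write(pid + "  " + "  ".join(f"{v:.10f}" for v in row) + "\n")
        finally:
            if close:
                sink.close()


def _pop_counts(dataset: GenotypeDataset, idx: np.ndarray):
    """Per-locus (n genotyped, allele-B count, het count) for one population."""
    x = dataset.dosages[idx]
    obs = x != MISSING
    n = obs.sum(axis=0)
    b = np.where(obs, x, 0).sum(axis=0)
    het = ((x == 1) & obs).sum(axis=0)
    return n, b, het


def heterozygosity(
    dataset: GenotypeDataset, populations: list[str] | None = None
) -> DiversityTable:
    """Observed and unbiased expected heterozygosity per population.

    Per locus, unbiased H_E = (2n/(2n-1)) (1 - sum p^2) with n the number of
    genotyped diploids; H_O is the observed heterozygote fraction. The
    population value is the mean over loci with n >= 2.
    """
    pop_idx = dataset.population_indices()
    populations = populations or list(pop_idx)
    rows = []
    for pop in populations:
        idx = pop_idx[pop]
        n, b, het = _pop_counts(dataset, idx)
        usable = n >= 2
        if not usable.any():
            raise ValueError(f"population {pop!r} has < 2 genotyped samples at every locus")
        n_u = n[usable].astype(float)
        p = b[usable] / (2 * n_u)
        he = (2 * n_u / (2 * n_u - 1)) * (1 - p**2 - (1 - p) ** 2)
        ho = het[usable] / n_u
        rows.append((pop, len(idx), float(ho.mean()), float(he.mean())))
    frame = pd.DataFrame(rows, columns=["population_id", "n_samples", "H_O", "H_E"])
    return DiversityTable(frame.set_index("population_id"))


def _rarefied_richness(counts: np.ndarray, total: np.ndarray, g: int) -> np.ndarray:
    """Expected allele count in a draw of g alleles, per locus.

    ``counts``: (2, L) allele counts; ``total``: (L,) total alleles.
    Uses log-gamma for the hypergeometric miss probability C(N-Ni,g)/C(N,g).
    """
    N = total.astype(float)
    out = np.zeros(counts.shape[1])
    for Ni in counts:
        Ni = Ni.astype(float)
        miss = np.zeros_like(N)
        can_miss = N - Ni >= g
        a = N[can_miss] - Ni[can_miss]
        b = N[can_miss]
        miss[can_miss] = np.exp(
            gammaln(a + 1) - gammaln(a - g + 1) - (gammaln(b + 1) - gammaln(b - g + 1))
        )
        out += 1.0 - miss
    return out


def allelic_richness(
    dataset: GenotypeDataset,
    populations: list[str] | None = None,
    g: int | None = None,
) -> DiversityTable:
    """Rarefied allelic richness per population.

    ``g`` (allele draws) defaults to the minimum per-population per-locus
    genotyped allele count, so one rarefaction depth serves the whole table.
    """
    pop_idx = dataset.population_indices()
    populations = populations or list(pop_idx)
    stats = {pop: _pop_counts(dataset, pop_idx[pop]) for pop in populations}
    min_alleles = min(int((2 * n).min()) for n, _, _ in stats.values())
    if g is None:
        g = min_alleles
    if g < 2:
        raise ValueError(f"rarefaction depth g must be >= 2, got {g}")
    if g > min_alleles:
        raise ValueError(f"g={g} exceeds the minimum usable allele count {min_alleles}")
    rows = []
    for pop in populations:
        n, b, _ = stats[pop]
        total = 2 * n
        counts = np.stack([b, total - b])
        ar = _rarefied_richness(counts, total, g)
        rows.append((pop, len(pop_idx[pop]), float(ar.mean())))
    frame = pd.DataFrame(rows, columns=["population_id", "n_samples", "A_R"])
    return DiversityTable(frame.set_index("population_id"), rarefaction_g=g)


def _wc_components(dataset: GenotypeDataset, pops: list[str]):
    """Weir & Cockerham (1984) per-locus variance components a, b, c.

    Returns arrays over loci usable in every population (n >= 1 and at
    least some data); loci with a zero total component are retained here and
    skipped by callers via the denominator.
    """
    pop_idx = dataset.population_indices()
    r = len(pops)
    ns, ps, hs = [], [], []
    for pop in pops:
        n, bcnt, het = _pop_counts(dataset, pop_idx[pop])
        ns.append(n.astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            ps.append(np.where(n > 0, bcnt / (2 * np.maximum(n, 1)), np.nan))
            hs.append(np.where(n > 0, het / np.maximum(n, 1), np.nan))
    n_i = np.stack(ns)      # (r, L)
    p_i = np.stack(ps)
    h_i = np.stack(hs)
    usable = (n_i >= 2).all(axis=0)
    n_i, p_i, h_i = n_i[:, usable], p_i[:, usable], h_i[:, usable]

    nbar = n_i.mean(axis=0)
    nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst(dataset: GenotypeDataset, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two populations.

    Ratio of averages: sum of among-population components over the sum of
    all components; loci where the total component is zero are skipped.
    Small negative values are a property of the estimator and are kept.
    """
    a, b, c = _wc_components(dataset, [pop_a, pop_b])
    tot = a + b + c
    use = tot != 0.0
    if not use.any():
        raise ValueError("no usable loci for FST")
    return float(a[use].sum() / tot[use].sum())


def fst_matrix(dataset: GenotypeDataset, populations: list[str] | None = None) -> FstMatrix:
    pops = populations or list(dataset.population_indices())
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = wc_fst(dataset, pops[i], pops[j])
    return FstMatrix(pops, vals)


def nei_distance(dataset: GenotypeDataset, pop_a: str, pop_b: str) -> float:
    """Nei's (1972) standard genetic distance D = -ln(J_xy / sqrt(J_x J_y)).

    The gene-identity terms J are sums over loci and alleles of sample
    allele-frequency products. Returns +inf (with a warning) when the
    between-population identity is zero; no silent clamping.
    """
    pop_idx = dataset.population_indices()
    out = []
    for pop in (pop_a, pop_b):
        n, b, _ = _pop_counts(dataset, pop_idx[pop])
        if (n < 1).any():
            raise ValueError(f"population {pop!r} missing data at some loci")
        p = b / (2 * n)
        out.append(np.stack([p, 1 - p]))
    px, py = out
    jx = float((px * px).sum())
    jy = float((py * py).sum())
    jxy = float((px * py).sum())
    if jxy == 0.0:
        warnings.warn("between-population gene identity is 0; Nei D is infinite", stacklevel=2)
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def nei_distance_matrix(dataset: GenotypeDataset, populations: list[str] | None = None) -> FstMatrix:
    """Pairwise Nei (1972) distances, packaged like an FstMatrix."""
    pops = populations or list(dataset.population_indices())
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = nei_distance(dataset, pops[i], pops[j])
    return FstMatrix(pops, vals)
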