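"""Genomic relationships and relatedness-based pruning.

Implements the frequency-standardized additive relationship matrix (the
GCTA/GREML "unified additive relationship" estimator), greedy pruning of
highly related pairs, and tree-based outlier flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass
class RelationshipMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric (n, n)
    snp_count_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t")


def uar_matrix(dataset: GenotypeDataset) -> RelationshipMatrix:
    """SNP-based additive relationship matrix.

    Off-diagonal: ``A_jk = mean_l (x_jl - 2p_l)(x_kl - 2p_l) / (2 p_l (1-p_l))``.
    Diagonal: ``A_jj = 1 + mean_l (x_jl^2 - (1+2p_l) x_jl + 2 p_l^2) / (2 p_l (1-p_l))``
    with ``p_l`` the sample allele-B frequency on non-missing entries. A SNP
    contributes to a pair only when both genotypes are present; each pair is
    averaged over its own usable-SNP count.
    """
    X = dataset.dosages.astype(float)
    obs = dataset.dosages != MISSING
    p = dataset.allele_b_freq()
    if np.any(np.isnan(p)) or np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError(
            "monomorphic or fully missing SNP encountered; apply MAF filtering first"
        )
    # centering check: sum of (x - 2p) over genotyped samples is 0 by construction
    centered = np.where(obs, X - 2 * p, 0.0)
    assert np.allclose(centered.sum(axis=0), 0.0, atol=1e-8)

    denom = 2 * p * (1 - p)
    Z = centered / np.sqrt(denom)  # off-diagonal contributions factorize
    A = Z @ Z.T
    counts = obs.astype(float) @ obs.astype(float).T
    if np.any(counts == 0):
        raise ValueError("a sample pair shares no genotyped SNPs")
    A /= counts

    diag_terms = np.where(obs, (X * X - (1 + 2 * p) * X + 2 * p * p) / denom, 0.0)
    n_obs = obs.sum(axis=1)
    np.fill_diagonal(A, 1.0 + diag_terms.sum(axis=1) / n_obs)
    return RelationshipMatrix(dataset.sample_ids, A, dataset.n_snps)


def prune_related(
    matrix: RelationshipMatrix,
    threshold: float = 0.25,
    call_rates: dict[str, float] | None = None,
) -> list[str]:
    """Greedy removal until no pair exceeds ``threshold``; returns kept ids.

    At each step the worst (largest-value) offending pair is examined and
    the member involved in more above-threshold pairs is removed; ties fall
    back to lower call rate, then to the later sample in input order.
    """
    A = matrix.values
    n = len(matrix.sample_ids)
    alive = np.ones(n, dtype=bool)
    rates = np.array(
        [1.0 if call_rates is None else call_rates.get(s, 1.0) for s in matrix.sample_ids]
    )
    mask = ~np.eye(n, dtype=bool)
    while True:
        over = (A > threshold) & mask & alive[:, None] & alive[None, :]
        if not over.any():
            break
        vals = np.where(over, A, -np.inf)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        i, j = min(i, j), max(i, j)
        deg_i, deg_j = over[i].sum(), over[j].sum()
        if deg_i != deg_j:
            drop = i if deg_i > deg_j else j
        elif rates[i] != rates[j]:
            drop = i if rates[i] < rates[j] else j
        else:
            drop = j  # later sample
        alive[drop] = False
    return [s for s, a in zip(matrix.sample_ids, alive) if a]


def detect_outliers(dataset: GenotypeDataset, k: float = 3.0) -> list[str]:
    """Flag samples with anomalously long terminal branches.

    Builds the 1-IBS distance matrix and its neighbor-joining tree, then
    flags any sample whose terminal branch exceeds ``k`` times the median
    terminal branch length of its own population. Populations with fewer
    than 3 members are skipped with a warning.
    """
    from .networks import neighbor_joining, terminal_branch_lengths
    from .structure import ibs_distance_matrix

    if dataset.n_samples < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    dist = ibs_distance_matrix(dataset)
    tree = neighbor_joining(dist, clamp_negative=True)
    lengths = terminal_branch_lengths(tree)

    flagged: list[str] = []
    for pop, idx in dataset.population_indices().items():
        members = [dataset.samples[i].sample_id for i in idx]
        if len(members) < 3:
            warnings.warn(f"population {pop!r} has < 3 members; skipped", stacklevel=2)
            continue
        med = float(np.median([lengths[m] for m in members]))
        for m in members:
            if lengths[m] > k * med:
                flagged.append(m)
    return flagged
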