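"""Maximum-likelihood admixture model fitted by EM.

The model: individual i carries ancestry proportions Q_i (simplex over K
ancestral populations) and ancestral population k has allele-B frequency
F_kl at locus l. Each dosage x_il ~ Binomial(2, sum_k Q_ik F_kl). EM updates
are exact and monotone in log-likelihood, reaching the same stationary
points as the block-relaxation solvers used for this model. Cluster labels
carry no inherent order; aligning them across runs is the consumer's task.

Cross-validation masks individual genotype entries, refits, and scores the
masked entries by squared deviation from their fitted expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

_EPS = 1e-6


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                # (n, K), rows on the simplex
    F: np.ndarray                # (K, L) in [eps, 1-eps]
    loglik_trace: list[float]
    converged: bool
    seed: int
    sample_ids: list[str] = field(default_factory=list)
    population_ids: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def q_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.Q, index=self.sample_ids, columns=[f"Q{k+1}" for k in range(self.K)]
        )
        if self.population_ids:
            frame.insert(0, "population_id", self.population_ids)
        return frame

    def to_tsv(self, sink) -> None:
        self.q_frame().to_csv(sink, sep="\t")


@dataclass
class CVResult:
    K: int
    folds: int
    cv_error: float
    per_fold: list[float]
    seed: int


def _masked_dosages(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    X = dataset.dosages.astype(float)
    obs = dataset.dosages != MISSING
    X[~obs] = 0.0
    return X, obs


def admixture_loglik(Q: np.ndarray, F: np.ndarray, dataset: GenotypeDataset) -> float:
    """Binomial log-likelihood of dosages under (Q, F); missing entries skipped."""
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("Q rows must lie on the simplex")
    X, obs = _masked_dosages(dataset)
    P = np.clip(Q @ F, _EPS, 1 - _EPS)
    ll = np.where(obs, X * np.log(P) + (2.0 - X) * np.log1p(-P), 0.0)
    return float(ll.sum())


def _em_fit(
    X: np.ndarray,
    obs: np.ndarray,
    K: int,
    seed: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    n, L = X.shape
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = rng.uniform(0.1, 0.9, size=(K, L))
    Xo = np.where(obs, X, 0.0)
    X2o = np.where(obs, 2.0 - X, 0.0)
    n_obs_per_sample = 2.0 * obs.sum(axis=1)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        P = np.clip(Q @ F, _EPS, 1 - _EPS)
        ll = float(np.where(obs, X * np.log(P) + (2.0 - X) * np.log1p(-P), 0.0).sum())
        trace.append(ll)
        if len(trace) > 1 and ll - trace[-2] < tol:
            converged = True
            break
        R1 = Xo / P          # expected B-allele copies per unit Q_ik F_kl
        R0 = X2o / (1.0 - P)
        newQ = np.empty_like(Q)
        newF = np.empty_like(F)
        for k in range(K):
            W = Q[:, k : k + 1] * F[k]      # (n, L)
            Ak = R1 * W                     # E[# B alleles from ancestry k]
            Bk = R0 * (Q[:, k : k + 1] * (1.0 - F[k]))
            sa, sb = Ak.sum(axis=0), Bk.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                newF[k] = np.where(sa + sb > 0, sa / np.maximum(sa + sb, 1e-300), F[k])
            newQ[:, k] = (Ak + Bk).sum(axis=1)
        Q = newQ / n_obs_per_sample[:, None]
        Q = np.clip(Q, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)
        assert np.all(np.abs(Q.sum(axis=1) - 1.0) < 1e-9)
        F = np.clip(newF, _EPS, 1 - _EPS)
    return Q, F, trace, converged


def fit_admixture(
    dataset: GenotypeDataset,
    K: int,
    seed: int,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """Fit the K-population admixture model by EM from a seeded random start."""
    if K < 1:
        raise ValueError("K must be >= 1")
    X, obs = _masked_dosages(dataset)
    p = dataset.allele_b_freq()
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic or all-missing locus; run QC (MAF filter) first")

    if K == 1:  # closed-form MLE
        F = np.clip(p[None, :], _EPS, 1 - _EPS)
        Q = np.ones((dataset.n_samples, 1))
        ll = float(
            np.where(obs, X * np.log(F[0]) + (2.0 - X) * np.log1p(-F[0]), 0.0).sum()
        )
        return AdmixtureFit(1, Q, F, [ll], True, seed,
                            dataset.sample_ids, dataset.population_ids)

    Q, F, trace, converged = _em_fit(X, obs, K, seed, max_iter, tol)
    return AdmixtureFit(K, Q, F, trace, converged, seed,
                        dataset.sample_ids, dataset.population_ids)


def cv_error(
    dataset: GenotypeDataset,
    K: int,
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> CVResult:
    """K-fold cross-validation error of the admixture model.

    Non-missing genotype entries are assigned to folds by the seeded RNG;
    each fold is masked (treated as missing during fitting) and scored by
    the mean squared deviation between the held-out dosage and its fitted
    expectation 2 * sum_k Q_ik F_kl.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, obs = _masked_dosages(dataset)
    rng = np.random.default_rng(seed)
    assignment = rng.integers(folds, size=X.shape)
    per_fold: list[float] = []
    for f in range(folds):
        mask = obs & (assignment == f)
        train_obs = obs & ~mask
        empty = ~train_obs.any(axis=0)
        if empty.any():
            warnings.warn(
                f"fold {f}: {int(empty.sum())} loci entirely masked; skipped in scoring",
                stacklevel=2,
            )
        if K == 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                F = np.where(train_obs, X, 0.0).sum(axis=0) / np.maximum(
                    2.0 * train_obs.sum(axis=0), 1e-300
                )
            F = np.clip(F[None, :], _EPS, 1 - _EPS)
            Q = np.ones((X.shape[0], 1))
        else:
            Q, F, _, _ = _em_fit(X, train_obs, K, seed * folds + f + 1, max_iter, tol)
        expect = 2.0 * (Q @ F)
        score_mask = mask & ~empty[None, :]
        dev = (X - expect) ** 2
        per_fold.append(float(dev[score_mask].mean()))
    return CVResult(K, folds, float(np.mean(per_fold)), per_fold, seed)


def k_sweep(
    dataset: GenotypeDataset,
    k_min: int,
    k_max: int,
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """CV error across a range of K; the argmin row marks the supported K."""
    rows = []
    for K in range(k_min, k_max + 1):
        res = cv_error(dataset, K, folds=folds, seed=seed, max_iter=max_iter, tol=tol)
        rows.append((K, res.cv_error))
    frame = pd.DataFrame(rows, columns=["K", "cv_error"])
    frame["best"] = frame["cv_error"] == frame["cv_error"].min()
    return frame


def align_labels(Q_hat: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Permute columns of Q_hat to best match Q_ref (exhaustive over K!)."""
    from itertools import permutations

    K = Q_hat.shape[1]
    best, best_err = None, np.inf
    for perm in permutations(range(K)):
        err = np.abs(Q_hat[:, perm] - Q_ref).mean()
        if err < best_err:
            best, best_err = perm, err
    return Q_hat[:, list(best)]
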