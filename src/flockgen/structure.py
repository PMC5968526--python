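"""Identical-by-state distances and classical (Torgerson) MDS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t")


@dataclass
class MDSResult:
    ids: list[str]
    coordinates: np.ndarray     # (n, d)
    eigenvalues: np.ndarray     # (d,)
    variance_fraction: np.ndarray

    def to_frame(self, population_ids: list[str] | None = None) -> pd.DataFrame:
        d = self.coordinates.shape[1]
        frame = pd.DataFrame(
            self.coordinates, index=self.ids, columns=[f"C{i+1}" for i in range(d)]
        )
        if population_ids is not None:
            frame.insert(0, "population_id", population_ids)
        return frame

    def to_tsv(self, sink, population_ids: list[str] | None = None) -> None:
        frame = self.to_frame(population_ids)
        fractions = ", ".join(f"C{i+1}={f:.6f}" for i, f in enumerate(self.variance_fraction))
        header = f"# variance fractions: {fractions}\n"
        if isinstance(sink, str):
            with open(sink, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t")
        else:
            sink.write(header)
            frame.to_csv(sink, sep="\t")


def ibs_distance_matrix(dataset: GenotypeDataset) -> DistanceMatrix:
    """Pairwise 1 - IBS allele-sharing distance.

    Per pair, IBS similarity at one locus is (2 - |x_i - x_j|)/2; the pair
    value is the mean over loci where both genotypes are present.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = dataset.dosages.astype(np.int16)
    obs = dataset.dosages != MISSING
    n = dataset.n_samples
    dist = np.zeros((n, n))
    for i in range(n - 1):
        both = obs[i] & obs[i + 1 :]
        counts = both.sum(axis=1)
        if np.any(counts == 0):
            j = i + 1 + int(np.where(counts == 0)[0][0])
            raise ValueError(
                f"samples {dataset.sample_ids[i]!r} and {dataset.sample_ids[j]!r} "
                "share no genotyped loci"
            )
        diff = np.abs(X[i] - X[i + 1 :]) * both
        sim = 1.0 - diff.sum(axis=1) / (2.0 * counts)
        dist[i, i + 1 :] = dist[i + 1 :, i] = 1.0 - sim
    return DistanceMatrix(dataset.sample_ids, dist)


def classical_mds(distances: DistanceMatrix, dims: int = 4) -> MDSResult:
    """Torgerson metric MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and embeds on the
    top ``dims`` positive eigenpairs. Variance fractions are eigenvalues over
    the sum of positive eigenvalues only (negative eigenvalues of
    non-Euclidean inputs are excluded from the denominator). The sign of
    each dimension is fixed so its largest-magnitude loading is positive.
    """
    n = len(distances.ids)
    if dims >= n:
        raise ValueError(f"dims={dims} must be < n={n}")
    D2 = distances.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(1.0, abs(evals[0]))
    if not pos.any():
        raise ValueError("degenerate distances: no positive eigenvalue")
    d = min(dims, int(pos.sum()))
    lam = evals[:d]
    coords = evecs[:, :d] * np.sqrt(lam)
    for k in range(d):  # deterministic sign
        m = np.argmax(np.abs(coords[:, k]))
        if coords[m, k] < 0:
            coords[:, k] = -coords[:, k]
    fractions = lam / evals[pos].sum()
    return MDSResult(distances.ids, coords, lam, fractions)
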