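"""LD-decay effective population size and the NeC change statistic.

The estimator inverts the drift-recombination expectation
``E[r2_adj] = 1 / (alpha + 4 Ne f(c))`` per distance bin, where ``c`` is the
genetic distance at the bin midpoint and ``alpha`` absorbs mutation
(default 2.2). A bin at genetic distance ``c`` Morgans reflects the
effective size about ``t = 1/(2c)`` generations ago, so with the default
1 cM/Mb conversion a 1 Mb marker distance maps to ~50 generations.

NeC ("Ne changing ratio") is the per-segment slope of the recent trajectory
normalized by the median Ne of the most recent estimates; its extreme
segments mark sudden demographic events such as bottlenecks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .qc import genotype_r2

logger = logging.getLogger(__name__)

#: Pluggable genetic-distance -> recombination-rate mappings.
#: identity is the default; haldane inverts the Haldane map function
#: (map distance -> recombination fraction).
MAPPINGS: dict[str, Callable[[float], float]] = {
    "identity": lambda c: c,
    "haldane": lambda c: 0.5 * (1.0 - np.exp(-2.0 * c)),
}


@dataclass
class LDBin:
    d_low: float            # bp
    d_high: float           # bp
    c_mid: float            # Morgans at the physical bin midpoint
    mean_r2_adj: float
    n_pairs: int

    def t(self, mapping: Callable[[float], float] = MAPPINGS["identity"]) -> float:
        return 1.0 / (2.0 * mapping(self.c_mid))


@dataclass
class NeTrajectory:
    label: str
    points: list[tuple[float, float]]   # (t generations, Ne), strictly increasing t
    alpha: float = 2.2

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.points]
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("trajectory t values must be strictly increasing")
        if any(ne <= 0 for _, ne in self.points):
            raise ValueError("Ne must be positive")

    def ne_at(self, t_target: float) -> float:
        """Ne at the point nearest t_target (the Ne5 / Ne50 convention)."""
        ts = np.array([t for t, _ in self.points])
        return self.points[int(np.argmin(np.abs(ts - t_target)))][1]

    @property
    def ne5(self) -> float:
        return self.ne_at(5.0)

    @property
    def ne50(self) -> float:
        return self.ne_at(50.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["t", "Ne"])

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, source, label: str = "", alpha: float = 2.2) -> "NeTrajectory":
        frame = pd.read_csv(source, sep="\t")
        return cls(label, list(zip(frame["t"], frame["Ne"])), alpha)


@dataclass
class NeCSeries:
    segments: list[tuple[float, float]]  # (t_mid, nec)
    window_median: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments, columns=["t_mid", "nec"])

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)


def default_bin_edges(d_min: float = 5e4, d_max: float = 1e7, n_bins: int = 30) -> np.ndarray:
    """Logarithmically spaced physical-distance bin edges (bp)."""
    return np.logspace(np.log10(d_min), np.log10(d_max), n_bins + 1)


def generation_for_distance(d_bp: float, cm_per_mb: float = 1.0) -> float:
    """Generations-before-present probed by a marker pair d_bp apart."""
    c = d_bp / 1e6 * cm_per_mb / 100.0
    return 1.0 / (2.0 * c)


def _pair_r2_complete(X: np.ndarray, pairs_i: np.ndarray, pairs_j: np.ndarray) -> np.ndarray:
    """Vectorized r^2 for pair lists on complete (no-missing) data."""
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Z / sd
    n = X.shape[0]
    r = np.einsum("ij,ij->j", Z[:, pairs_i], Z[:, pairs_j]) / n
    return r * r


def bin_pairwise_r2(
    dataset: GenotypeDataset,
    bin_edges: np.ndarray | None = None,
    cm_per_mb: float = 1.0,
    min_pairs: int = 30,
) -> list[LDBin]:
    """Mean adjusted r^2 per physical-distance bin (intra-chromosomal pairs).

    The small-sample adjustment is ``r2_adj = r2 - 1/n`` with ``n`` the
    pairwise-complete sample count. Bins with fewer than ``min_pairs``
    usable pairs are dropped.
    """
    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, dtype=float)
    nb = len(edges) - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)

    has_missing = bool(dataset.missing_mask().any())
    chrom_cols: dict[str, list[int]] = {}
    for j, snp in enumerate(dataset.snps):
        chrom_cols.setdefault(snp.chromosome, []).append(j)

    for cols in chrom_cols.values():
        cols = sorted(cols, key=lambda j: dataset.snps[j].position_bp)
        pos = np.array([dataset.snps[j].position_bp for j in cols], dtype=float)
        cols = np.array(cols)
        m = len(cols)
        if m < 2:
            continue
        # pair list limited to the maximum binned distance
        d_max = edges[-1]
        ii, jj, dd = [], [], []
        hi = np.searchsorted(pos, pos + d_max, side="right")
        for a in range(m - 1):
            b = np.arange(a + 1, hi[a])
            if b.size == 0:
                continue
            d = pos[b] - pos[a]
            sel = d >= edges[0]
            ii.append(np.full(sel.sum(), a))
            jj.append(b[sel])
            dd.append(d[sel])
        if not ii:
            continue
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        dd = np.concatenate(dd)
        which = np.digitize(dd, edges) - 1
        ok_bin = (which >= 0) & (which < nb)
        ii, jj, which = ii[ok_bin], jj[ok_bin], which[ok_bin]

        if not has_missing:
            X = dataset.dosages[:, cols].astype(float)
            sd0 = X.std(axis=0) == 0
            ok = ~(sd0[ii] | sd0[jj])
            r2 = _pair_r2_complete(X, ii[ok], jj[ok])
            adj = r2 - 1.0 / dataset.n_samples
            np.add.at(sums, which[ok], adj)
            np.add.at(counts, which[ok], 1)
        else:
            for a, b, w in zip(ii, jj, which):
                x = dataset.dosages[:, cols[a]]
                y = dataset.dosages[:, cols[b]]
                complete = (x != MISSING) & (y != MISSING)
                r2 = genotype_r2(x, y)
                if np.isnan(r2):
                    continue
                sums[w] += r2 - 1.0 / complete.sum()
                counts[w] += 1

    bins: list[LDBin] = []
    for k in range(nb):
        if counts[k] < min_pairs:
            continue
        mid_bp = 0.5 * (edges[k] + edges[k + 1])
        c_mid = mid_bp / 1e6 * cm_per_mb / 100.0
        bins.append(LDBin(edges[k], edges[k + 1], c_mid, sums[k] / counts[k], int(counts[k])))
    if not bins:
        raise ValueError("no distance bin reached min_pairs usable pairs")
    return bins


def pool_ld_bins(bin_lists: list[list[LDBin]]) -> list[LDBin]:
    """Pool LD bins from replicate chromosomes (pair-count-weighted means).

    Multiple chromosomes are simulated or analyzed as separate runs; their
    bins are merged here by physical bounds before Ne estimation.
    """
    by_edges: dict[tuple[float, float], list[LDBin]] = {}
    for bins in bin_lists:
        for b in bins:
            by_edges.setdefault((b.d_low, b.d_high), []).append(b)
    out = []
    for (lo, hi), group in sorted(by_edges.items()):
        n = sum(b.n_pairs for b in group)
        mean = sum(b.mean_r2_adj * b.n_pairs for b in group) / n
        out.append(LDBin(lo, hi, group[0].c_mid, mean, n))
    return out


def estimate_ne(
    bins: list[LDBin],
    alpha: float = 2.2,
    mapping: str | Callable[[float], float] = "identity",
    label: str = "",
) -> NeTrajectory:
    """Invert the LD expectation per bin: Ne = (1/(4 f(c))) (1/r2_adj - alpha).

    Bins whose mean adjusted r^2 implies a non-positive Ne are dropped with
    a log message.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not bins:
        raise ValueError("no LD bins supplied")
    f = MAPPINGS[mapping] if isinstance(mapping, str) else mapping
    points = []
    for b in bins:
        c = f(b.c_mid)
        if b.mean_r2_adj <= 0:
            logger.info("bin [%g, %g): non-positive adjusted r2, dropped", b.d_low, b.d_high)
            continue
        ne = (1.0 / (4.0 * c)) * (1.0 / b.mean_r2_adj - alpha)
        if ne <= 0:
            logger.info("bin [%g, %g): non-positive Ne estimate, dropped", b.d_low, b.d_high)
            continue
        points.append((1.0 / (2.0 * c), ne))
    points.sort(key=lambda p: p[0])
    return NeTrajectory(label, points, alpha)


def nec_series(trajectory: NeTrajectory, window: int = 20) -> NeCSeries:
    """Normalized slopes over the ``window`` most recent Ne estimates.

    For neighboring points ordered by increasing t,
    ``nec_i = (Ne_{i+1} - Ne_i) / (t_{i+1} - t_i) / median(Ne in window)``.
    Positive values mean Ne was larger further in the past, i.e. a decline
    toward the present.
    """
    pts = sorted(trajectory.points, key=lambda p: p[0])
    if len(pts) < 2:
        raise ValueError("need at least 2 trajectory points")
    ts = [t for t, _ in pts]
    if len(set(ts)) != len(ts):
        raise ValueError("duplicate t values in trajectory")
    recent = pts[: min(window, len(pts))]
    med = float(np.median([ne for _, ne in recent]))
    segments = []
    for (t1, n1), (t2, n2) in zip(recent, recent[1:]):
        slope = (n2 - n1) / (t2 - t1)
        segments.append(((t1 + t2) / 2.0, slope / med))
    return NeCSeries(segments, med)


def nec_peaks(series: NeCSeries, min_abs: float = 0.0) -> list[tuple[float, float]]:
    """Segments ranked by |nec| descending; ties -> earlier generation first."""
    if not series.segments:
        raise ValueError("empty NeC series")
    picked = [(t, v) for t, v in series.segments if abs(v) >= min_abs]
    return sorted(picked, key=lambda s: (-abs(s[1]), s[0]))


def ne_for_population(
    dataset: GenotypeDataset,
    population_id: str,
    alpha: float = 2.2,
    cm_per_mb: float = 1.0,
    bin_edges: np.ndarray | None = None,
    min_pairs: int = 30,
    mapping: str | Callable[[float], float] = "identity",
) -> NeTrajectory:
    """Within-breed Ne trajectory: subset one population, bin LD, invert."""
    sub = dataset.select_population(population_id)
    bins = bin_pairwise_r2(sub, bin_edges=bin_edges, cm_per_mb=cm_per_mb, min_pairs=min_pairs)
    return estimate_ne(bins, alpha=alpha, mapping=mapping, label=population_id)
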