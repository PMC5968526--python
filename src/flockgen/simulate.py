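"""Synthetic genotype generators.

Two complementary models:

* Balding-Nichols: K drift-structured populations whose allele frequencies
  are Beta-distributed around shared ancestral frequencies with a
  per-population differentiation parameter F, plus optional admixed
  individuals. This is the structure the FST / MDS / admixture stages assume.
* Forward Wright-Fisher: one recombining chromosome evolved through discrete
  generations under an arbitrary Ne(t) schedule (Haldane crossover model,
  selfing allowed), the regime the LD-based Ne estimator targets -
  including abrupt recent bottlenecks at controllable generations.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import GenotypeDataset, SampleRecord, SNPRecord
from .io import write_plink_text


@dataclass
class BNConfig:
    n_pops: int = 2
    fst_targets: tuple[float, ...] = (0.1, 0.1)
    n_per_pop: int = 50
    L: int = 1000
    admixture: float | np.ndarray | None = None  # Dirichlet conc. or explicit Q
    n_admixed: int = 0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    chromosome: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fst_targets) != self.n_pops:
            raise ValueError("need one fst target per population")
        if any(not 0.0 <= f < 1.0 for f in self.fst_targets):
            raise ValueError("fst targets must be in [0,1)")
        if min(self.n_pops, self.n_per_pop, self.L) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class WFConfig:
    ne_schedule: tuple[tuple[int, int], ...] = ((0, 100),)  # (gen before present, N)
    chrom_length_morgans: float = 1.0
    L: int = 1000
    n_sampled: int = 50
    generations: int = 100
    mutation_rate: float | None = None
    init_freq: float | None = None  # None -> uniform(0.05, 0.95) per locus
    cm_per_mb: float = 1.0
    population_id: str = "WF"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(N < 2 for _, N in self.ne_schedule):
            raise ValueError("N must be >= 2 everywhere")
        if self.chrom_length_morgans < 0:
            raise ValueError("chromosome length must be >= 0")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    def n_at(self, gen_before_present: int) -> int:
        """Piecewise-constant N(t): each (g, N) entry applies to all
        generations <= g until a more recent entry takes over; the oldest
        entry extends back to the start of the simulation."""
        candidates = [(g, N) for g, N in self.ne_schedule if g >= gen_before_present]
        if candidates:
            return min(candidates)[1]
        return max(self.ne_schedule)[1]


@dataclass
class SimTruth:
    kind: str
    Q: np.ndarray | None = None
    pop_freqs: np.ndarray | None = None
    ne_schedule: tuple[tuple[int, int], ...] | None = None
    meta: dict = field(default_factory=dict)


def _make_snps(L: int, chromosome: str, positions_bp: np.ndarray,
               gen_pos: np.ndarray | None = None) -> list[SNPRecord]:
    return [
        SNPRecord(
            snp_id=f"snp{j:06d}",
            chromosome=chromosome,
            position_bp=int(positions_bp[j]),
            allele_a="A",
            allele_b="G",
            genetic_pos_morgans=None if gen_pos is None else float(gen_pos[j]),
        )
        for j in range(L)
    ]


def simulate_balding_nichols(config: BNConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Drift-structured populations, optionally with admixed individuals.

    Population k's frequency at locus l is Beta(p(1-F)/F, (1-p)(1-F)/F)
    around the ancestral p; F = 0 degenerates to p itself. Unadmixed
    dosages are Binomial(2, p_kl); admixed dosages use the Q-weighted
    frequency.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.L)
    pop_freqs = np.empty((config.n_pops, config.L))
    for k, F in enumerate(config.fst_targets):
        if F == 0.0:
            pop_freqs[k] = p_anc
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            pop_freqs[k] = rng.beta(a, b)

    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    q_rows: list[np.ndarray] = []
    for k in range(config.n_pops):
        for i in range(config.n_per_pop):
            samples.append(SampleRecord(f"P{k+1}_{i:03d}", f"POP{k+1}"))
            rows.append(rng.binomial(2, pop_freqs[k]))
            q = np.zeros(config.n_pops)
            q[k] = 1.0
            q_rows.append(q)

    if config.n_admixed:
        if isinstance(config.admixture, np.ndarray):
            Qadm = np.asarray(config.admixture, dtype=float)
            if Qadm.shape != (config.n_admixed, config.n_pops):
                raise ValueError("explicit Q must be (n_admixed, n_pops)")
        else:
            conc = 1.0 if config.admixture is None else float(config.admixture)
            Qadm = rng.dirichlet(np.full(config.n_pops, conc), size=config.n_admixed)
        for i, q in enumerate(Qadm):
            samples.append(SampleRecord(f"ADM_{i:03d}", "ADMIX"))
            rows.append(rng.binomial(2, q @ pop_freqs))
            q_rows.append(q)

    positions = (1 + np.arange(config.L)) * 10_000
    dataset = GenotypeDataset(
        samples,
        _make_snps(config.L, config.chromosome, positions),
        np.stack(rows).astype(np.int8),
    )
    truth = SimTruth("balding_nichols", Q=np.stack(q_rows), pop_freqs=pop_freqs,
                     meta={"fst_targets": list(config.fst_targets)})
    return dataset, truth


def _recombine(h0: np.ndarray, h1: np.ndarray, loci_pos: np.ndarray,
               chrom_len: float, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent under the Haldane crossover model."""
    start = rng.integers(2)
    n_x = rng.poisson(chrom_len)
    if n_x == 0:
        return h0 if start == 0 else h1
    xpos = np.sort(rng.uniform(0.0, chrom_len, size=n_x))
    parity = (start + np.searchsorted(xpos, loci_pos)) % 2
    return np.where(parity == 0, h0, h1)


def simulate_wright_fisher(config: WFConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Forward Wright-Fisher chromosome under an Ne(t) schedule.

    Discrete non-overlapping generations; each offspring draws two parents
    uniformly (selfing allowed) from the generation-specific N; gametes
    recombine with Poisson(chromosome length in Morgans) crossovers at
    uniform positions. Loci monomorphic at sampling time are dropped.
    Physical positions come from the genetic map at ``cm_per_mb``.
    """
    rng = np.random.default_rng(config.seed)
    loci_pos = np.sort(rng.uniform(0.0, max(config.chrom_length_morgans, 1e-12), size=config.L))
    if config.init_freq is None:
        p0 = rng.uniform(0.05, 0.95, size=config.L)
    else:
        p0 = np.full(config.L, float(config.init_freq))

    N0 = config.n_at(config.generations)
    haps = (rng.random((N0, 2, config.L)) < p0).astype(np.int8)

    for gen_bp in range(config.generations - 1, -1, -1):
        N_new = config.n_at(gen_bp)
        N_prev = haps.shape[0]
        parents = rng.integers(N_prev, size=(N_new, 2))
        new = np.empty((N_new, 2, config.L), dtype=np.int8)
        for i in range(N_new):
            for g in range(2):
                p = parents[i, g]
                new[i, g] = _recombine(haps[p, 0], haps[p, 1], loci_pos,
                                       config.chrom_length_morgans, rng)
        if config.mutation_rate:
            flips = rng.random(new.shape) < config.mutation_rate
            new ^= flips.astype(np.int8)
        haps = new

    if config.n_sampled > haps.shape[0]:
        raise ValueError(
            f"n_sampled={config.n_sampled} exceeds final population size {haps.shape[0]}"
        )
    take = rng.choice(haps.shape[0], size=config.n_sampled, replace=False)
    dosages = haps[take].sum(axis=1)
    freqs = dosages.mean(axis=0) / 2.0
    poly = (freqs > 0) & (freqs < 1)
    dosages = dosages[:, poly]
    pos_m = loci_pos[poly]
    if not poly.any():
        raise ValueError("all loci monomorphic at sampling time")

    positions_bp = np.round(pos_m * 100.0 / config.cm_per_mb * 1e6).astype(np.int64)
    # enforce strictly increasing physical positions after rounding
    positions_bp = np.maximum.accumulate(positions_bp + np.arange(len(positions_bp)))
    samples = [
        SampleRecord(f"{config.population_id}_{i:03d}", config.population_id)
        for i in range(config.n_sampled)
    ]
    dataset = GenotypeDataset(
        samples,
        _make_snps(int(poly.sum()), "1", positions_bp, gen_pos=pos_m),
        dosages.astype(np.int8),
    )
    truth = SimTruth("wright_fisher", ne_schedule=config.ne_schedule,
                     meta={"n_loci_segregating": int(poly.sum()),
                           "chrom_length_morgans": config.chrom_length_morgans})
    return dataset, truth


def make_fixture_suite(out_dir: str | Path, seed: int = 0, force: bool = False) -> dict:
    """Write the small PED/MAP fixtures used across the test-suite.

    Contents: a QC toy (one sub-threshold-MAF SNP, one high-missingness
    sample), a merge toy pair, a two-population Balding-Nichols set, and a
    Wright-Fisher bottleneck set, plus a JSON manifest of the ground truths.
    Byte-stable for a given seed.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "fixtures": {}}

    def emit(name: str, dataset: GenotypeDataset, truth: dict) -> None:
        write_plink_text(dataset, out / f"{name}.ped", out / f"{name}.map")
        manifest["fixtures"][name] = truth

    # QC toy: 6 samples x 5 SNPs, planted MAF failure and missingness failure
    rng = np.random.default_rng(seed)
    dos = rng.integers(0, 3, size=(6, 5)).astype(np.int8)
    dos[:, 1] = [1, 1, 1, 1, 1, 1]        # guaranteed polymorphic elsewhere
    dos[:, 2] = [0, 0, 0, 0, 0, 1]        # MAF = 1/12 < 0.05? no: plant harder
    dos[:, 2] = 0
    dos[5, 2] = 1                          # MAF = 1/12 ~ 0.083 -> keep
    dos[:, 3] = 0                          # monomorphic -> MAF 0 < 0.05
    dos[0, :4] = -1                        # sample 0: 80% missing
    samples = [SampleRecord(f"S{i}", "TOY") for i in range(6)]
    snps = _make_snps(5, "1", (1 + np.arange(5)) * 100_000)
    emit("qc_toy", GenotypeDataset(samples, snps, dos),
         {"low_maf_snp": "snp000003", "high_missing_sample": "S0"})

    # merge toy: shared SNPs with swapped coding / ambiguous pair
    base = GenotypeDataset(
        [SampleRecord("L1", "LOC"), SampleRecord("L2", "LOC")],
        [
            SNPRecord("m1", "1", 1000, "A", "G"),
            SNPRecord("m2", "1", 2000, "A", "T"),
            SNPRecord("m3", "1", 3000, "C", "A"),
        ],
        np.array([[0, 1, 2], [1, 1, 0]], dtype=np.int8),
    )
    other = GenotypeDataset(
        [SampleRecord("E1", "EXT"), SampleRecord("E2", "EXT")],
        [
            SNPRecord("m1", "1", 1000, "G", "A"),
            SNPRecord("m2", "1", 2000, "T", "A"),
            SNPRecord("m3", "1", 3000, "A", "C"),
        ],
        np.array([[2, 0, 1], [0, 2, 2]], dtype=np.int8),
    )
    emit("merge_local", base, {"ambiguous_snp": "m2"})
    emit("merge_external", other, {"ambiguous_snp": "m2"})

    # two-population Balding-Nichols set
    bn_cfg = BNConfig(n_pops=2, fst_targets=(0.1, 0.1), n_per_pop=30, L=400,
                      seed=seed + 1)
    bn, bn_truth = simulate_balding_nichols(bn_cfg)
    emit("bn_two_pop", bn, {"fst_targets": [0.1, 0.1], "n_per_pop": 30, "L": 400})

    # Wright-Fisher bottleneck set (N 200 -> 60 at generation 8)
    wf_cfg = WFConfig(ne_schedule=((9, 200), (8, 60)), chrom_length_morgans=1.0,
                      L=600, n_sampled=40, generations=60, seed=seed + 2)
    wf, wf_truth = simulate_wright_fisher(wf_cfg)
    emit("wf_bottleneck", wf, {"ne_schedule": [[9, 200], [8, 60]], "generations": 60})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
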