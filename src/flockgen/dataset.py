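"""Core genotype container shared by every stage of the pipeline.

A :class:`GenotypeDataset` holds a samples x SNPs matrix of allele-B dosages
(0, 1, 2 copies) for diploid biallelic markers, plus per-SNP and per-sample
metadata. Missing genotypes use the dedicated sentinel :data:`MISSING`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Sentinel dosage code for a missing genotype. Kept out of arithmetic by
#: masking, never treated as a numeric value.
MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP on a physical map.

    ``allele_b`` is the allele counted by the dosage matrix (minor allele at
    load time by convention; downstream statistics recompute frequencies on
    the current sample subset so the choice is arbitrary).
    """

    snp_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str
    genetic_pos_morgans: float | None = None

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"negative position for {self.snp_id}")
        if self.allele_a not in _VALID_ALLELES or self.allele_b not in _VALID_ALLELES:
            raise ValueError(
                f"SNP {self.snp_id}: alleles must be A/C/G/T, got "
                f"{self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")
        if not self.chromosome:
            raise ValueError(f"SNP {self.snp_id}: empty chromosome label")
        if self.genetic_pos_morgans is not None and self.genetic_pos_morgans < 0:
            raise ValueError(f"SNP {self.snp_id}: negative genetic position")


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual with its breed/population label."""

    sample_id: str
    population_id: str
    call_rate: float = 1.0


class GenotypeDataset:
    """Samples x SNPs dosage matrix with metadata.

    Parameters
    ----------
    samples
        Ordered sample records; ``sample_id`` must be unique.
    snps
        Ordered SNP records; ``snp_id`` must be unique.
    dosages
        ``(n_samples, n_snps)`` integer matrix with entries in
        ``{0, 1, 2, MISSING}`` counting copies of each SNP's ``allele_b``.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        snps: Sequence[SNPRecord],
        dosages: np.ndarray,
    ) -> None:
        samples = list(samples)
        snps = list(snps)
        dosages = np.asarray(dosages, dtype=np.int8)
        if len(samples) < 1 or len(snps) < 1:
            raise ValueError("dataset needs at least 1 sample and 1 SNP")
        if dosages.shape != (len(samples), len(snps)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        legal = (dosages == MISSING) | ((dosages >= 0) & (dosages <= 2))
        if not legal.all():
            bad = np.argwhere(~legal)[0]
            raise ValueError(
                f"illegal dosage code {dosages[tuple(bad)]} at sample "
                f"{samples[bad[0]].sample_id}, SNP {snps[bad[1]].snp_id}"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        sids = [s.snp_id for s in snps]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate snp_id")
        self.samples = samples
        self.snps = snps
        self.dosages = dosages
        # refresh derived call rates so SampleRecord.call_rate is trustworthy
        rates = self.sample_call_rates()
        self.samples = [replace(s, call_rate=float(r)) for s, r in zip(samples, rates)]

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def population_ids(self) -> list[str]:
        return [s.population_id for s in self.samples]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    # -- derived statistics ------------------------------------------------
    def allele_b_freq(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP allele-B frequency on non-missing entries.

        Returns NaN for SNPs with no genotyped sample in the subset.
        """
        x = self.dosages if sample_index is None else self.dosages[sample_index]
        obs = x != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(obs, x, 0).sum(axis=0) / n_alleles

    def maf(self, sample_index: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_b_freq(sample_index)
        return np.minimum(p, 1.0 - p)

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    # -- subsetting --------------------------------------------------------
    def subset(
        self,
        sample_index: Iterable[int] | None = None,
        snp_index: Iterable[int] | None = None,
    ) -> "GenotypeDataset":
        si = np.arange(self.n_samples) if sample_index is None else np.asarray(list(sample_index))
        ci = np.arange(self.n_snps) if snp_index is None else np.asarray(list(snp_index))
        return GenotypeDataset(
            [self.samples[i] for i in si],
            [self.snps[j] for j in ci],
            self.dosages[np.ix_(si, ci)],
        )

    def select_samples(self, ids: Iterable[str]) -> "GenotypeDataset":
        wanted = set(ids)
        idx = [i for i, s in enumerate(self.samples) if s.sample_id in wanted]
        return self.subset(sample_index=idx)

    def select_snps(self, ids: Iterable[str]) -> "GenotypeDataset":
        wanted = set(ids)
        idx = [j for j, s in enumerate(self.snps) if s.snp_id in wanted]
        return self.subset(snp_index=idx)

    def select_population(self, population_id: str) -> "GenotypeDataset":
        idx = [i for i, s in enumerate(self.samples) if s.population_id == population_id]
        if not idx:
            raise KeyError(f"no samples with population_id {population_id!r}")
        return self.subset(sample_index=idx)

    def population_indices(self) -> dict[str, np.ndarray]:
        """Map population_id -> sample row indices, in first-seen order."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.population_id, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}

    def drop_monomorphic(self) -> "GenotypeDataset":
        """Drop SNPs fixed (or fully missing) in the current sample set."""
        p = self.allele_b_freq()
        keep = np.where(~np.isnan(p) & (p > 0) & (p < 1))[0]
        if keep.size == 0:
            raise ValueError("all SNPs monomorphic")
        return self.subset(snp_index=keep)

    def sort_by_map(self) -> "GenotypeDataset":
        """Return a copy sorted by (chromosome, position); chromosome labels
        compare numerically when they are integers."""

        def chrom_key(c: str):
            return (0, int(c), "") if c.isdigit() else (1, 0, c)

        order = sorted(
            range(self.n_snps),
            key=lambda j: (chrom_key(self.snps[j].chromosome), self.snps[j].position_bp),
        )
        return self.subset(snp_index=order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.snps == other.snps
            and [
                (s.sample_id, s.population_id) for s in self.samples
            ] == [(s.sample_id, s.population_id) for s in other.samples]
            and np.array_equal(self.dosages, other.dosages)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        pops = len(set(self.population_ids))
        return (
            f"<GenotypeDataset {self.n_samples} samples / {pops} populations "
            f"x {self.n_snps} SNPs>"
        )


def validate_autosome(chromosome: str, max_autosome: int = 26) -> bool:
    """True when ``chromosome`` is an autosome label ("1".."26" for sheep)."""
    return chromosome.isdigit() and 1 <= int(chromosome) <= max_autosome
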