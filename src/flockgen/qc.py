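"""SNP and sample quality control.

The cascade mirrors standard SNP-array practice: genotype-score masking,
autosome restriction, sample call-rate, SNP call-rate, MAF, an exact
Hardy-Weinberg test, and sliding-window LD pruning. Filter order is fixed
(genotype-level -> sample-level -> SNP-level -> LD) so removal counts are
reproducible; per-step rates are always recomputed on the current data,
never cached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, validate_autosome


@dataclass
class QCConfig:
    """Thresholds for the QC cascade (defaults follow common 50K-chip use)."""

    gc_min: float = 0.5
    gt_min: float = 0.5
    snp_call_rate_min: float = 0.9
    maf_min: float = 0.05
    hwe_alpha: float = 1e-6
    hwe_enabled: bool = True
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.5
    sample_call_rate_min: float = 0.9
    autosomes_only: bool = True
    max_autosome: int = 26

    def __post_init__(self) -> None:
        for name in ("gc_min", "gt_min", "snp_call_rate_min", "maf_min",
                     "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (self.ld_window_snps > self.ld_step_snps > 0):
            raise ValueError("need ld_window_snps > ld_step_snps > 0")


@dataclass
class QCReport:
    """Ordered (filter_name, removed, remaining) triples for each step."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int) -> None:
        self.steps.append((name, int(removed), int(remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "items_removed", "items_remaining"])

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability
    ``P(n_Aa | n, n_A) ∝ n! 2^{n_Aa} / (n_AA! n_Aa! n_aa!)`` does not exceed
    that of the observed count (the standard two-sided tail).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)

    # admissible heterozygote counts share the parity of the rare-allele count
    hets = range(rare % 2, rare + 1, 2)
    logprobs = []
    for h in hets:
        hom_rare = (rare - h) // 2
        hom_common = (max(n_A, n_a) - h) // 2
        lp = (
            h * math.log(2.0)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
        )
        logprobs.append(lp)
    logprobs = np.array(logprobs)
    probs = np.exp(logprobs - logprobs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on pairwise-complete entries; returns NaN (the flagged
    undefined value callers must skip) when either vector is constant on
    those entries or fewer than 2 complete pairs exist.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    xv -= xv.mean()
    yv -= yv.mean()
    den = (xv @ xv) * (yv @ yv)
    if den == 0.0:
        return float("nan")
    r = (xv @ yv) / math.sqrt(den)
    return float(r * r)


def ld_prune(dataset: GenotypeDataset, config: QCConfig | None = None) -> list[str]:
    """PLINK-style ``--indep-pairwise`` pruning; returns kept snp_ids.

    Within each window of ``ld_window_snps`` SNPs (advanced by
    ``ld_step_snps``), while any kept pair has r^2 above ``ld_r2_max`` the
    member with the smaller MAF is removed (tie: the SNP later in map
    order). Pairs are scanned in map order, so the pass is deterministic.
    """
    config = config or QCConfig()
    maf = dataset.maf()
    keep = np.ones(dataset.n_snps, dtype=bool)
    chroms: dict[str, list[int]] = {}
    for j, snp in enumerate(dataset.snps):
        chroms.setdefault(snp.chromosome, []).append(j)
    for idx in chroms.values():
        n = len(idx)
        for start in range(0, n, config.ld_step_snps):
            window = idx[start:start + config.ld_window_snps]
            changed = True
            while changed:
                changed = False
                kept = [j for j in window if keep[j]]
                for a in range(len(kept)):
                    for b in range(a + 1, len(kept)):
                        ja, jb = kept[a], kept[b]
                        r2 = genotype_r2(dataset.dosages[:, ja], dataset.dosages[:, jb])
                        if np.isnan(r2) or r2 <= config.ld_r2_max:
                            continue
                        if maf[ja] < maf[jb]:
                            keep[ja] = False
                        else:  # equal MAF -> later SNP removed
                            keep[jb] = False
                        changed = True
                        break
                    if changed:
                        break
            if start + config.ld_window_snps >= n:
                break
    return [s.snp_id for j, s in enumerate(dataset.snps) if keep[j]]


def apply_qc(
    dataset: GenotypeDataset,
    config: QCConfig | None = None,
    scores: pd.DataFrame | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full QC cascade and record each step.

    ``scores``, when given, is a long table with columns
    ``sample_id, snp_id, gc, gt``; genotypes scoring below either cut-off
    are set to missing before any filter runs.
    """
    config = config or QCConfig()
    report = QCReport()
    ds = dataset

    # (1) genotype-score masking
    masked = 0
    if scores is not None:
        dosages = ds.dosages.copy()
        srow = {s: i for i, s in enumerate(ds.sample_ids)}
        scol = {s: j for j, s in enumerate(ds.snp_ids)}
        for rec in scores.itertuples(index=False):
            i = srow.get(rec.sample_id)
            j = scol.get(rec.snp_id)
            if i is None or j is None:
                continue
            if (rec.gc < config.gc_min or rec.gt < config.gt_min) and dosages[i, j] != MISSING:
                dosages[i, j] = MISSING
                masked += 1
        ds = GenotypeDataset(ds.samples, ds.snps, dosages)
    report.add("genotype_scores", masked, int((ds.dosages != MISSING).sum()))

    # (2) autosomes only
    if config.autosomes_only:
        keep = [j for j, s in enumerate(ds.snps)
                if validate_autosome(s.chromosome, config.max_autosome)]
        report.add("autosomes", ds.n_snps - len(keep), len(keep))
        if not keep:
            raise ValueError("QC emptied dataset (no autosomal SNPs)")
        ds = ds.subset(snp_index=keep)
    else:
        report.add("autosomes", 0, ds.n_snps)

    # (3) sample call rate
    rates = ds.sample_call_rates()
    keep_s = np.where(rates >= config.sample_call_rate_min)[0]
    report.add("sample_call_rate", ds.n_samples - len(keep_s), len(keep_s))
    if len(keep_s) == 0:
        raise ValueError("QC emptied dataset (all samples below call rate)")
    ds = ds.subset(sample_index=keep_s)

    # (4) SNP call rate
    keep = np.where(ds.snp_call_rates() >= config.snp_call_rate_min)[0]
    report.add("snp_call_rate", ds.n_snps - len(keep), len(keep))
    if len(keep) == 0:
        raise ValueError("QC emptied dataset (all SNPs below call rate)")
    ds = ds.subset(snp_index=keep)

    # (5) MAF
    keep = np.where(np.nan_to_num(ds.maf()) >= config.maf_min)[0]
    report.add("maf", ds.n_snps - len(keep), len(keep))
    if len(keep) == 0:
        raise ValueError("QC emptied dataset (all SNPs below MAF)")
    ds = ds.subset(snp_index=keep)

    # (6) HWE on the pooled sample
    if config.hwe_enabled:
        keep = []
        for j in range(ds.n_snps):
            col = ds.dosages[:, j]
            obs = col != MISSING
            n_bb = int((col[obs] == 2).sum())
            n_ab = int((col[obs] == 1).sum())
            n_aa = int((col[obs] == 0).sum())
            if hwe_exact_test(n_aa, n_ab, n_bb) >= config.hwe_alpha:
                keep.append(j)
        report.add("hwe", ds.n_snps - len(keep), len(keep))
        if not keep:
            raise ValueError("QC emptied dataset (all SNPs fail HWE)")
        ds = ds.subset(snp_index=keep)
    else:
        report.add("hwe", 0, ds.n_snps)

    # (7) LD pruning
    kept_ids = set(ld_prune(ds, config))
    keep = [j for j, s in enumerate(ds.snps) if s.snp_id in kept_ids]
    report.add("ld_prune", ds.n_snps - len(keep), len(keep))
    ds = ds.subset(snp_index=keep)

    return ds, report
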