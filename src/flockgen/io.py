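"""PLINK text (PED/MAP) reading, writing, and dataset merging.

The PED dialect is the classic 6-column-header one: FID IID PAT MAT SEX
PHENO followed by two allele columns per SNP. Alleles may be coded A/C/G/T
or 1/2 (1->A, 2->B placeholder bases); "0" marks a missing allele. The MAP
file is CHR SNP_ID CM BP.

Merging intersects SNP sets, reconciles allele codings (swapped REF/ALT ->
dosage recode x -> 2-x; opposite-strand codings -> complemented), drops
strand-ambiguous (A/T, C/G) and irreconcilable markers, and reports every
drop.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, SampleRecord, SNPRecord

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# numeric PLINK codings are mapped onto placeholder bases
_NUMERIC_ALLELES = {"1": "A", "2": "C"}


class PlinkParseError(ValueError):
    """Malformed PED/MAP content."""


def _open(source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def _read_map(map_source) -> list[tuple[str, str, float, int]]:
    fh, close = _open(map_source, "r")
    try:
        rows = []
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkParseError(f"MAP line {ln}: expected 4 fields, got {len(parts)}")
            chrom, snp_id, cm, bp = parts
            rows.append((chrom, snp_id, float(cm), int(bp)))
        return rows
    finally:
        if close:
            fh.close()


def read_plink_text(ped_source, map_source) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Allele B of each SNP is the minor allele as observed in this file; the
    PED family-ID column becomes the sample's ``population_id``.
    """
    map_rows = _read_map(map_source)
    n_snps = len(map_rows)
    if n_snps == 0:
        raise PlinkParseError("MAP file contains no SNPs")

    fh, close = _open(ped_source, "r")
    try:
        samples: list[SampleRecord] = []
        allele_rows: list[np.ndarray] = []
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PlinkParseError(f"PED line {ln}: fewer than 6 header fields")
            geno = parts[6:]
            if len(geno) % 2 == 1:
                raise PlinkParseError(f"PED line {ln}: odd allele count ({len(geno)})")
            if len(geno) != 2 * n_snps:
                raise PlinkParseError(
                    f"PED line {ln}: {len(geno) // 2} genotypes but MAP lists {n_snps} SNPs"
                )
            coded = []
            for a in geno:
                a = _NUMERIC_ALLELES.get(a, a)
                if a == "0":
                    coded.append("")
                elif a in _COMPLEMENT:
                    coded.append(a)
                else:
                    raise PlinkParseError(f"PED line {ln}: unknown allele symbol {a!r}")
            samples.append(SampleRecord(sample_id=parts[1], population_id=parts[0]))
            allele_rows.append(np.array(coded, dtype="U1").reshape(n_snps, 2))
    finally:
        if close:
            fh.close()
    if not samples:
        raise PlinkParseError("PED file contains no samples")

    alleles = np.stack(allele_rows)  # (n_samples, n_snps, 2)
    snps: list[SNPRecord] = []
    dosages = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, cm, bp) in enumerate(map_rows):
        col = alleles[:, j, :]
        observed = sorted({a for a in col.ravel() if a})
        if len(observed) > 2:
            raise PlinkParseError(f"SNP {snp_id}: more than two alleles {observed}")
        if not observed:
            observed = ["A", "C"]  # fully missing column: arbitrary legal pair
        if len(observed) == 1:
            # monomorphic column: pick a non-complementary partner allele
            observed = [observed[0], "C" if observed[0] != "C" else "A"]
        a1, a2 = observed
        nonmiss = col[:, 0] != ""
        count2 = (col == a2).sum(axis=1)
        # allele_b = minor allele at first read
        if nonmiss.any() and count2[nonmiss].sum() > nonmiss.sum():
            a1, a2 = a2, a1
            count2 = (col == a2).sum(axis=1)
        dosages[nonmiss, j] = count2[nonmiss]
        snps.append(
            SNPRecord(
                snp_id=snp_id,
                chromosome=chrom,
                position_bp=bp,
                allele_a=a1,
                allele_b=a2,
                genetic_pos_morgans=cm / 100.0 if cm > 0 else None,
            )
        )
    return GenotypeDataset(samples, snps, dosages)


def write_plink_text(dataset: GenotypeDataset, ped_sink, map_sink) -> None:
    """Serialize to PED/MAP text; missing genotypes become ``0 0``."""
    fh, close = _open(map_sink, "w")
    try:
        for snp in dataset.snps:
            cm = 0.0 if snp.genetic_pos_morgans is None else snp.genetic_pos_morgans * 100.0
            fh.write(f"{snp.chromosome}\t{snp.snp_id}\t{cm:g}\t{snp.position_bp}\n")
    finally:
        if close:
            fh.close()

    fh, close = _open(ped_sink, "w")
    try:
        for i, sample in enumerate(dataset.samples):
            fields = [sample.population_id, sample.sample_id, "0", "0", "0", "-9"]
            row = dataset.dosages[i]
            for j, snp in enumerate(dataset.snps):
                x = row[j]
                if x == MISSING:
                    fields += ["0", "0"]
                elif x == 0:
                    fields += [snp.allele_a, snp.allele_a]
                elif x == 1:
                    fields += [snp.allele_a, snp.allele_b]
                else:
                    fields += [snp.allele_b, snp.allele_b]
            fh.write(" ".join(fields) + "\n")
    finally:
        if close:
            fh.close()


@dataclass
class MergeReport:
    """Per-SNP record of merge decisions."""

    rows: list[tuple[str, str, str]]  # snp_id, action, reason

    def dropped(self) -> list[str]:
        return [r[0] for r in self.rows if r[1] == "drop"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["snp_id", "action", "reason"])

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)


def _is_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def merge_datasets(
    local: GenotypeDataset,
    external: GenotypeDataset,
    drop_ambiguous: bool = True,
) -> tuple[GenotypeDataset, MergeReport]:
    """Merge two datasets on their shared SNPs.

    Allele codings are reconciled against ``local``: matching allele sets keep
    the external dosages (recoded ``x -> 2 - x`` when allele_b is swapped);
    allele sets matching only after strand complementation are complemented
    first; A/T and C/G SNPs are dropped by default (strand is unresolvable);
    anything else is dropped as irreconcilable.
    """
    loc_idx = {s.snp_id: j for j, s in enumerate(local.snps)}
    ext_idx = {s.snp_id: j for j, s in enumerate(external.snps)}
    shared = [s for s in local.snp_ids if s in ext_idx]
    report_rows: list[tuple[str, str, str]] = []
    keep_local: list[int] = []
    ext_cols: list[np.ndarray] = []

    for snp_id in shared:
        ls = local.snps[loc_idx[snp_id]]
        es = external.snps[ext_idx[snp_id]]
        if drop_ambiguous and (_is_ambiguous(ls.allele_a, ls.allele_b) or _is_ambiguous(es.allele_a, es.allele_b)):
            report_rows.append((snp_id, "drop", "strand-ambiguous allele pair"))
            continue
        lset = {ls.allele_a, ls.allele_b}
        eset = {es.allele_a, es.allele_b}
        col = external.dosages[:, ext_idx[snp_id]].copy()
        if eset == lset:
            pass
        elif {_COMPLEMENT[a] for a in eset} == lset:
            es = SNPRecord(
                es.snp_id, es.chromosome, es.position_bp,
                _COMPLEMENT[es.allele_a], _COMPLEMENT[es.allele_b],
                es.genetic_pos_morgans,
            )
            report_rows.append((snp_id, "keep", "strand-complemented"))
        else:
            report_rows.append((snp_id, "drop", "irreconcilable allele sets"))
            continue
        if es.allele_b != ls.allele_b:
            nm = col != MISSING
            col[nm] = 2 - col[nm]
            report_rows.append((snp_id, "keep", "dosage recoded (allele_b swap)"))
        elif (snp_id, "keep", "strand-complemented") not in report_rows[-1:]:
            report_rows.append((snp_id, "keep", "identical coding"))
        keep_local.append(loc_idx[snp_id])
        ext_cols.append(col)

    if not keep_local:
        raise ValueError("no shared markers")

    merged_snps = [local.snps[j] for j in keep_local]
    local_block = local.dosages[:, keep_local]
    ext_block = np.stack(ext_cols, axis=1)
    samples = list(local.samples) + list(external.samples)
    dosages = np.vstack([local_block, ext_block])
    return GenotypeDataset(samples, merged_snps, dosages), MergeReport(report_rows)


def dataset_from_strings(ped_text: str, map_text: str) -> GenotypeDataset:
    """Convenience constructor from in-memory PED/MAP text (fixtures, docs)."""
    return read_plink_text(_stdio.StringIO(ped_text), _stdio.StringIO(map_text))
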