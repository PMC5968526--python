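"""End-to-end orchestration: QC -> relatedness pruning -> diversity/FST ->
MDS -> admixture sweep -> Ne/NeC -> networks, from one config with one seed.

Every stochastic stage derives its own sub-seed from the pipeline seed, so
a (inputs, config, seed) triple is a pure function of its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .admixture import fit_admixture, k_sweep
from .dataset import GenotypeDataset
from .diversity import allelic_richness, fst_matrix, heterozygosity, nei_distance_matrix
from .io import read_plink_text
from .ne import ne_for_population, nec_series
from .networks import neighbor_joining, neighbor_net, write_newick, write_nexus_splits
from .qc import QCConfig, apply_qc
from .relatedness import prune_related, uar_matrix
from .structure import classical_mds, ibs_distance_matrix

STAGES = ("qc", "relatedness", "diversity", "mds", "admixture", "ne", "networks")


@dataclass
class PipelineConfig:
    ped: str
    map: str
    out_dir: str
    seed: int = 0
    qc: QCConfig = field(default_factory=QCConfig)
    relatedness_threshold: float = 0.25
    mds_dims: int = 4
    admix_k_min: int = 1
    admix_k_max: int = 3
    admix_folds: int = 5
    admix_max_iter: int = 500
    ne_alpha: float = 2.2
    ne_cm_per_mb: float = 1.0
    ne_bins: int = 30
    nec_window: int = 20
    stages: tuple[str, ...] = STAGES
    worldwide_merge: bool = False  # merged worldwide runs skip the HWE test

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        qc_raw = raw.pop("qc", {})
        cfg = cls(**{k: (tuple(v) if k == "stages" else v) for k, v in raw.items()})
        cfg.qc = QCConfig(**qc_raw)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"] = dataclasses.asdict(self.qc)
        return d


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)
    version: str = ""

    def add(self, stage: str, status: str, **info) -> None:
        self.stages.append({"stage": stage, "status": status, **info})

    def to_json(self, sink) -> None:
        payload = {"version": self.version, "config": self.config_echo, "stages": self.stages}
        if isinstance(sink, (str, Path)):
            with open(sink, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
        else:
            json.dump(payload, sink, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_echo=config.echo(), version=__version__)
    rng = np.random.default_rng(config.seed)
    sub_seeds = {stage: int(rng.integers(2**31 - 1)) for stage in STAGES}

    dataset = read_plink_text(config.ped, config.map)
    enabled = set(config.stages)

    if "qc" in enabled:
        qc_cfg = config.qc
        if config.worldwide_merge and qc_cfg.hwe_enabled:
            qc_cfg = dataclasses.replace(qc_cfg, hwe_enabled=False)
        dataset, qc_report = apply_qc(dataset.sort_by_map(), qc_cfg)
        qc_report.to_tsv(out / "qc_report.tsv")
        report.add("qc", "complete", samples=dataset.n_samples, snps=dataset.n_snps)
    else:
        report.add("qc", "skipped")

    if "relatedness" in enabled:
        grm = uar_matrix(dataset)
        grm.to_tsv(out / "uar_matrix.tsv")
        keep = prune_related(grm, config.relatedness_threshold,
                             {s.sample_id: s.call_rate for s in dataset.samples})
        dataset = dataset.select_samples(keep)
        with open(out / "kept_samples.tsv", "w") as fh:
            fh.write("sample_id\n" + "\n".join(keep) + "\n")
        report.add("relatedness", "complete", samples=dataset.n_samples)
    else:
        report.add("relatedness", "skipped")

    pops = sorted(set(dataset.population_ids))
    multi_pop = len(pops) >= 2

    if "diversity" in enabled:
        het = heterozygosity(dataset)
        ar = allelic_richness(dataset)
        table = het.frame.join(ar.frame["A_R"])
        table.to_csv(out / "diversity.tsv", sep="\t")
        if multi_pop:
            fst = fst_matrix(dataset)
            fst.to_tsv(out / "fst_matrix.tsv")
            fst.to_phylip(str(out / "fst_matrix.phylip"))
            nei_distance_matrix(dataset).to_tsv(out / "nei_matrix.tsv")
        report.add("diversity", "complete", populations=len(pops))
    else:
        report.add("diversity", "skipped")

    if "mds" in enabled:
        dist = ibs_distance_matrix(dataset)
        dist.to_tsv(out / "ibs_distance.tsv")
        mds = classical_mds(dist, dims=min(config.mds_dims, dataset.n_samples - 1))
        mds.to_tsv(str(out / "mds.tsv"), population_ids=dataset.population_ids)
        report.add("mds", "complete", dims=mds.coordinates.shape[1])
    else:
        report.add("mds", "skipped")

    if "admixture" in enabled:
        sweep = k_sweep(dataset, config.admix_k_min, config.admix_k_max,
                        folds=config.admix_folds, seed=sub_seeds["admixture"],
                        max_iter=config.admix_max_iter)
        sweep.to_csv(out / "admixture_cv.tsv", sep="\t", index=False)
        for K in range(config.admix_k_min, config.admix_k_max + 1):
            fit = fit_admixture(dataset, K, seed=sub_seeds["admixture"] + K,
                                max_iter=config.admix_max_iter)
            fit.to_tsv(out / f"admixture_Q_K{K}.tsv")
        report.add("admixture", "complete",
                   best_k=int(sweep.loc[sweep["best"], "K"].iloc[0]))
    else:
        report.add("admixture", "skipped")

    if "ne" in enabled:
        n_done = 0
        for pop in pops:
            try:
                traj = ne_for_population(dataset, pop, alpha=config.ne_alpha,
                                         cm_per_mb=config.ne_cm_per_mb)
            except ValueError:
                continue
            traj.to_tsv(out / f"ne_{pop}.tsv")
            if len(traj.points) >= 2:
                nec_series(traj, window=config.nec_window).to_tsv(out / f"nec_{pop}.tsv")
            n_done += 1
        report.add("ne", "complete", populations=n_done)
    else:
        report.add("ne", "skipped")

    if "networks" in enabled:
        if multi_pop:
            fst = fst_matrix(dataset)
            from .structure import DistanceMatrix

            dm = DistanceMatrix(fst.population_ids, np.clip(fst.values, 0.0, None))
            if len(pops) >= 2:
                tree = neighbor_joining(dm)
                (out / "fst_nj.nwk").write_text(write_newick(tree) + "\n")
            net = neighbor_net(dm)
            (out / "fst_neighbor_net.nex").write_text(write_nexus_splits(net))
            report.add("networks", "complete", splits=len(net.splits))
        else:
            report.add("networks", "skipped", reason="single population")
    else:
        report.add("networks", "skipped")

    report.to_json(out / "run_report.json")
    return report
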