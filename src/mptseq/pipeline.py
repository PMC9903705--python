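"""End-to-end runs: simulate -> qc -> cluster -> cnv -> doublets -> lineage
-> benchmark, with YAML configuration, per-stage derived seeds, and a
manifest that makes reruns reproducible bit for bit (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_matrix_bundle, write_matrix_bundle
from .model import ClonalModel
from .qc import ScFilterConfig
from .simulate import (
    CnaEvent,
    derive_pseudobulk,
    simulate_cells,
    simulate_observations,
    simulate_truth,
    truth_tables,
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    out_dir: str = "mpt_run"
    master_seed: int = 0
    # simulation (used when no input matrices are given)
    simulate: dict = field(default_factory=dict)
    n_cells: int = 4000
    # analysis
    qc: dict = field(default_factory=dict)
    k: int | None = None
    k_max: int = 8
    doublet_alpha: float = 0.05
    doublet_iterative: bool = True
    gain_log2: float = 0.32
    loss_log2: float = -0.32
    # inputs (matrix dialect prefixes); simulation used when absent
    counts_prefix: str | None = None
    genotypes_prefix: str | None = None
    known_het_sites: list | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig):
    """Execute all stages; write artifacts and a manifest into ``out_dir``.

    Returns the fitted :class:`~mptseq.model.ClonalResults`.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "stages": [],
        "config": {k: v for k, v in asdict(config).items()},
    }

    def stage_done(name, **info):
        manifest["stages"].append({"stage": name, **info})

    truth = cells = None
    if config.counts_prefix and config.genotypes_prefix:
        counts = read_matrix_bundle(config.counts_prefix, ["COUNT"])
        genotypes = read_matrix_bundle(config.genotypes_prefix)
        stage_done("load", counts=config.counts_prefix,
                   genotypes=config.genotypes_prefix)
        known_het = config.known_het_sites
    else:
        sim_seed = derive_seed(config.master_seed, "simulate")
        sim_params = dict(config.simulate)
        cna = [CnaEvent(**e) for e in sim_params.pop("cna_events", [])]
        truth = simulate_truth(seed=sim_seed, cna_events=cna, **sim_params)
        cells = simulate_cells(
            truth, config.n_cells, seed=derive_seed(config.master_seed, "cells")
        )
        counts, genotypes = simulate_observations(
            truth, cells, seed=derive_seed(config.master_seed, "observe")
        )
        known_het = truth.germline_ids
        prefix = os.path.join(config.out_dir, "sim")
        write_matrix_bundle(prefix + ".counts", counts)
        write_matrix_bundle(prefix + ".genotypes", genotypes)
        for name, frame in truth_tables(truth, cells).items():
            frame.to_csv(os.path.join(config.out_dir, f"truth_{name}.tsv"),
                         sep="\t")
        bulk_vaf, bulk_cn = derive_pseudobulk(truth)
        bulk_vaf.to_csv(os.path.join(config.out_dir, "pseudobulk_vaf.tsv"),
                        sep="\t")
        bulk_cn.to_csv(os.path.join(config.out_dir, "pseudobulk_cn.tsv"),
                       sep="\t")
        stage_done("simulate", seed=sim_seed, n_cells=config.n_cells,
                   n_doublets=sum(c.is_doublet for c in cells))

    model = ClonalModel(
        counts=counts,
        genotypes=genotypes,
        qc=ScFilterConfig(**config.qc),
        k=config.k,
        k_max=config.k_max,
        doublet_alpha=config.doublet_alpha,
        doublet_iterative=config.doublet_iterative,
        gain_log2=config.gain_log2,
        loss_log2=config.loss_log2,
        known_het_sites=known_het,
    )
    results = model.fit(seed=derive_seed(config.master_seed, "cluster"))
    stage_done("fit", n_clusters=results.n_clusters_detected,
               n_doublet_cells=len(results.doublet_cells))

    out = config.out_dir
    results.qc_ledger.to_csv(os.path.join(out, "qc_ledger.tsv"), sep="\t",
                             index=False)
    results.assignment.labels.rename("cluster").to_csv(
        os.path.join(out, "assignment.tsv"), sep="\t")
    results.cluster_table().to_csv(os.path.join(out, "clusters.tsv"),
                                   sep="\t", index=False)
    results.cn_table.to_csv(os.path.join(out, "cluster_cn.tsv"), sep="\t",
                            index=False)
    results.doublet_report.to_frame().to_csv(
        os.path.join(out, "doublet_tests.tsv"), sep="\t", index=False)
    if results.tree is not None:
        with open(os.path.join(out, "lineage.nwk"), "w") as fh:
            fh.write(results.tree.newick() + "\n")
        results.tree.events_frame().to_csv(
            os.path.join(out, "lineage_events.tsv"), sep="\t", index=False)
    results.metrics.to_series().to_csv(os.path.join(out, "qc_metrics.tsv"),
                                       sep="\t")
    with open(os.path.join(out, "summary.txt"), "w") as fh:
        fh.write(results.summary() + "\n")

    manifest["input_hash"] = hashlib.sha256(
        np.ascontiguousarray(counts.layers["COUNT"]).tobytes()
    ).hexdigest()
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return results
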