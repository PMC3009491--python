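"""Run configuration and the end-to-end prioritization pipeline.

A single YAML config names the input networks, annotation tables and
family files and fixes every numeric knob (restart probability, KNN k,
rating levels, AUC weight floor, fusion method, number of controls) plus
one master seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from . import evaluation, fusion, io, rwr
from .annotations import build_knn_graph, compute_information_content, load_annotations
from .network import load_network, save_network

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    networks: list[dict] = field(default_factory=list)     # {path, label}
    annotations: list[dict] = field(default_factory=list)  # {path, label}
    families: list[str] = field(default_factory=list)
    gamma: float = rwr.DEFAULT_GAMMA
    tol: float = rwr.DEFAULT_TOL
    knn_k: int = 5
    levels: int = fusion.DEFAULT_LEVELS
    auc_floor: float = fusion.DEFAULT_AUC_FLOOR
    method: str = "drs"
    controls_per_gene: int = evaluation.DEFAULT_CONTROLS
    seed: int = 0
    outdir: str = "generank_out"

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not 0 <= self.auc_floor <= 1:
            raise ValueError(f"auc_floor must lie in [0, 1], got {self.auc_floor}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.controls_per_gene < 0:
            raise ValueError("controls_per_gene must be >= 0")
        if self.method.lower() not in fusion.FUSION_METHODS:
            raise ValueError(f"unknown fusion method {self.method!r}")
        if not self.networks and not self.annotations:
            raise ValueError("config names no networks and no annotations")
        for entry in list(self.networks) + list(self.annotations):
            p = entry["path"]
            if not os.path.exists(p):
                raise FileNotFoundError(f"input path does not exist: {p}")
        for p in self.families:
            if not os.path.exists(p):
                raise FileNotFoundError(f"family file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def _load_sources(config: RunConfig):
    nets = []
    for entry in config.networks:
        nets.append(load_network(entry["path"], entry.get("label", entry["path"])))
    for entry in config.annotations:
        table = load_annotations(entry["path"], entry.get("label"))
        ic = compute_information_content(table)
        nets.append(
            build_knn_graph(
                table, ic, k=config.knn_k,
                source_label=entry.get("label", table.ontology_label),
            )
        )
    return nets


def run_pipeline(config: RunConfig) -> dict:
    """LOOCV-evaluate every family and write all outputs under ``outdir``.

    Outputs: per-source LOOCV rank lists, fusion results, a per-family
    AUC table, pooled ROC points, the built networks' edge lists, and a
    JSON manifest echoing the config, package version and seed.
    Returns a summary dict with the per-family and pooled AUCs.
    """
    os.makedirs(config.outdir, exist_ok=True)
    networks = _load_sources(config)
    for net in networks:
        save_network(
            net, os.path.join(config.outdir, f"network_{net.graph['source_label']}.tsv")
        )
    families = [io.load_family(p) for p in config.families]
    rng = np.random.default_rng(config.seed)

    method = config.method.lower()
    auc_rows: list[tuple[str, str, float]] = []
    all_records: list[evaluation.PrioritizationRecord] = []
    for fam in families:
        weights = None
        if method == "wdrs":
            weights = evaluation.per_source_weights(
                fam, networks, floor=config.auc_floor,
                controls_per_gene=config.controls_per_gene,
                gamma=config.gamma, tol=config.tol,
                rng=np.random.default_rng(config.seed),
            )
        records = evaluation.loocv_run(
            fam, networks,
            controls_per_gene=config.controls_per_gene,
            method=method, levels=config.levels,
            gamma=config.gamma, tol=config.tol,
            weights=weights, rng=rng,
        )
        all_records.extend(records)
        fam_auc = evaluation.roc_auc(records).auc if records else float("nan")
        auc_rows.append((fam.name, method.upper(), fam_auc))
        for rec in records:
            stem = f"{fam.name}__{rec.held_out}"
            io.save_rank_lists(
                list(rec.source_rank_lists.values()),
                os.path.join(config.outdir, f"ranks_{stem}.tsv"),
            )
            io.save_rank_lists(
                [rec.combined],
                os.path.join(config.outdir, f"combined_{stem}.tsv"),
            )

    io.save_auc_table(auc_rows, os.path.join(config.outdir, "auc_table.tsv"))
    pooled = evaluation.roc_auc(all_records)
    io.save_roc_points(pooled, os.path.join(config.outdir, "roc_points.tsv"))

    manifest = {
        "config": dataclasses.asdict(config),
        "generank_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "n_records": len(all_records),
        "pooled_auc": pooled.auc,
        "per_family_auc": {fam: auc for fam, _, auc in auc_rows},
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
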