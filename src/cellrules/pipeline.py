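"""End-to-end orchestration: filter -> Boruta -> mRMR -> IFS (CART + random
forest) -> rule tree on the CART optimum -> rules + exclusive genes ->
optional over-representation analysis on the forest optimum genes.

One global seed deterministically derives per-stage seeds by hashing the
stage name, so any stage can be rerun in isolation. Every artifact plus a
manifest (parameters, seeds, versions, timings) is written to the output
directory; with ``resume=True`` stages whose artifacts already exist are
skipped and reloaded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

import cellrules
from cellrules.boruta import run_boruta, BorutaResult
from cellrules.datamodel import LabeledDataset, filter_cell_types, load_dataset
from cellrules.enrichment import enrichment_to_frame, ora, read_gmt
from cellrules.ifs import ClassifierSpec, find_optimum, run_ifs
from cellrules.mrmr import RankedGeneList, discretize, rank_mrmr
from cellrules.rules import (exclusive_genes, extract_rules, rules_to_frame,
                             train_rule_tree)
from cellrules.synth import SyntheticConfig, generate

log = logging.getLogger("cellrules")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized verbatim into the manifest."""

    # input: either paths to a saved dataset, or a synthetic config
    matrix_path: str | None = None
    labels_path: str | None = None
    matrix_format: str = "dense"
    synthetic: SyntheticConfig | None = None
    # stage parameters
    min_cells: int = 100
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    boruta_trees: int = 100
    smote_k: int = 5
    smote_policy: str = "within"
    ifs_step: int = 10
    folds: int = 10
    forest_trees: int = 100
    enrichment_gmt: str | None = None
    enrichment_alpha: float = 0.001
    seed: int = 0
    outdir: str = "cellrules_run"

    def validate(self) -> None:
        if self.synthetic is None:
            if not (self.matrix_path and self.labels_path):
                raise ValueError("need either matrix/labels paths or a synthetic config")
            for p in (self.matrix_path, self.labels_path):
                if not os.path.exists(p):
                    raise ValueError(f"input file not found: {p}")
        if self.enrichment_gmt and not os.path.exists(self.enrichment_gmt):
            raise ValueError(f"GMT file not found: {self.enrichment_gmt}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    dataset: LabeledDataset
    boruta: BorutaResult
    ranked: RankedGeneList
    curves: dict = field(default_factory=dict)      # classifier -> IFSCurve
    optima: dict = field(default_factory=dict)      # classifier -> (n, mcc)
    rules: list = field(default_factory=list)
    exclusive: dict = field(default_factory=dict)
    enrichment: list = field(default_factory=list)
    outdir: str = ""


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> PipelineResult:
    """Execute every stage and write artifacts + manifest to cfg.outdir."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    def path(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    def done(name: str) -> bool:
        return resume and os.path.exists(path(name))

    # --- input ---------------------------------------------------------
    if cfg.synthetic is not None:
        ds, _ = generate(cfg.synthetic)
        log.info("generated synthetic dataset: %d cells x %d genes",
                 ds.n_cells, ds.n_genes)
    else:
        ds = load_dataset(cfg.matrix_path, cfg.labels_path, format=cfg.matrix_format)
        log.info("loaded dataset: %d cells x %d genes", ds.n_cells, ds.n_genes)

    ds = filter_cell_types(ds, min_cells=cfg.min_cells)
    timings["input"] = time.time() - t0

    # --- boruta --------------------------------------------------------
    t = time.time()
    if done("boruta.tsv"):
        df = pd.read_csv(path("boruta.tsv"), sep="\t")
        bres = BorutaResult(
            status=dict(zip(df.gene_id, df.status)),
            hit_counts=dict(zip(df.gene_id, df.hit_count)),
        )
        log.info("boruta: resumed from artifact")
    else:
        bres = run_boruta(ds, max_iter=cfg.boruta_max_iter, alpha=cfg.boruta_alpha,
                          seed=stage_seed(cfg.seed, "boruta"),
                          n_trees=cfg.boruta_trees)
        bres.save(path("boruta.tsv"))
    important = bres.important
    log.info("boruta: %d important genes of %d", len(important), ds.n_genes)
    if not important:
        raise RuntimeError("stage boruta: no gene confirmed important")
    timings["boruta"] = time.time() - t

    # --- mrmr ----------------------------------------------------------
    t = time.time()
    if done("ranked.tsv"):
        df = pd.read_csv(path("ranked.tsv"), sep="\t")
        ranked = RankedGeneList(df.gene_id.tolist(), df.score.tolist())
        log.info("mrmr: resumed from artifact")
    else:
        sub = ds.subset_genes(important)
        ranked = rank_mrmr(discretize(sub), sub.labels)
        ranked.save(path("ranked.tsv"))
    timings["mrmr"] = time.time() - t

    # --- ifs -----------------------------------------------------------
    curves, optima = {}, {}
    for name in ("cart", "random_forest"):
        t = time.time()
        spec = ClassifierSpec(name=name, n_trees=cfg.forest_trees)
        curve = run_ifs(ds, ranked, spec, step=cfg.ifs_step, folds=cfg.folds,
                        smote_policy=cfg.smote_policy, smote_k=cfg.smote_k,
                        seed=stage_seed(cfg.seed, f"ifs:{name}"))
        curve.save(path(f"ifs_{name}.tsv"))
        curves[name] = curve
        optima[name] = find_optimum(curve)
        for n, rec in curve.rows:
            log.info("ifs[%s] n=%d mcc=%.4f acc=%.4f", name, n, rec.mcc,
                     rec.overall_accuracy)
        log.info("ifs[%s]: optimum %d genes, MCC %.4f", name, *optima[name])
        timings[f"ifs:{name}"] = time.time() - t

    # --- rules on the CART optimum --------------------------------------
    t = time.time()
    n_opt, _ = optima["cart"]
    tree = train_rule_tree(ds, ranked.top(n_opt),
                           seed=stage_seed(cfg.seed, "rules"))
    rules = extract_rules(tree)
    rules_to_frame(rules).to_csv(path("rules.tsv"), sep="\t", index=False)
    report = exclusive_genes(rules)
    report.save(path("exclusive_genes.tsv"))
    log.info("rules: %d rules, %d classes with exclusive genes",
             len(rules), len(report.mapping))
    timings["rules"] = time.time() - t

    # --- enrichment on the forest optimum --------------------------------
    enrich_rows: list = []
    if cfg.enrichment_gmt:
        t = time.time()
        sets = read_gmt(cfg.enrichment_gmt, universe=set(ds.gene_ids))
        n_rf, _ = optima["random_forest"]
        enrich_rows = ora(set(ranked.top(n_rf)), sets, alpha=cfg.enrichment_alpha)
        enrichment_to_frame(enrich_rows).to_csv(path("enrichment.tsv"),
                                                sep="\t", index=False)
        timings["enrichment"] = time.time() - t

    manifest = {
        "package_version": cellrules.__version__,
        "config": cfg.to_dict(),
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("boruta", "ifs:cart", "ifs:random_forest", "rules")},
        "optima": {k: {"n_features": v[0], "mcc": v[1]} for k, v in optima.items()},
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(ds, bres, ranked, curves, optima, rules,
                          report.mapping, enrich_rows, cfg.outdir)
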