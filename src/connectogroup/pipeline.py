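"""End-to-end orchestration: simulate -> edge stats -> graph metrics ->
group stats -> classification -> report.

Every stage is optional (toggles), every output is attributable to the run
configuration and master seed through the run manifest, and re-running an
identical configuration reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierSuiteConfig, report_table, run_classifier_suite
from .core import FILTERINGS, write_cohort
from .edge_stats import HYPOTHESES, TFNBSConfig, tfnbs_fwe, top_connections_table
from .graph_metrics import compute_cohort_metrics
from .group_stats import (filtering_impact, global_group_tests,
                          node_group_tests, significance_report)
from .synthetic import (SimulationConfig, scenario_config, sift2_weight_histograms,
                        simulate_cohort)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Master configuration of a pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    scenario: str | None = "null"           # preset; None to use `simulation`
    simulation: SimulationConfig | None = None
    tfnbs: TFNBSConfig = field(default_factory=TFNBSConfig)
    alpha: float = 0.05
    classifier: ClassifierSuiteConfig = field(default_factory=ClassifierSuiteConfig)
    top_k: int = 10
    run_edge_stats: bool = True
    run_graph_metrics: bool = True
    run_group_stats: bool = True
    run_classification: bool = True

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return scenario_config(self.scenario or "null", seed=self.seed)


def _config_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {f.name: _config_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, (list, tuple)):
        return [_config_dict(v) for v in cfg]
    if isinstance(cfg, dict):
        return {k: _config_dict(v) for k, v in cfg.items()}
    return cfg


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages; returns the report directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = _config_dict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)

    sim_cfg = cfg.resolved_simulation()
    if sim_cfg.seed != cfg.seed:
        sim_cfg = dataclasses.replace(sim_cfg, seed=cfg.seed)
    logger.info("simulating cohort (%d HC / %d PD, %d regions)",
                sim_cfg.n_hc, sim_cfg.n_pd, sim_cfg.n_regions)
    cohort, trace = simulate_cohort(sim_cfg)
    write_cohort(cohort, out / "cohort")
    metrics = tuple(cohort.available_metrics())

    hist, ks_stat, ks_p = sift2_weight_histograms(
        trace, cohort.manifest,
        n_subjects=min(20, 2 * min(sim_cfg.n_hc, sim_cfg.n_pd)), seed=cfg.seed)
    hist.to_csv(out / "sift2_weight_histograms.csv", index=False)
    (out / "sift2_weight_ks.json").write_text(
        json.dumps({"ks_statistic": ks_stat, "ks_pvalue": ks_p}, indent=2))

    if cfg.run_edge_stats:
        try:
            frames = []
            for filtering in FILTERINGS:
                for metric in metrics:
                    res = tfnbs_fwe(cohort, metric, filtering,
                                    dataclasses.replace(cfg.tfnbs, seed=cfg.seed))
                    for hyp in HYPOTHESES:
                        tab = top_connections_table(res, cfg.top_k, hypothesis=hyp)
                        tab.insert(0, "metric", metric)
                        tab.insert(1, "filtering", filtering)
                        frames.append(tab)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "top_connections.csv", index=False)
        except Exception:
            logger.exception("stage edge_stats failed; partial outputs preserved")
            raise RuntimeError("stage 'edge_stats' failed") from None

    node_tables, global_tables = {}, {}
    if cfg.run_graph_metrics or cfg.run_group_stats:
        try:
            all_nodes, all_globals = [], []
            for filtering in FILTERINGS:
                for metric in metrics:
                    nt, gt = compute_cohort_metrics(cohort, metric, filtering)
                    node_tables[(metric, filtering)] = nt
                    global_tables[(metric, filtering)] = gt
                    all_nodes.append(nt)
                    all_globals.append(gt)
            pd.concat(all_nodes, ignore_index=True).to_csv(
                out / "node_metrics.csv", index=False)
            pd.concat(all_globals, ignore_index=True).to_csv(
                out / "global_metrics.csv", index=False)
        except Exception:
            logger.exception("stage graph_metrics failed")
            raise RuntimeError("stage 'graph_metrics' failed") from None

    if cfg.run_group_stats:
        try:
            node_all = pd.concat(node_tables.values(), ignore_index=True)
            comp = node_group_tests(node_all, cohort.manifest)
            comp.to_csv(out / "node_comparisons.csv", index=False)
            for measure in ("strength", "betweenness", "clustering"):
                significance_report(comp, measure).to_csv(
                    out / f"significance_{measure}.csv", index=False)
            impact = filtering_impact(
                comp[comp["filtering"] == "unfiltered"],
                comp[comp["filtering"] == "filtered"], alpha=cfg.alpha)
            impact.to_csv(out / "filtering_impact.csv", index=False)
            glob_all = pd.concat(global_tables.values(), ignore_index=True)
            gcomp, esummary = global_group_tests(glob_all, cohort.manifest)
            gcomp.to_csv(out / "global_comparisons.csv", index=False)
            esummary.to_csv(out / "effect_size_summary.csv", index=False)
        except Exception:
            logger.exception("stage group_stats failed")
            raise RuntimeError("stage 'group_stats' failed") from None

    if cfg.run_classification:
        try:
            fold_rows = run_classifier_suite(cohort, metrics, FILTERINGS,
                                             cfg.classifier, seed=cfg.seed)
            fold_rows.to_csv(out / "classification_folds.csv", index=False)
            report_table(fold_rows).to_csv(out / "classification_report.csv",
                                           index=False)
        except Exception:
            logger.exception("stage classification failed")
            raise RuntimeError("stage 'classification' failed") from None

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": cfg_dict,
        "numpy": np.__version__,
        "python": platform.python_version(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
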