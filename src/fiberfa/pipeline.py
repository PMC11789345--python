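"""End-to-end orchestration: simulate/load -> QC -> panel -> factors ->
classify -> profile, with a machine-readable run report.

Every stage is available separately; this module wires the defaults
together for the command line and for reproducibility scripts.
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import FiberClassAssignment, classify_cells, propose_thresholds
from .factor import FiberFactorModel, FiberFactorResults
from .gosim import panel_table, rank_similar_genes, select_feature_panel
from .io import CountMatrix, RunReport, write_report
from .preprocess import ExprMatrix, QCReport, normalize_log_rpm, qc_filter
from .profile import (ClusterAnnotation, ProportionTable, cluster_subpopulation,
                      combine_clusters, compare_marker_expression,
                      condition_proportions, find_sigups, name_clusters)
from .simulate import SimConfig, SyntheticTruth, generate_fiber_counts, \
    generate_go_annotations

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResults", "run_pipeline"]

SEEDS_FAST = ("Myh1", "Myh2", "Myh4")
SEEDS_SLOW = ("Myh7",)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, loadable from a TOML file."""

    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    # QC
    count_cutoff: float = 5000.0
    mito_cutoff: float = 0.10
    count_filter: str = "ge_removes"
    # panel
    seeds_fast: tuple[str, ...] = SEEDS_FAST
    seeds_slow: tuple[str, ...] = SEEDS_SLOW
    similar_top_k: int = 3
    similar_min_score: float | None = None
    aggregate: str = "max"
    # factors
    n_factors: int | str = "auto"
    pa_reps: int = 100
    pa_quantile: float = 0.95
    rotation: str = "quartimin"
    score_method: str = "regression"
    # classify
    tau_fast: float | None = None
    tau_slow: float | None = None
    threshold_method: str = "valley"
    # profile
    resolution: float = 1.0
    n_neighbors: int = 15
    sigup_alpha: float = 0.05
    sigup_min_lfc: float = 1.0
    combine_names: tuple[str, ...] = ()
    atrophy_markers: tuple[str, ...] = ("Fbxo32", "Trim63")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_kwargs = raw.pop("simulate", {})
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in flat.items()})
        if sim_kwargs:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim_kwargs) - sim_known
            if bad:
                raise ValueError(f"unknown [simulate] keys: {sorted(bad)}")
            cfg.simulate = SimConfig(**sim_kwargs)
        return cfg


@dataclass
class PipelineResults:
    """Everything one run produced, ready for `write_report`."""

    counts_raw: CountMatrix
    counts: CountMatrix
    qc: QCReport
    expr: ExprMatrix
    panel: list[str]
    panel_frame: pd.DataFrame
    factors: FiberFactorResults
    assignment: FiberClassAssignment
    class_proportions: ProportionTable
    subpop: dict  # subpopulation -> dict(labels, sigups, annotations, proportions)
    marker_comparison: pd.DataFrame | None
    combined: pd.Series | None
    report: RunReport
    truth: SyntheticTruth | None = None

    def tables(self) -> dict:
        cluster_rows = []
        sigup_frames = []
        prop_rows = []
        for sub, d in self.subpop.items():
            name_of = {a.cluster: a.name for a in d["annotations"]}
            for cell, lab in zip(d["cells"], d["labels"]):
                cluster_rows.append((cell, sub, int(lab), name_of[int(lab)]))
            sg = d["sigups"].copy()
            sg.insert(0, "subpopulation", sub)
            sigup_frames.append(sg)
            tab: ProportionTable = d["proportions"]
            for cond in tab.counts.index:
                for cname in tab.counts.columns:
                    prop_rows.append((sub, cond, cname,
                                      int(tab.counts.loc[cond, cname]),
                                      float(tab.fractions.loc[cond, cname])))
        for cond in self.class_proportions.counts.index:
            for cname in self.class_proportions.counts.columns:
                prop_rows.append(("all", cond, cname,
                                  int(self.class_proportions.counts.loc[cond, cname]),
                                  float(self.class_proportions.fractions.loc[cond, cname])))
        return {
            "loadings": self.factors.loading_table(),
            "scores": self.factors.scores.reset_index(names="cell"),
            "classes": self.assignment.frame,
            "clusters": pd.DataFrame(cluster_rows, columns=[
                "cell", "subpopulation", "cluster", "name"]),
            "sigups": (pd.concat(sigup_frames, ignore_index=True)
                       if sigup_frames else pd.DataFrame(
                           columns=["subpopulation", "cluster", "gene",
                                    "lfc", "p_adj"])),
            "proportions": pd.DataFrame(prop_rows, columns=[
                "subpopulation", "condition", "cluster", "count", "fraction"]),
            "report": self.report,
        }

    def write(self, out_dir) -> dict[str, Path]:
        return write_report(self.tables(), out_dir)


def _build_panel(config: PipelineConfig, go_table, expr_genes):
    seeds = list(config.seeds_fast) + list(config.seeds_slow)
    ranking = rank_similar_genes(seeds, go_table, aggregate=config.aggregate)
    if config.similar_min_score is not None:
        panel = select_feature_panel(seeds, ranking,
                                     min_score=config.similar_min_score)
    else:
        panel = select_feature_panel(seeds, ranking, top_k=config.similar_top_k)
    absent = [g for g in panel if g not in expr_genes]
    if absent:
        logger.warning("panel genes absent from expression matrix: %s", absent)
        panel = [g for g in panel if g in expr_genes]
    return panel, panel_table(seeds, ranking, panel)


def run_pipeline(config: PipelineConfig | None = None, seed: int | None = None,
                 counts: CountMatrix | None = None,
                 go_table: dict[str, set[str]] | None = None,
                 with_profile: bool = True) -> PipelineResults:
    """Run the full analysis; simulate inputs when none are given."""
    config = config or PipelineConfig()
    if seed is not None:
        config.seed = seed
        config.simulate = dataclasses.replace(config.simulate, seed=seed)

    truth = None
    if counts is None:
        counts, truth = generate_fiber_counts(config.simulate)
    if go_table is None:
        go_table = generate_go_annotations(
            extra_genes=[g for g in counts.genes])

    filtered, qc = qc_filter(counts, count_cutoff=config.count_cutoff,
                             mito_cutoff=config.mito_cutoff,
                             count_filter=config.count_filter)
    expr = normalize_log_rpm(filtered)

    panel, panel_frame = _build_panel(config, go_table, expr.genes)

    model = FiberFactorModel(expr, panel=panel,
                             seeds_fast=list(config.seeds_fast),
                             seeds_slow=list(config.seeds_slow))
    factors = model.fit(n_factors=config.n_factors, rotation=config.rotation,
                        score_method=config.score_method,
                        pa_reps=config.pa_reps, pa_quantile=config.pa_quantile,
                        seed=config.seed)

    thresholds = propose_thresholds(factors.scores,
                                    method=config.threshold_method,
                                    tau_fast=config.tau_fast,
                                    tau_slow=config.tau_slow)
    assignment = classify_cells(factors.scores, thresholds)

    conditions = pd.Series(expr.condition, index=expr.cells) \
        if expr.condition is not None else pd.Series("NA", index=expr.cells)
    class_props = condition_proportions(assignment.frame["label"],
                                        conditions.to_numpy())

    subpop: dict = {}
    marker_cmp = None
    combined = None
    if with_profile:
        expr_df = expr.to_frame()
        for sub in ("fast", "slow"):
            mask = (assignment.frame["label"] == sub).to_numpy()
            cells = [c for c, m in zip(expr.cells, mask) if m]
            if mask.sum() < 3:
                logger.warning("subpopulation %r has %d cells; skipping "
                               "profiling", sub, int(mask.sum()))
                continue
            sub_expr = expr_df.loc[cells]
            labels = cluster_subpopulation(
                sub_expr.to_numpy(), n_neighbors=config.n_neighbors,
                resolution=config.resolution, seed=config.seed)
            sizes = {int(c): int((labels == c).sum())
                     for c in np.unique(labels)}
            if len(sizes) >= 2:
                sigups = find_sigups(sub_expr, labels,
                                     alpha=config.sigup_alpha,
                                     min_lfc=config.sigup_min_lfc)
            else:
                sigups = pd.DataFrame(columns=["cluster", "gene", "lfc",
                                               "p_adj"])
            annotations = name_clusters(sigups, sizes)
            name_of = {a.cluster: a.name for a in annotations}
            named = np.array([name_of[int(c)] for c in labels], dtype=object)
            props = condition_proportions(named, conditions.loc[cells].to_numpy())
            subpop[sub] = {"cells": cells, "labels": labels, "sigups": sigups,
                           "annotations": annotations, "proportions": props}
        markers = [g for g in config.atrophy_markers if g in expr.genes]
        if markers and expr.condition is not None:
            marker_cmp = compare_marker_expression(expr_df, markers,
                                                   conditions.to_numpy())
        if config.combine_names and "slow" in subpop:
            combined = combine_clusters(subpop["slow"]["proportions"],
                                        list(config.combine_names))
        else:
            # default slow-typical summary: the slow class itself
            combined = combine_clusters(class_props, ["slow"]) \
                if "slow" in class_props.fractions.columns else None

    report = RunReport(
        seed=config.seed,
        config={k: str(v) for k, v in dataclasses.asdict(config).items()},
        thresholds={"tau_fast": thresholds.tau_fast,
                    "tau_slow": thresholds.tau_slow,
                    "provenance": thresholds.provenance},
        stage_tallies={
            "cells_raw": counts.n_cells,
            "cells_kept": filtered.n_cells,
            "genes": counts.n_genes,
            "panel_genes": len(panel),
            "n_factors": factors.n_factors,
            "class_counts": {k: int(v) for k, v
                             in assignment.counts().items()},
            "clusters": {sub: len(d["annotations"])
                         for sub, d in subpop.items()},
        },
        stage_seeds={"simulate": config.simulate.seed,
                     "parallel_analysis": config.seed,
                     "rotation_restarts": config.seed,
                     "clustering": config.seed},
        design_choices={"extraction": "minres", "rotation": config.rotation,
                        "score_method": config.score_method,
                        "pa_reps": config.pa_reps,
                        "pa_quantile": config.pa_quantile,
                        "standardized": True},
        version=__version__,
    )
    return PipelineResults(
        counts_raw=counts, counts=filtered, qc=qc, expr=expr, panel=panel,
        panel_frame=panel_frame, factors=factors, assignment=assignment,
        class_proportions=class_props, subpop=subpop,
        marker_comparison=marker_cmp, combined=combined, report=report,
        truth=truth,
    )
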