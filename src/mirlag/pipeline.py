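"""End-to-end orchestration: simulate/load -> preprocess -> DE -> classify
-> networks -> enrichment -> qPCR validation, with a stage-by-stage report.

In simulation mode the run is a pure function of the seed, and the report
additionally scores every stage against the planted ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential_expression import (
    Comparison,
    apply_de_filters,
    apply_quality_exclusions,
    differential_expression,
)
from .enrichment import enrich, write_gmt
from .preprocessing import filter_undetected, quantile_normalize
from .qpcr import ddct_fold_change, select_references, validate_candidates
from .synthetic_data import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_prediction_table,
    simulate_qpcr,
    write_ground_truth,
)
from .target_networks import (
    build_inverse_network,
    export_network,
    filter_min_algorithms,
    inverse_gene_set,
)
from .temporal_grouping import GroupLabel, build_profiles, classify_groups

logger = logging.getLogger("mirlag")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and study settings for one pipeline run.

    Defaults are the study's candidate filters: |FC| >= 1.5 (miRNA) and
    >= 1.3 (mRNA), adjusted p < 0.05, predictions supported by >= 2
    algorithms.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    mirna_fc: float = 1.5
    mrna_fc: float = 1.3
    alpha: float = 0.05
    min_algorithms: int = 2
    background_margin: float = 1.2
    cv_max: float = 0.5
    min_term_size: int = 3
    require_p13: bool = False
    n_qpcr_candidates: int = 25
    n_reference_candidates: int = 5

    def __post_init__(self) -> None:
        if self.mirna_fc < 1 or self.mrna_fc < 1:
            raise ValueError("fold-change cutoffs must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_algorithms < 1 or self.min_term_size < 1:
            raise ValueError("count thresholds must be >= 1")


@dataclass
class RunReport:
    """Stage-by-stage feature counts, ground-truth scores and output paths."""

    counts: dict
    metrics: dict
    manifest: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"counts": self.counts, "metrics": self.metrics, "manifest": self.manifest}, indent=2, sort_keys=True) + "\n")


def _comparisons(config: SimulationConfig) -> tuple[dict[str, Comparison], dict[str, Comparison]]:
    case, control = config.genotypes
    tps = config.timepoints
    baseline_tp = tps[0]
    mirna = {}
    for tp in tps:
        mirna[f"wt_{tp}"] = Comparison((case, tp), (control, tp))
    for tp in tps[1:]:
        mirna[f"base_{tp}"] = Comparison((case, tp), (case, baseline_tp))
    mrna = {f"wt_{tp}": Comparison((case, tp), (control, tp)) for tp in tps}
    return mirna, mrna


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Run every stage on a fresh simulation; write all artefacts to outdir."""
    sim_cfg = config.simulation
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    metrics: dict = {}

    logger.info("stage simulate: %d miRNA x %d mRNA features, seed %d", sim_cfg.n_mirna, sim_cfg.n_mrna, sim_cfg.seed)
    sim = simulate_expression(sim_cfg)
    truth = sim.truth
    predictions = simulate_prediction_table(sim_cfg, truth)
    annotation = simulate_annotation(sim_cfg, truth)
    counts["mirna_raw"] = len(sim.mirna.feature_ids)
    counts["mrna_raw"] = len(sim.mrna.feature_ids)
    counts["prediction_rows"] = len(predictions)

    logger.info("stage preprocess: quantile normalization + detection filter")
    mirna_norm = quantile_normalize(sim.mirna)
    mrna_norm = quantile_normalize(sim.mrna)
    mirna = filter_undetected(mirna_norm, sim.mirna_calls)
    mrna = filter_undetected(mrna_norm, sim.mrna_calls)
    counts["mirna_detected"] = len(mirna.feature_ids)
    counts["mrna_detected"] = len(mrna.feature_ids)

    logger.info("stage de: Welch tests with BH adjustment per comparison")
    mirna_cmp, mrna_cmp = _comparisons(sim_cfg)
    mirna_de = {slot: differential_expression(mirna, cmp) for slot, cmp in mirna_cmp.items()}
    mrna_de = {slot: differential_expression(mrna, cmp) for slot, cmp in mrna_cmp.items()}
    mirna_filtered = {}
    for slot, table in mirna_de.items():
        passed = apply_de_filters(table, config.mirna_fc, config.alpha)
        # background level is anchored on the full normalized matrix, where
        # never-detected probes are still present
        mirna_filtered[slot] = apply_quality_exclusions(
            passed, mirna_norm, sim.mirna_calls, config.background_margin, config.cv_max
        )
    mrna_filtered = {slot: apply_de_filters(t, config.mrna_fc, config.alpha) for slot, t in mrna_de.items()}
    tps = sim_cfg.timepoints
    mid_tp, last_tp = tps[len(tps) // 2], tps[-1]
    de_union = sorted({f for t in mirna_filtered.values() for f in t["feature_id"]})
    counts["mirna_de_any_comparison"] = len(de_union)
    counts["mrna_de_mid"] = len(mrna_filtered[f"wt_{mid_tp}"])
    counts["mrna_de_last"] = len(mrna_filtered[f"wt_{last_tp}"])

    logger.info("stage classify: temporal group assignment")
    profiles = build_profiles(mirna_filtered, de_union, {s: s for s in mirna_filtered})
    labels = classify_groups(profiles, require_p13=config.require_p13)
    group_a = sorted(f for f, g in labels.items() if g is GroupLabel.A)
    group_b = sorted(f for f, g in labels.items() if g is GroupLabel.B)
    counts["group_a"] = len(group_a)
    counts["group_b"] = len(group_b)

    logger.info("stage network: inverse-expression networks A15/A17/B17")
    preds_k = filter_min_algorithms(predictions, config.min_algorithms)
    counts["prediction_rows_min_algorithms"] = len(preds_k)
    mi_anchor_a = mirna_filtered[f"wt_{mid_tp}"]
    mi_anchor_b = mirna_filtered[f"wt_{last_tp}"]
    nets = {
        "A15": build_inverse_network(
            "A15", mi_anchor_a[mi_anchor_a["feature_id"].isin(group_a)], mrna_filtered[f"wt_{mid_tp}"], preds_k, sim.mrna_calls
        ),
        "A17": build_inverse_network(
            "A17", mi_anchor_a[mi_anchor_a["feature_id"].isin(group_a)], mrna_filtered[f"wt_{last_tp}"], preds_k, sim.mrna_calls
        ),
        "B17": build_inverse_network(
            "B17", mi_anchor_b[mi_anchor_b["feature_id"].isin(group_b)], mrna_filtered[f"wt_{last_tp}"], preds_k, sim.mrna_calls
        ),
    }
    for name, net in nets.items():
        counts[f"edges_{name}"] = len(net.edges)
    genes = inverse_gene_set(list(nets.values()))
    counts["inverse_genes"] = len(genes)

    logger.info("stage enrich: hypergeometric over-representation")
    universe = set(mrna.feature_ids)
    enrichment = enrich(genes & universe, universe, annotation, config.min_term_size, config.alpha)
    counts["terms_tested"] = len(enrichment)
    counts["terms_significant"] = int(enrichment["significant"].sum()) if len(enrichment) else 0

    logger.info("stage qpcr: reference selection and ddCt validation")
    qpcr_summary = _qpcr_stage(config, sim, mirna_filtered, group_a, group_b, mid_tp, last_tp, counts, metrics)

    _truth_metrics(truth, mirna_filtered, labels, nets, enrichment, group_a, group_b, mid_tp, last_tp, metrics)

    manifest = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "pipeline_config": {k: v for k, v in asdict(config).items() if k != "simulation"},
        "simulation_config": asdict(sim_cfg),
    }
    if out is not None:
        _write_outputs(out, sim, predictions, annotation, mirna_de, mrna_de, mirna_filtered, mrna_filtered, labels, nets, enrichment, qpcr_summary)
        manifest["outdir"] = str(out)
    report = RunReport(counts, metrics, manifest)
    if out is not None:
        report.to_json(out / "report.json")
    return report


def _qpcr_stage(config, sim, mirna_filtered, group_a, group_b, mid_tp, last_tp, counts, metrics):
    sim_cfg = config.simulation
    truth = sim.truth
    anchor = {f: mid_tp for f in group_a} | {f: last_tp for f in group_b}
    rows = []
    for tp, slot in ((mid_tp, f"wt_{mid_tp}"), (last_tp, f"wt_{last_tp}")):
        t = mirna_filtered[slot]
        rows.append(t[t["feature_id"].map(anchor.get) == tp])
    array_de = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["feature_id", "signed_fc"])
    if array_de.empty:
        counts["qpcr_candidates"] = 0
        return None
    array_de = array_de.reindex(array_de["signed_fc"].abs().sort_values(ascending=False).index)
    array_de = array_de.head(config.n_qpcr_candidates).reset_index(drop=True)
    counts["qpcr_candidates"] = len(array_de)

    rng = np.random.default_rng([5, sim_cfg.seed])
    null_pool = sorted(truth.null_mirnas() - set(array_de["feature_id"]))
    ref_candidates = list(rng.choice(null_pool, size=min(config.n_reference_candidates, len(null_pool)), replace=False))
    ct = simulate_qpcr(sim_cfg, truth, list(array_de["feature_id"]) + ref_candidates)
    references, ref_report = select_references(ref_candidates, ct)
    counts["qpcr_references"] = len(references)
    metrics["reference_min_ct_sd"] = float(ref_report["ct_sd"].min())

    case, control = sim_cfg.genotypes
    qpcr_fcs = {}
    for fid, tp in zip(array_de["feature_id"], array_de["feature_id"].map(anchor)):
        case_samples = [f"{case}_{tp}_{r}" for r in range(1, sim_cfg.n_replicates + 1)]
        ctrl_samples = [f"{control}_{tp}_{r}" for r in range(1, sim_cfg.n_replicates + 1)]
        qpcr_fcs[fid] = ddct_fold_change(ct, fid, references, case_samples, ctrl_samples)
    summary = validate_candidates(array_de, qpcr_fcs, alpha=config.alpha)
    for key in ("up_tested", "up_confirmed", "up_pct", "down_tested", "down_confirmed", "down_pct", "overall_tested", "overall_confirmed", "overall_pct"):
        metrics[f"qpcr_{key}"] = summary.attrs[key]
    return summary


def _truth_metrics(truth, mirna_filtered, labels, nets, enrichment, group_a, group_b, mid_tp, last_tp, metrics):
    planted = truth.de_mirnas
    if len(planted):
        planted_a = set(planted.index[planted["group"] == "A"])
        planted_b = set(planted.index[planted["group"] == "B"])
        if planted_a:
            metrics["group_a_recall"] = len(planted_a & set(group_a)) / len(planted_a)
        if planted_b:
            metrics["group_b_recall"] = len(planted_b & set(group_b)) / len(planted_b)
    a17 = nets.get("A17")
    if a17 is not None and len(planted):
        true_a = truth.true_targets[truth.true_targets["mirna_id"].isin(planted.index[planted["group"] == "A"])]
        if len(true_a):
            true_pairs = set(zip(true_a["mirna_id"], true_a["gene_id"]))
            edge_pairs = set(zip(a17.edges["mirna_id"], a17.edges["gene_id"]))
            metrics["a17_true_regulation_recall"] = len(true_pairs & edge_pairs) / len(true_pairs)
            if edge_pairs:
                all_true = set(zip(truth.true_targets["mirna_id"], truth.true_targets["gene_id"]))
                metrics["a17_edge_precision"] = len(edge_pairs & all_true) / len(edge_pairs)
    if truth.planted_terms and len(enrichment) and int(enrichment["k"].sum()) > 0:
        top = set(enrichment.head(len(truth.planted_terms))["term_id"])
        metrics["planted_terms_in_top"] = len(top & set(truth.planted_terms)) / len(truth.planted_terms)


def _write_outputs(out, sim, predictions, annotation, mirna_de, mrna_de, mirna_filtered, mrna_filtered, labels, nets, enrichment, qpcr_summary):
    sim.mirna.to_tsv(out / "mirna_expression.tsv")
    sim.mrna.to_tsv(out / "mrna_expression.tsv")
    sim.mirna_calls.to_tsv(out / "mirna_detection.tsv")
    sim.mrna_calls.to_tsv(out / "mrna_detection.tsv")
    predictions.to_tsv(out / "predictions.tsv")
    write_gmt(annotation, out / "annotation.gmt")
    write_ground_truth(sim.truth, out / "ground_truth.tsv")
    pd.concat(mirna_de.values(), ignore_index=True).to_csv(out / "mirna_de_full.tsv", sep="\t", index=False)
    pd.concat(mrna_de.values(), ignore_index=True).to_csv(out / "mrna_de_full.tsv", sep="\t", index=False)
    pd.concat(mirna_filtered.values(), ignore_index=True).to_csv(out / "mirna_de_filtered.tsv", sep="\t", index=False)
    pd.concat(mrna_filtered.values(), ignore_index=True).to_csv(out / "mrna_de_filtered.tsv", sep="\t", index=False)
    pd.DataFrame({"feature_id": list(labels), "group": [g.value for g in labels.values()]}).to_csv(
        out / "group_assignments.tsv", sep="\t", index=False
    )
    for name, net in nets.items():
        export_network(net, "tsv", out / f"network_{name}.tsv")
        export_network(net, "sif", out / f"network_{name}.sif")
        export_network(net, "graphml", out / f"network_{name}.graphml")
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if qpcr_summary is not None:
        qpcr_summary.to_csv(out / "qpcr_validation.tsv", sep="\t", index=False)
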