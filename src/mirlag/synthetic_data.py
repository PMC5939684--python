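"""Seeded generators emulating the rd10 time-course study design.

The generators plant a known ground truth into miRNA/mRNA expression
matrices (two genotypes x three postnatal timepoints x triplicates), a
target-prediction table, gene-set annotation and qPCR Ct tables, so every
downstream stage of the pipeline can be scored against what was planted.

Temporal templates mirror the biology: photoreceptor apoptosis in the
rd10 retina starts between P15.5 and P16, so group-A miRNAs carry their
planted effect already at P15 (optionally, smaller, at P13) and keep it
at P17, while group-B miRNAs shift only at P17.  True target mRNAs
respond with the opposite sign one timepoint later than their regulator
becomes active (group-A targets at P17 by default — the time-lagged
signature), group-B targets at P17.

Signals are simulated on the log2 scale (additive noise) and exported
linear.  A detection call is present iff the signal exceeds the 0.95
quantile of the background model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .preprocessing import DetectionCalls, ExpressionMatrix
from .qpcr import CtTable
from .target_networks import TargetPredictionTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExpression",
    "simulate_expression",
    "simulate_prediction_table",
    "simulate_annotation",
    "simulate_qpcr",
    "write_ground_truth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for the synthetic generators.

    Defaults reproduce the study conditions: ~1900 miRNA features, a
    larger mRNA panel, rd10 vs WT at P13/P15/P17 in triplicate, planted
    |log2 ratio| 1.5 for DE miRNAs (|FC| ~2.83, above the ±1.5 cutoff)
    and 0.6 for responding targets (|FC| ~1.52, above ±1.3), and a DE
    fraction of 8% (frac_groupA + frac_groupB) matching the scale of DE
    calls reported on this design.
    """

    n_mirna: int = 1900
    n_mrna: int = 5000
    genotypes: tuple[str, str] = ("rd10", "WT")  # (case, control)
    timepoints: tuple[str, ...] = ("P13", "P15", "P17")
    n_replicates: int = 3
    frac_groupA: float = 0.03
    frac_groupB: float = 0.05
    effect_log2: float = 1.5
    mrna_effect_log2: float = 0.6
    noise_sd: float = 0.25
    background_mu: float = 6.0       # log2 scale
    background_sd: float = 0.5
    frac_background: float = 0.2
    baseline_log2_range: tuple[float, float] = (8.5, 13.0)
    groupA_p13_effect: float = 0.0   # optional smaller pre-P15 effect, off by default
    groupA_targets_respond_p15: bool = False
    prob_up: float = 0.5
    detection_quantile: float = 0.95
    targets_per_mirna: int = 8
    false_prediction_rate: float = 5e-4
    spurious_support_probs: tuple[float, ...] = (0.6, 0.25, 0.1, 0.05)
    algo_names: tuple[str, ...] = ("miRWalk", "miRanda", "TargetScan", "RNA22")
    n_planted_terms: int = 5
    n_decoy_terms: int = 50
    term_size: int = 25
    planted_term_purity: float = 0.8
    ct_intercept: float = 32.0
    ct_tech_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_mrna, self.n_replicates, self.targets_per_mirna) <= 0:
            raise ValueError("all counts must be positive")
        if self.frac_groupA < 0 or self.frac_groupB < 0 or self.frac_groupA + self.frac_groupB > 1:
            raise ValueError("require frac_groupA, frac_groupB >= 0 and their sum <= 1")
        if self.noise_sd < 0 or self.background_sd < 0 or self.ct_tech_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be distinct ordered labels")
        if len(self.algo_names) < 2:
            raise ValueError("need at least two prediction algorithms")
        if len(self.spurious_support_probs) != len(self.algo_names):
            raise ValueError("spurious_support_probs must give one weight per support count 1..n_algorithms")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}_{tp}_{r}"
            for g in self.genotypes
            for tp in self.timepoints
            for r in range(1, self.n_replicates + 1)
        ]

    @property
    def group_keys(self) -> list[str]:
        return [f"{g}_{tp}" for g in self.genotypes for tp in self.timepoints]


@dataclass
class GroundTruth:
    """What was planted: DE miRNAs, true regulations, and true mean signals.

    ``de_mirnas`` is indexed by miRNA id with columns ``group`` (A/B),
    ``direction`` (+1/-1) and one true log2-ratio column ``lr_<tp>`` per
    timepoint.  ``true_targets`` lists (mirna_id, gene_id,
    response_timepoint, gene_direction) regulations.  ``true_log2_*``
    hold each feature's noise-free log2 mean per genotype x timepoint
    group.  ``planted_terms`` is filled by :func:`simulate_annotation`.
    """

    de_mirnas: pd.DataFrame
    true_targets: pd.DataFrame
    true_log2_mirna: pd.DataFrame
    true_log2_mrna: pd.DataFrame
    background_mirnas: set[str]
    background_mrnas: set[str]
    planted_terms: dict[str, set[str]] = field(default_factory=dict)

    def null_mirnas(self) -> set[str]:
        return set(self.true_log2_mirna.index) - set(self.de_mirnas.index) - self.background_mirnas


@dataclass
class SimulatedExpression:
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    mirna_calls: DetectionCalls
    mrna_calls: DetectionCalls
    truth: GroundTruth


def _feature_ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _simulate_panel(
    rng: np.random.Generator,
    ids: list[str],
    config: SimulationConfig,
    true_log2: pd.DataFrame,
    background: set[str],
) -> tuple[ExpressionMatrix, DetectionCalls]:
    """Draw linear signals and detection calls from per-group true log2 means."""
    samples = config.sample_ids
    n, s = len(ids), len(samples)
    is_bg = np.array([f in background for f in ids])
    group_of_sample = [sid.rsplit("_", 1)[0] for sid in samples]
    means = true_log2.loc[ids, group_of_sample].to_numpy()
    log2_vals = means + rng.normal(0.0, config.noise_sd, size=(n, s))
    # background probes: pure background draws, unaffected by replicate noise model
    n_bg = int(is_bg.sum())
    if n_bg:
        log2_vals[is_bg] = rng.normal(config.background_mu, config.background_sd, size=(n_bg, s))
    threshold = config.background_mu + norm.ppf(config.detection_quantile) * config.background_sd
    calls = log2_vals > threshold
    matrix = ExpressionMatrix(pd.DataFrame(2.0 ** log2_vals, index=ids, columns=samples))
    return matrix, DetectionCalls(pd.DataFrame(calls, index=ids, columns=samples))


def simulate_expression(config: SimulationConfig) -> SimulatedExpression:
    """Generate the miRNA and mRNA panels with planted ground truth.

    Deterministic in (config, config.seed): identical configs give
    byte-identical matrices.
    """
    rng = np.random.default_rng([1, config.seed])
    case, _ = config.genotypes
    tps = list(config.timepoints)
    mirna_ids = _feature_ids("miR_", config.n_mirna)
    gene_ids = _feature_ids("gene_", config.n_mrna)

    n_bg_mi = round(config.frac_background * config.n_mirna)
    n_bg_g = round(config.frac_background * config.n_mrna)
    bg_mirnas = set(rng.choice(mirna_ids, size=n_bg_mi, replace=False)) if n_bg_mi else set()
    bg_genes = set(rng.choice(gene_ids, size=n_bg_g, replace=False)) if n_bg_g else set()
    expressed_mi = [f for f in mirna_ids if f not in bg_mirnas]
    expressed_g = [g for g in gene_ids if g not in bg_genes]

    lo, hi = config.baseline_log2_range
    base_mi = pd.Series(rng.uniform(lo, hi, size=config.n_mirna), index=mirna_ids)
    base_g = pd.Series(rng.uniform(lo, hi, size=config.n_mrna), index=gene_ids)

    n_a = round(config.frac_groupA * config.n_mirna)
    n_b = round(config.frac_groupB * config.n_mirna)
    if n_a + n_b > len(expressed_mi):
        raise ValueError("too few expressed miRNAs for the requested DE fractions")
    de_ids = list(rng.choice(expressed_mi, size=n_a + n_b, replace=False))
    groups = ["A"] * n_a + ["B"] * n_b
    directions = np.where(rng.random(n_a + n_b) < config.prob_up, 1, -1)
    # temporal templates by position: group A active from the mid timepoint
    # (optionally, smaller, from the first), group B only at the last
    first_tp, mid_tp, last_tp = tps[0], tps[len(tps) // 2], tps[-1]
    lr = {tp: np.zeros(n_a + n_b) for tp in tps}
    for i, (grp, d) in enumerate(zip(groups, directions)):
        if grp == "A":
            lr[first_tp][i] = d * config.groupA_p13_effect
            lr[mid_tp][i] = d * config.effect_log2
            lr[last_tp][i] = d * config.effect_log2
        else:
            lr[last_tp][i] = d * config.effect_log2
    de_mirnas = pd.DataFrame(
        {"group": groups, "direction": directions, **{f"lr_{tp}": lr[tp] for tp in tps}},
        index=pd.Index(de_ids, name="feature_id"),
    )

    # true regulations: each DE miRNA represses (or releases) distinct target genes,
    # which respond with the opposite sign one timepoint after the regulator turns on
    n_targets = config.targets_per_mirna * len(de_ids)
    if n_targets > len(expressed_g):
        raise ValueError("too few expressed genes for targets_per_mirna")
    target_pool = list(rng.choice(expressed_g, size=n_targets, replace=False))
    target_rows = []
    for i, mid in enumerate(de_ids):
        for g in target_pool[i * config.targets_per_mirna : (i + 1) * config.targets_per_mirna]:
            target_rows.append((mid, g, last_tp, -int(directions[i])))
    true_targets = pd.DataFrame(target_rows, columns=["mirna_id", "gene_id", "response_timepoint", "gene_direction"])

    group_keys = config.group_keys
    true_log2_mi = pd.DataFrame(
        np.repeat(base_mi.to_numpy()[:, None], len(group_keys), axis=1), index=mirna_ids, columns=group_keys
    )
    for tp in tps:
        true_log2_mi.loc[de_ids, f"{case}_{tp}"] += lr[tp]
    true_log2_g = pd.DataFrame(
        np.repeat(base_g.to_numpy()[:, None], len(group_keys), axis=1), index=gene_ids, columns=group_keys
    )
    gene_effect = pd.Series(
        true_targets["gene_direction"].to_numpy(dtype=float) * config.mrna_effect_log2,
        index=true_targets["gene_id"],
    )
    responding_tps: dict[str, list[str]] = {g: [last_tp] for g in gene_effect.index}
    if config.groupA_targets_respond_p15:
        a_genes = true_targets.loc[true_targets["mirna_id"].isin(de_mirnas.index[de_mirnas["group"] == "A"]), "gene_id"]
        for g in a_genes:
            responding_tps[g].append(mid_tp)
    for g, eff in gene_effect.items():
        for tp in responding_tps[g]:
            true_log2_g.loc[g, f"{case}_{tp}"] += eff

    truth = GroundTruth(de_mirnas, true_targets, true_log2_mi, true_log2_g, bg_mirnas, bg_genes)
    mirna_mat, mirna_calls = _simulate_panel(rng, mirna_ids, config, true_log2_mi, bg_mirnas)
    mrna_mat, mrna_calls = _simulate_panel(rng, gene_ids, config, true_log2_g, bg_genes)
    return SimulatedExpression(mirna_mat, mrna_mat, mirna_calls, mrna_calls, truth)


def simulate_prediction_table(config: SimulationConfig, truth: GroundTruth) -> TargetPredictionTable:
    """Target predictions: all true pairs (support >= 2) plus spurious pairs.

    Spurious (miRNA, gene) pairs appear with probability
    ``false_prediction_rate`` each; their supporting-algorithm count is
    drawn from ``spurious_support_probs`` (count 1, 2, ... in order), so a
    configurable fraction carries only single-algorithm support.
    """
    rng = np.random.default_rng([2, config.seed])
    mirna_ids = list(truth.true_log2_mirna.index)
    gene_ids = list(truth.true_log2_mrna.index)
    if len(mirna_ids) != config.n_mirna or len(gene_ids) != config.n_mrna:
        raise ValueError("ground truth id space does not match the config dimensions")
    algos = list(config.algo_names)
    n_algo = len(algos)

    rows: list[tuple[str, str, frozenset]] = []
    true_pairs = set(zip(truth.true_targets["mirna_id"], truth.true_targets["gene_id"]))
    for m, g in zip(truth.true_targets["mirna_id"], truth.true_targets["gene_id"]):
        support = int(rng.integers(2, n_algo + 1))
        rows.append((m, g, frozenset(rng.choice(algos, size=support, replace=False))))

    n_pairs = config.n_mirna * config.n_mrna - len(true_pairs)
    n_spurious = rng.binomial(n_pairs, config.false_prediction_rate)
    probs = np.asarray(config.spurious_support_probs, dtype=float)
    probs = probs / probs.sum()
    seen = set(true_pairs)
    while n_spurious > 0:
        mi = rng.choice(mirna_ids, size=n_spurious)
        gi = rng.choice(gene_ids, size=n_spurious)
        for m, g in zip(mi, gi):
            if (m, g) in seen:
                continue
            seen.add((m, g))
            support = int(rng.choice(np.arange(1, n_algo + 1), p=probs))
            rows.append((m, g, frozenset(rng.choice(algos, size=support, replace=False))))
            n_spurious -= 1
    return TargetPredictionTable(pd.DataFrame(rows, columns=["mirna_id", "gene_id", "algorithms"]))


def simulate_annotation(config: SimulationConfig, truth: GroundTruth) -> dict[str, tuple[str, set[str]]]:
    """Gene-set annotation with terms enriched among responding target genes.

    Planted terms draw ``planted_term_purity`` of their members from the
    true-target genes and the rest at random; decoy terms are uniform
    draws from the whole mRNA panel.  Planted term ids are recorded in
    ``truth.planted_terms``.
    """
    rng = np.random.default_rng([4, config.seed])
    gene_ids = list(truth.true_log2_mrna.index)
    responding = list(pd.unique(truth.true_targets["gene_id"]))
    annotation: dict[str, tuple[str, set[str]]] = {}
    truth.planted_terms = {}
    for i in range(1, config.n_planted_terms + 1):
        n_resp = min(round(config.planted_term_purity * config.term_size), len(responding))
        members = set(rng.choice(responding, size=n_resp, replace=False)) if n_resp else set()
        while len(members) < config.term_size:
            members.add(str(rng.choice(gene_ids)))
        term_id = f"PLT{i:04d}"
        annotation[term_id] = (f"planted term {i}", members)
        truth.planted_terms[term_id] = members
    for i in range(1, config.n_decoy_terms + 1):
        members = set(rng.choice(gene_ids, size=config.term_size, replace=False))
        annotation[f"RND{i:04d}"] = (f"random term {i}", members)
    return annotation


def simulate_qpcr(config: SimulationConfig, truth: GroundTruth, features: list[str]) -> CtTable:
    """qPCR Ct tables for the requested features, triplicate technical reps.

    Ct = intercept - (true log2 expression + biological noise) + technical
    noise.  Non-DE features have genotype- and timepoint-invariant true
    expression, so any of them can serve as a stability reference.
    """
    rng = np.random.default_rng([3, config.seed])
    rows = []
    for f in features:
        if f in truth.true_log2_mirna.index:
            means = truth.true_log2_mirna.loc[f]
        elif f in truth.true_log2_mrna.index:
            means = truth.true_log2_mrna.loc[f]
        else:
            raise KeyError(f"unknown feature id {f!r}")
        for sid in config.sample_ids:
            group = sid.rsplit("_", 1)[0]
            bio = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
            base_ct = config.ct_intercept - (float(means[group]) + bio)
            for rep in range(1, 4):
                tech = rng.normal(0.0, config.ct_tech_sd) if config.ct_tech_sd else 0.0
                rows.append((f, sid, rep, base_ct + tech))
    return CtTable(pd.DataFrame(rows, columns=["feature_id", "sample_id", "tech_rep", "ct"]))


def write_ground_truth(truth: GroundTruth, path) -> None:
    """TSV sidecar of the planted DE miRNAs and true regulations."""
    de = truth.de_mirnas.reset_index()
    de["record"] = "de_mirna"
    tt = truth.true_targets.copy()
    tt["record"] = "true_target"
    pd.concat([de, tt], ignore_index=True).to_csv(path, sep="\t", index=False)
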