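"""Signed fold changes, Welch tests and the candidate-selection filters.

Each comparison contrasts two genotype x timepoint groups (mutant vs
age-matched wild type, or mutant vs its own pre-onset baseline).  Testing
is per feature on log2 signals with Benjamini-Hochberg adjustment across
the features of one comparison; fold changes are reported in the signed
convention (ratio r becomes r when r >= 1 and -1/r otherwise, so
down-regulation reads as a negative magnitude >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import DetectionCalls, ExpressionMatrix

__all__ = [
    "Comparison",
    "signed_fold_change",
    "differential_expression",
    "apply_de_filters",
    "apply_quality_exclusions",
    "merge_platform_candidates",
    "estimate_background_level",
]

DE_COLUMNS = [
    "feature_id",
    "comparison",
    "signed_fc",
    "log2fc",
    "p_raw",
    "p_adj",
    "mean_case",
    "mean_control",
    "replicate_cv",
]


@dataclass(frozen=True)
class Comparison:
    """A case-vs-control contrast between two genotype x timepoint groups."""

    case: tuple[str, str]
    control: tuple[str, str]

    def __post_init__(self) -> None:
        if self.case == self.control:
            raise ValueError("case and control groups must differ")

    @property
    def label(self) -> str:
        return f"{self.case[0]}_{self.case[1]}_vs_{self.control[0]}_{self.control[1]}"


def signed_fold_change(mean_case: float, mean_control: float) -> float:
    """Map the linear ratio case/control to the signed convention.

    Returns the ratio itself when >= 1 and minus its reciprocal otherwise,
    so e.g. a ratio of 0.568 is reported as -1.76.
    """
    if mean_case <= 0 or mean_control <= 0:
        raise ValueError("group means must be positive")
    r = mean_case / mean_control
    return r if r >= 1 else -1.0 / r


def _signed_fc_vec(ratio: np.ndarray) -> np.ndarray:
    return np.where(ratio >= 1, ratio, -1.0 / ratio)


def differential_expression(matrix: ExpressionMatrix, comparison: Comparison) -> pd.DataFrame:
    """Per-feature Welch t-test on log2 signals for one comparison.

    Returns a DataFrame with one row per feature: signed fold change from
    linear group means, log2 fold change, raw and BH-adjusted p values,
    group means, and the larger of the two within-group linear CVs.
    Features with zero variance on both sides and equal means get p = 1.
    """
    case_cols = matrix.group_columns(*comparison.case)
    ctrl_cols = matrix.group_columns(*comparison.control)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError(
            f"need >=2 replicates per side for {comparison.label}; "
            f"got {len(case_cols)} case and {len(ctrl_cols)} control"
        )
    case = matrix.values[case_cols].to_numpy(dtype=float)
    ctrl = matrix.values[ctrl_cols].to_numpy(dtype=float)
    if (case <= 0).any() or (ctrl <= 0).any():
        raise ValueError("signals must be positive for log2 testing")

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(np.log2(case), np.log2(ctrl), axis=1, equal_var=False)
        p_raw = np.asarray(res.pvalue, dtype=float)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    # degenerate features (no variance on either side): p=1 if means equal, else ~0
    degenerate = ~np.isfinite(p_raw)
    p_raw[degenerate & np.isclose(mean_case, mean_ctrl)] = 1.0
    p_raw[degenerate & ~np.isclose(mean_case, mean_ctrl)] = 0.0

    p_adj = multipletests(p_raw, method="fdr_bh")[1] if len(p_raw) else np.array([])
    cv_case = case.std(axis=1, ddof=1) / mean_case
    cv_ctrl = ctrl.std(axis=1, ddof=1) / mean_ctrl
    ratio = mean_case / mean_ctrl
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "comparison": comparison.label,
            "signed_fc": _signed_fc_vec(ratio),
            "log2fc": np.log2(ratio),
            "p_raw": p_raw,
            "p_adj": np.maximum(p_adj, p_raw),
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "replicate_cv": np.maximum(cv_case, cv_ctrl),
        }
    )


def apply_de_filters(results: pd.DataFrame, fc_cutoff: float, alpha: float = 0.05) -> pd.DataFrame:
    """Keep features passing both |signed FC| >= cutoff and adjusted p < alpha."""
    if fc_cutoff < 1:
        raise ValueError("fc_cutoff must be >= 1 in the signed convention")
    if results.empty:
        return results.copy()
    keep = (results["signed_fc"].abs() >= fc_cutoff) & (results["p_adj"] < alpha)
    return results.loc[keep].reset_index(drop=True)


def estimate_background_level(matrix: ExpressionMatrix, calls: DetectionCalls) -> float:
    """Background signal level: median signal of features absent in every array.

    Falls back to the matrix-wide lower 5% quantile when every feature was
    detected somewhere (no fully-absent feature to anchor the estimate).
    """
    never = ~calls.calls.any(axis=1)
    vals = matrix.values.to_numpy(dtype=float)
    if never.any():
        return float(np.median(matrix.values.loc[never.to_numpy()].to_numpy()))
    return float(np.quantile(vals, 0.05)) if vals.size else 0.0


def apply_quality_exclusions(
    results: pd.DataFrame,
    matrix: ExpressionMatrix,
    calls: DetectionCalls,
    background_margin: float = 1.2,
    cv_max: float = 0.5,
) -> pd.DataFrame:
    """Drop near-background features and features with noisy replicates.

    A feature is excluded when its median normalized signal falls below
    ``background_margin`` times the estimated background level, or when its
    replicate CV (linear scale, worst of the two comparison groups) exceeds
    ``cv_max``.
    """
    if background_margin <= 0 or cv_max <= 0:
        raise ValueError("thresholds must be positive")
    if results.empty:
        return results.copy()
    background = estimate_background_level(matrix, calls)
    medians = matrix.values.median(axis=1)
    above = results["feature_id"].map(medians) >= background_margin * background
    steady = results["replicate_cv"] <= cv_max
    return results.loc[above & steady].reset_index(drop=True)


def merge_platform_candidates(list_a: pd.DataFrame, list_b: pd.DataFrame) -> pd.DataFrame:
    """Union candidate lists from two platforms, deduplicated by feature id.

    When both platforms report a feature, the first platform's row is kept;
    a ``direction_conflict`` flag marks features whose fold-change signs
    disagree between platforms.
    """
    merged = pd.concat([list_a, list_b], ignore_index=True)
    if merged.empty:
        out = merged.copy()
        out["direction_conflict"] = pd.Series(dtype=bool)
        return out
    sign = np.sign(merged["signed_fc"])
    conflict = (
        pd.DataFrame({"feature_id": merged["feature_id"], "sign": sign})
        .groupby("feature_id")["sign"]
        .nunique()
        .gt(1)
    )
    out = merged.drop_duplicates(subset="feature_id", keep="first").reset_index(drop=True)
    out["direction_conflict"] = out["feature_id"].map(conflict).fillna(False).astype(bool)
    return out
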