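"""Reference-gene selection and ddCt relative quantification.

qPCR validation normalizes each target's threshold cycle (Ct) to the mean
Ct of reference assays chosen for their expression stability (lowest Ct
standard deviation across biological samples).  Relative quantity follows
the ddCt model with amplification efficiency fixed at 2:

    dCt   = Ct(target) - mean Ct(references)        per biological sample
    ddCt  = mean dCt(case) - mean dCt(control)
    ratio = 2^(-ddCt), reported as a signed fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential_expression import signed_fold_change
from .preprocessing import parse_sample_id

__all__ = [
    "CtTable",
    "read_ct_table",
    "select_references",
    "ddct_fold_change",
    "validate_candidates",
]

CT_COLUMNS = ["feature_id", "sample_id", "tech_rep", "ct"]


@dataclass
class CtTable:
    """Long-form qPCR table: one row per (feature, biological sample, tech rep)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["ct"].to_numpy(dtype=float)).all():
            raise ValueError("Ct values must be finite")
        for s in self.table["sample_id"].unique():
            parse_sample_id(s)

    def mean_ct(self, feature_id: str) -> pd.Series:
        """Mean over technical replicates, indexed by biological sample."""
        sub = self.table.loc[self.table["feature_id"] == feature_id]
        if sub.empty:
            raise KeyError(f"no Ct measurements for {feature_id!r}")
        return sub.groupby("sample_id")["ct"].mean()

    def features(self) -> list[str]:
        return list(self.table["feature_id"].unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"))


def select_references(
    candidates: list[str],
    ct_table: CtTable,
    n_references: int = 2,
) -> tuple[list[str], pd.DataFrame]:
    """Pick the most stable reference assays and report pairwise agreement.

    Candidates are ranked by the standard deviation of their mean Ct across
    biological samples (lower = more stable); the ``n_references`` most
    stable are returned together with a report holding each candidate's Ct
    SD and all pairwise r-squared values of their Ct profiles.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two reference candidates")
    profiles = {}
    samples = None
    for c in candidates:
        prof = ct_table.mean_ct(c)
        if samples is None:
            samples = prof.index
        elif not prof.index.equals(samples):
            raise ValueError(f"candidate {c!r} lacks Ct coverage on some samples")
        profiles[c] = prof
    sd = pd.Series({c: float(p.std(ddof=1)) for c, p in profiles.items()}, name="ct_sd")
    ranked = sd.sort_values(kind="mergesort")
    prof_df = pd.DataFrame(profiles)
    r2 = prof_df.corr() ** 2
    report = pd.DataFrame({"ct_sd": ranked})
    report["rank"] = range(1, len(ranked) + 1)
    for c in candidates:
        report[f"r2_{c}"] = r2.loc[report.index, c]
    return list(ranked.index[:n_references]), report


def _delta_ct(ct_table: CtTable, target: str, references: list[str], samples: list[str]) -> np.ndarray:
    tgt = ct_table.mean_ct(target)
    refs = pd.concat([ct_table.mean_ct(r) for r in references], axis=1)
    missing = [s for s in samples if s not in tgt.index or s not in refs.index]
    if missing:
        raise ValueError(f"target or reference not measured in samples {missing}")
    return (tgt.loc[samples] - refs.loc[samples].mean(axis=1)).to_numpy(dtype=float)


def ddct_fold_change(
    ct_table: CtTable,
    target: str,
    references: list[str],
    case_samples: list[str],
    control_samples: list[str],
) -> tuple[float, float]:
    """Signed fold change and p value for one target via the ddCt model.

    The p value comes from a two-sample Welch t-test on the per-sample
    reference-normalized dCt values; degenerate zero-variance inputs give
    p = 1 when the group means agree and p = 0 otherwise.
    """
    if not case_samples or not control_samples:
        raise ValueError("sample groups must be non-empty")
    dct_case = _delta_ct(ct_table, target, references, case_samples)
    dct_ctrl = _delta_ct(ct_table, target, references, control_samples)
    ddct = dct_case.mean() - dct_ctrl.mean()
    fc = signed_fold_change(2.0 ** (-ddct), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = float(stats.ttest_ind(dct_case, dct_ctrl, equal_var=False).pvalue)
    if not np.isfinite(p):
        p = 1.0 if np.isclose(ddct, 0.0) else 0.0
    return fc, p


def validate_candidates(
    array_de: pd.DataFrame,
    qpcr_fcs: dict[str, tuple[float, float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cross-technique confirmation of array candidates by qPCR.

    ``array_de`` needs columns ``feature_id`` and ``signed_fc``;
    ``qpcr_fcs`` maps each candidate to its (signed FC, p).  A candidate
    is confirmed when both techniques agree in direction and the qPCR p
    is below ``alpha``.  Returns a per-candidate table whose ``.attrs``
    carry tested/confirmed counts and confirmation percentages stratified
    by array direction (up, down, overall).
    """
    missing = set(array_de["feature_id"]) - set(qpcr_fcs)
    if missing:
        raise ValueError(f"candidates missing a qPCR measurement: {sorted(missing)[:5]}")
    rows = []
    for fid, array_fc in zip(array_de["feature_id"], array_de["signed_fc"]):
        q_fc, q_p = qpcr_fcs[fid]
        confirmed = (np.sign(array_fc) == np.sign(q_fc)) and (q_p < alpha)
        rows.append((fid, float(array_fc), float(q_fc), float(q_p), bool(confirmed)))
    summary = pd.DataFrame(rows, columns=["feature_id", "array_fc", "qpcr_fc", "qpcr_p", "confirmed"])
    stats_out = {}
    for label, mask in {
        "up": summary["array_fc"] > 0,
        "down": summary["array_fc"] < 0,
        "overall": pd.Series(True, index=summary.index),
    }.items():
        tested = int(mask.sum())
        confirmed = int(summary.loc[mask, "confirmed"].sum())
        stats_out[f"{label}_tested"] = tested
        stats_out[f"{label}_confirmed"] = confirmed
        stats_out[f"{label}_pct"] = 100.0 * confirmed / tested if tested else float("nan")
    summary.attrs.update(stats_out)
    return summary
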