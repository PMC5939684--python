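"""Classify differentially expressed miRNAs by temporal onset.

Photoreceptor apoptosis in the rd10 retina begins between P15.5 and P16.
miRNAs whose dysregulation is already significant before that onset
(P13/P15) form group A (candidate disease-etiology regulators); miRNAs
dysregulated only at P17, with no earlier filter-passing differential
expression, form group B (candidate compensatory/progression regulators).

Significance here always means "passed the candidate filters" (fold-change
cutoff and adjusted p), not merely a raw p value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

__all__ = ["GroupLabel", "TemporalProfile", "build_profiles", "classify_groups", "track_trajectory"]

TIMEPOINTS = ("P13", "P15", "P17")


class GroupLabel(str, Enum):
    A = "A"
    B = "B"
    UNASSIGNED = "unassigned"


@dataclass
class TemporalProfile:
    """Filter-passing significance pattern of one miRNA across comparisons.

    ``sig_vs_wt`` is keyed by timepoint (vs age-matched wild type);
    ``sig_vs_baseline`` by P15/P17 (vs the pre-onset rd10 P13 baseline —
    undefined at P13 itself).  ``direction`` records the fold-change sign
    of each significant comparison.
    """

    feature_id: str
    sig_vs_wt: dict[str, bool]
    sig_vs_baseline: dict[str, bool]
    direction: dict[str, int] = field(default_factory=dict)


def build_profiles(
    filtered: dict[str, pd.DataFrame],
    feature_ids: list[str],
    comparison_map: dict[str, str],
) -> list[TemporalProfile]:
    """Assemble per-miRNA profiles from filtered DE tables.

    ``filtered`` maps comparison labels to filter-passing DE tables;
    ``comparison_map`` maps the profile slots (``wt_P13``, ``wt_P15``,
    ``wt_P17``, ``base_P15``, ``base_P17``) to those labels.
    """
    sig_sets: dict[str, dict[str, int]] = {}
    for slot, label in comparison_map.items():
        table = filtered.get(label)
        if table is None or table.empty:
            sig_sets[slot] = {}
        else:
            signs = (table["signed_fc"] > 0).map({True: 1, False: -1})
            sig_sets[slot] = dict(zip(table["feature_id"], signs))
    profiles = []
    for fid in feature_ids:
        direction = {}
        sig_wt, sig_base = {}, {}
        for tp in TIMEPOINTS:
            slot = f"wt_{tp}"
            sig_wt[tp] = fid in sig_sets.get(slot, {})
            if sig_wt[tp]:
                direction[slot] = sig_sets[slot][fid]
        for tp in ("P15", "P17"):
            slot = f"base_{tp}"
            sig_base[tp] = fid in sig_sets.get(slot, {})
            if sig_base[tp]:
                direction[slot] = sig_sets[slot][fid]
        profiles.append(TemporalProfile(fid, sig_wt, sig_base, direction))
    return profiles


def classify_groups(
    profiles: list[TemporalProfile],
    require_p13: bool = False,
) -> dict[str, GroupLabel]:
    """Assign each profile to group A, group B or unassigned.

    Group A: significant before apoptosis onset — at P15 against both the
    age-matched wild type and the rd10 P13 baseline, or (disjunctive
    default) already at P13 vs wild type.  With ``require_p13=True`` the
    stricter conjunctive reading is used: P13 vs WT and P15 vs both
    references must all pass.

    Group B: significant at P17 against both references with no
    filter-passing differential expression at any earlier stage.  The two
    groups are mutually exclusive by construction.
    """
    labels: dict[str, GroupLabel] = {}
    for p in profiles:
        missing = set(TIMEPOINTS) - set(p.sig_vs_wt) or {"P15", "P17"} - set(p.sig_vs_baseline)
        if missing:
            warnings.warn(f"{p.feature_id}: missing comparison data for {sorted(missing)}; unassigned")
            labels[p.feature_id] = GroupLabel.UNASSIGNED
            continue
        p15_both = p.sig_vs_wt["P15"] and p.sig_vs_baseline["P15"]
        if require_p13:
            is_a = p.sig_vs_wt["P13"] and p15_both
        else:
            is_a = p15_both or p.sig_vs_wt["P13"]
        early_de = p.sig_vs_wt["P13"] or p.sig_vs_wt["P15"] or p.sig_vs_baseline["P15"]
        is_b = p.sig_vs_wt["P17"] and p.sig_vs_baseline["P17"] and not early_de and not is_a
        if is_a:
            labels[p.feature_id] = GroupLabel.A
        elif is_b:
            labels[p.feature_id] = GroupLabel.B
        else:
            labels[p.feature_id] = GroupLabel.UNASSIGNED
    return labels


def track_trajectory(feature_id: str, de_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Signed fold-change series of one feature across all comparisons.

    ``de_results`` maps comparison labels to full (unfiltered) DE tables.
    Returns one row per comparison in which the feature was tested, in the
    supplied order, with the signed FC and adjusted p.
    """
    rows = []
    for label, table in de_results.items():
        hit = table.loc[table["feature_id"] == feature_id]
        if hit.empty:
            raise KeyError(f"{feature_id} was not tested in comparison {label}")
        rows.append(
            {
                "comparison": label,
                "signed_fc": float(hit["signed_fc"].iloc[0]),
                "p_adj": float(hit["p_adj"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)
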