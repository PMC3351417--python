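"""Classification of treatment effects on disease-altered transcripts.

For each transcript, let ``d`` be the signed log2 fold change of the
diabetic group versus normal and ``t`` that of a treated group versus
normal.  With a change threshold tau (default 1.5, the same cutoff the
differential-expression routes use; theta = log2(tau)) and a margin ``m``
on the |log2| scale:

* disease-changed transcripts (|d| >= theta):
  **positive** (reversal toward normalcy) if |t| < |d| - m,
  **negative** (change beyond the diabetic level) if |t| > |d| + m,
  **unresponsive** otherwise;
* disease-unchanged transcripts (|d| < theta):
  **side_effect** if the therapy itself changes the transcript
  (|t| >= theta), **unaffected** otherwise.

"Toward normalcy" is strict shrinkage of |log2 fold| regardless of sign:
an overshoot past normal still counts as positive unless it exceeds the
diabetic displacement, in which case it is negative.  The five categories
are mutually exclusive and exhaustive for any finite (d, t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .models import ValidationError

CATEGORIES = ("positive", "negative", "unresponsive", "side_effect", "unaffected")
TREATMENTS = ("T1", "T2")  # RAGE inhibitor, p38 MAPK inhibitor
TREATMENT_GROUP = {"T1": "D_T1", "T2": "D_T2"}


@dataclass(frozen=True)
class ResponseConfig:
    """Thresholds for the response taxonomy."""

    tau: float = 1.5
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if self.margin < 0:
            raise ValidationError("margin must be >= 0")

    @property
    def theta(self) -> float:
        return math.log2(self.tau)


def classify(d: float, t: float, config: ResponseConfig = ResponseConfig()) -> str:
    """Category of one (disease, treated) signed-log2 fold pair."""
    if math.isnan(d) or math.isnan(t):
        raise ValidationError("classify requires non-NaN fold changes")
    theta = config.theta
    ad, at = abs(d), abs(t)
    if ad >= theta:
        if at < ad - config.margin:
            return "positive"
        if at > ad + config.margin:
            return "negative"
        return "unresponsive"
    return "side_effect" if at >= theta else "unaffected"


def classify_table(
    folds: pd.DataFrame, config: ResponseConfig = ResponseConfig()
) -> pd.DataFrame:
    """Classify every feature for both treatments.

    ``folds`` must carry signed log2 columns ``d`` (diabetic vs normal),
    ``t1`` and ``t2`` (each treated group vs normal); see
    :func:`signed_log2_columns` for building them from directional fold
    tables.  Returns a long table with one row per feature x treatment and
    a ``category`` column; per-category counts are in ``.attrs["summary"]``.
    """
    needed = {"d", "t1", "t2"}
    if not needed <= set(folds.columns):
        raise ValidationError(f"fold table must have columns {sorted(needed)}")
    rows = []
    for feature, row in folds.iterrows():
        for treatment in TREATMENTS:
            t = row["t1"] if treatment == "T1" else row["t2"]
            rows.append(
                {
                    "feature_id": feature,
                    "treatment": treatment,
                    "d": row["d"],
                    "t": t,
                    "category": classify(row["d"], t, config),
                }
            )
    calls = pd.DataFrame(rows)
    calls.attrs["summary"] = calls.groupby(["treatment", "category"]).size().to_dict()
    calls.attrs["config"] = {"tau": config.tau, "margin": config.margin}
    return calls


def signed_log2_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a directional fold table (ratio + direction per contrast)
    to signed log2 columns ``d``, ``t1``, ``t2``.

    Expects columns ``ratio_D``, ``dir_D``, ``ratio_T1``, ``dir_T1``,
    ``ratio_T2``, ``dir_T2`` as produced by the published-table loader.
    """
    out = {}
    for col, (ratio_col, dir_col) in {
        "d": ("ratio_D", "dir_D"),
        "t1": ("ratio_T1", "dir_T1"),
        "t2": ("ratio_T2", "dir_T2"),
    }.items():
        sign = np.where(table[dir_col] == "down", -1.0, 1.0)
        out[col] = sign * np.log2(table[ratio_col].astype(float))
    return pd.DataFrame(out, index=table.index)


SPLICE_CATEGORIES = (
    "responsive_to_T1_and_T2",
    "responsive_to_T1",
    "responsive_to_T2",
    "unresponsive_to_T1_and_T2",
    "exacerbated_by_T1",
    "exacerbated_by_T2",
    "exacerbated_by_T1_and_T2",
)


def splice_response_sets(
    d_events: pd.DataFrame,
    t1_events: pd.DataFrame,
    t2_events: pd.DataFrame,
) -> dict:
    """Partition splice events by their response to the two treatments.

    Inputs are the per-contrast event tables from the splicing scan
    (indexed by event id with a boolean ``passes`` column) for the
    disease, T1-treated, and T2-treated contrasts against normal.
    An event *responsive* to a treatment passes in the disease contrast
    but no longer in that treated contrast; *unresponsive* events pass in
    the disease contrast and in both treated contrasts; *exacerbated*
    events pass in a treated contrast without passing in the disease one.
    The seven categories partition the union of all passing events; the
    returned dict also carries the membership-region counts of the
    three passing sets and the union size.
    """
    def passing(events: pd.DataFrame) -> frozenset:
        if "passes" not in events.columns:
            raise ValidationError("event table lacks a 'passes' column")
        return frozenset(events.index[events["passes"].astype(bool)])

    in_d, in_t1, in_t2 = passing(d_events), passing(t1_events), passing(t2_events)
    union = in_d | in_t1 | in_t2
    sets = {
        "responsive_to_T1_and_T2": in_d - in_t1 - in_t2,
        "responsive_to_T1": (in_d - in_t1) & in_t2,
        "responsive_to_T2": (in_d - in_t2) & in_t1,
        "unresponsive_to_T1_and_T2": in_d & in_t1 & in_t2,
        "exacerbated_by_T1": (in_t1 - in_d) - in_t2,
        "exacerbated_by_T2": (in_t2 - in_d) - in_t1,
        "exacerbated_by_T1_and_T2": (in_t1 & in_t2) - in_d,
    }
    regions = {
        "D_only": len(in_d - in_t1 - in_t2),
        "T1_only": len(in_t1 - in_d - in_t2),
        "T2_only": len(in_t2 - in_d - in_t1),
        "D_and_T1": len((in_d & in_t1) - in_t2),
        "D_and_T2": len((in_d & in_t2) - in_t1),
        "T1_and_T2": len((in_t1 & in_t2) - in_d),
        "D_and_T1_and_T2": len(in_d & in_t1 & in_t2),
    }
    return {
        "sets": sets,
        "counts": {k: len(v) for k, v in sets.items()},
        "regions": regions,
        "union_size": len(union),
    }
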