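"""Assign participants to symptom clusters under the main and sensitivity criteria.

Membership of a symptom-cluster is defined on corrected item scores.  The
main criterion requires the *mean* corrected score over the cluster's items
to reach a severity threshold — at least mild (2) or at least moderate (3).
The sensitivity criteria replace the mean with *any* single symptom (max) or
*all* symptoms (min) reaching the threshold.  For a fixed threshold the three
criteria nest: all-membership implies mean-membership implies any-membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rpq_scoring import CorrectedScores

MILD = 2
MODERATE = 3

AGGREGATIONS = ("mean", "any", "all")


@dataclass(frozen=True)
class MembershipCriteria:
    """How a participant qualifies for a symptom-cluster.

    aggregation: "mean" (main analysis), "any" or "all" (sensitivity).
    severity_threshold: 2 (at least mild) or 3 (at least moderate),
    compared inclusively on the corrected 0-4 scale.
    """

    aggregation: str
    severity_threshold: int

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.severity_threshold not in (MILD, MODERATE):
            raise ValueError("severity_threshold must be 2 (mild) or 3 (moderate)")

    @property
    def label(self) -> str:
        level = "mild" if self.severity_threshold == MILD else "moderate"
        return f"{self.aggregation}_{level}"


@dataclass
class MembershipTable:
    """Participant x cluster binary membership under one criteria setting."""

    memberships: pd.DataFrame  # bool, one column per cluster
    criteria: MembershipCriteria

    def counts(self) -> pd.Series:
        return self.memberships.sum(axis=0)


def assign_membership(
    scores: CorrectedScores, clusters, criteria: MembershipCriteria
) -> MembershipTable:
    """Binary cluster membership per participant.

    mean mode: cluster mean >= threshold (exact rational comparison, no
    rounding); any mode: cluster max >= threshold; all mode: cluster min >=
    threshold.  Thresholds are inclusive.
    """
    label_to_idx = {lab: i for i, lab in enumerate(scores.item_labels)}
    t = criteria.severity_threshold
    cols: dict[str, np.ndarray] = {}
    for name, members in clusters.clusters.items():
        if not members:
            raise ValueError(f"cluster {name!r} is empty")
        idx = [label_to_idx[m] for m in members]
        sub = scores.corrected[:, idx]
        if criteria.aggregation == "mean":
            # sum >= t * size avoids float division entirely
            cols[name] = sub.sum(axis=1) >= t * len(idx)
        elif criteria.aggregation == "any":
            cols[name] = sub.max(axis=1) >= t
        else:
            cols[name] = sub.min(axis=1) >= t
    index = (
        pd.Index(scores.participant_ids, name="participant_id")
        if scores.participant_ids is not None
        else None
    )
    table = MembershipTable(pd.DataFrame(cols, index=index), criteria)
    _assert_nesting(scores, clusters, criteria, table)
    return table


def _assert_nesting(scores, clusters, criteria, table: MembershipTable) -> None:
    """Runtime invariant: all-membership <= mean-membership <= any-membership."""
    t = criteria.severity_threshold
    label_to_idx = {lab: i for i, lab in enumerate(scores.item_labels)}
    for name, members in clusters.clusters.items():
        idx = [label_to_idx[m] for m in members]
        sub = scores.corrected[:, idx]
        all_m = sub.min(axis=1) >= t
        mean_m = sub.sum(axis=1) >= t * len(idx)
        any_m = sub.max(axis=1) >= t
        if not (np.all(~all_m | mean_m) and np.all(~mean_m | any_m)):
            raise AssertionError(
                f"membership nesting violated for cluster {name!r}"
            )


def membership_under_all_criteria(
    scores: CorrectedScores, clusters, severity_threshold: int
) -> dict[str, MembershipTable]:
    """Membership tables for mean, any and all at one severity threshold."""
    return {
        agg: assign_membership(
            scores, clusters, MembershipCriteria(agg, severity_threshold)
        )
        for agg in AGGREGATIONS
    }
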