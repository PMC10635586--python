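"""Corrected RPQ-16 scoring, totals, thresholds, subscales, and duration groups.

The Rivermead Post Concussion Symptoms Questionnaire (RPQ-16) rates 16
symptoms relative to pre-injury levels on a five-point scale (0-4).  Before
any analysis, responses of 1 ("present but no more of a problem") are recoded
to 0, so corrected item scores live in {0, 2, 3, 4}.  Corrected totals of 16
or more mark clinically significant post-concussion symptomatology.  Cohorts
are stratified into an *early* group (concussion under 12 months ago) and a
*prolonged* group (12 months or more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("rpqcluster")

# Standard published RPQ-16 item order.
RPQ_ITEMS: tuple[str, ...] = (
    "headache",
    "dizziness",
    "nausea_vomiting",
    "noise_sensitivity",
    "sleep_disturbance",
    "fatigue",
    "irritability",
    "depression_tearfulness",
    "frustration",
    "forgetfulness",
    "poor_concentration",
    "longer_to_think",
    "blurred_vision",
    "light_sensitivity",
    "double_vision",
    "restlessness",
)

SEVERITY_LABELS: tuple[str, ...] = (
    "not experienced at all",
    "present but no more of a problem",
    "mild problem",
    "moderate problem",
    "severe problem",
)

N_ITEMS = 16
# First three items form the RPQ-3 subscale; the remaining thirteen the RPQ-13.
RPQ3_ITEMS: tuple[str, ...] = RPQ_ITEMS[:3]
RPQ13_ITEMS: tuple[str, ...] = RPQ_ITEMS[3:]

SIGNIFICANT_TOTAL_THRESHOLD = 16  # inclusive ("total corrected score >= 16")
PROLONGED_MONTHS = 12.0  # inclusive ("12 months or more")

SCORE_COLUMNS: tuple[str, ...] = tuple(f"rpq_{item}" for item in RPQ_ITEMS)


@dataclass(frozen=True)
class RPQItemSchema:
    """The ordered RPQ-16 item list and its five severity levels."""

    items: tuple[str, ...] = RPQ_ITEMS
    severity_labels: tuple[str, ...] = SEVERITY_LABELS

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(f"RPQ schema requires 16 items, got {len(self.items)}")
        if len(self.severity_labels) != 5:
            raise ValueError("RPQ schema requires 5 severity levels")

    @property
    def rpq3_items(self) -> tuple[str, ...]:
        return self.items[:3]

    @property
    def rpq13_items(self) -> tuple[str, ...]:
        return self.items[3:]


class ScoreValidationError(ValueError):
    """Raised for out-of-range or missing raw RPQ responses.

    The message names the offending participant (row) and item so data
    problems can be traced back to the source table.
    """


def _validate_raw(raw: np.ndarray, participant_ids=None) -> None:
    if raw.ndim != 2 or raw.shape[1] != N_ITEMS:
        raise ScoreValidationError(
            f"raw scores must have 16 item columns, got shape {raw.shape}"
        )
    bad = ~np.isin(raw, [0, 1, 2, 3, 4]) | np.isnan(raw.astype(float))
    if bad.any():
        row, col = np.argwhere(bad)[0]
        pid = participant_ids[row] if participant_ids is not None else row
        raise ScoreValidationError(
            f"invalid raw score {raw[row, col]!r} for participant {pid!r}, "
            f"item '{RPQ_ITEMS[col]}' (must be an integer 0..4)"
        )


def correct_scores(raw, participant_ids=None) -> np.ndarray:
    """Apply the RPQ score correction: responses of 1 are recoded to 0.

    Parameters
    ----------
    raw
        Array-like of shape (n, 16) with integer responses 0..4 (a single
        16-vector is also accepted).
    participant_ids
        Optional identifiers used in validation error messages.

    Returns
    -------
    ndarray of shape (n, 16) with values in {0, 2, 3, 4}.  Idempotent.
    """
    arr = np.asarray(raw)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr.reshape(1, -1)
    _validate_raw(arr, participant_ids)
    corrected = arr.astype(np.int64).copy()
    corrected[corrected == 1] = 0
    return corrected[0] if squeeze else corrected


@dataclass
class CorrectedScores:
    """Per-participant corrected scores with totals, flags and subscales."""

    corrected: np.ndarray  # (n, 16), values in {0, 2, 3, 4}
    total: np.ndarray  # (n,), 0..64
    significant_symptoms: np.ndarray  # (n,) bool, total >= 16
    rpq3_total: np.ndarray
    rpq13_total: np.ndarray
    participant_ids: np.ndarray | None = None
    item_labels: tuple[str, ...] = field(default=RPQ_ITEMS)

    def __len__(self) -> int:
        return self.corrected.shape[0]

    def cluster_means(self, cluster_set) -> pd.DataFrame:
        """Mean corrected score per symptom cluster, one column per cluster.

        ``cluster_set`` is a :class:`~rpqcluster.symptom_clustering.SymptomClusterSet`
        (anything exposing ``clusters: Mapping[str, tuple[str, ...]]``).
        """
        label_to_idx = {lab: i for i, lab in enumerate(self.item_labels)}
        data = {}
        for name, members in cluster_set.clusters.items():
            idx = [label_to_idx[m] for m in members]
            data[name] = self.corrected[:, idx].mean(axis=1)
        index = (
            pd.Index(self.participant_ids, name="participant_id")
            if self.participant_ids is not None
            else None
        )
        return pd.DataFrame(data, index=index)


def total_and_flags(corrected, participant_ids=None) -> CorrectedScores:
    """Compute totals, the >=16 significance flag, and RPQ-3 / RPQ-13 subscales."""
    arr = np.asarray(corrected)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != N_ITEMS:
        raise ScoreValidationError(
            f"corrected scores must have 16 columns, got {arr.shape[1]}"
        )
    if not np.isin(arr, [0, 2, 3, 4]).all():
        raise ScoreValidationError(
            "corrected scores must be in {0, 2, 3, 4}; run correct_scores first"
        )
    arr = arr.astype(np.int64)
    total = arr.sum(axis=1)
    return CorrectedScores(
        corrected=arr,
        total=total,
        significant_symptoms=total >= SIGNIFICANT_TOTAL_THRESHOLD,
        rpq3_total=arr[:, :3].sum(axis=1),
        rpq13_total=arr[:, 3:].sum(axis=1),
        participant_ids=None if participant_ids is None else np.asarray(participant_ids),
    )


def score_cohort(cohort: pd.DataFrame) -> CorrectedScores:
    """Correct and score a cohort table (see :mod:`rpqcluster.pipeline` schema).

    Rows with missing item responses are excluded (complete-case) with a
    logged count.
    """
    raw = cohort.loc[:, list(SCORE_COLUMNS)]
    complete = raw.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("excluding %d participants with missing RPQ item responses", n_dropped)
    kept = cohort.loc[complete]
    corrected = correct_scores(
        kept.loc[:, list(SCORE_COLUMNS)].to_numpy(),
        participant_ids=kept["participant_id"].to_numpy(),
    )
    return total_and_flags(corrected, participant_ids=kept["participant_id"].to_numpy())


def split_by_duration(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into (early, prolonged) by months since concussion.

    Prolonged means 12 months or more (the 12-month boundary is prolonged);
    early means under 12 months.  Rows with missing duration are excluded
    from both groups with a logged count.
    """
    months = pd.to_numeric(cohort["months_since_concussion"], errors="coerce")
    valid = months.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("excluding %d participants with missing duration", n_dropped)
    prolonged_mask = valid & (months >= PROLONGED_MONTHS)
    early_mask = valid & (months < PROLONGED_MONTHS)
    return cohort.loc[early_mask].copy(), cohort.loc[prolonged_mask].copy()
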