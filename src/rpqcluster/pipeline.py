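"""End-to-end orchestration, cohort CSV I/O, and result export.

``run_pipeline`` chains the stages — simulate/load, correct and score, split
by duration, Spearman-profile clustering, cluster formation, membership
assignment, and both association perspectives — and writes every intermediate
artifact plus a run log.  All randomness flows from one seed, so a run is
deterministic given (input, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association_analysis as assoc
from . import cluster_membership as membership
from . import rpq_scoring as scoring
from . import symptom_clustering as clustering
from . import synthetic_cohort as synth

logger = logging.getLogger("rpqcluster")

COHORT_COLUMNS: tuple[str, ...] = (
    ("participant_id", "months_since_concussion")
    + scoring.SCORE_COLUMNS
    + assoc.IMPAIRMENT_COLUMNS
    + ("imp_other", "imp_none", "impairment_data_available")
)
_IMPAIRMENT_BLOCK = assoc.IMPAIRMENT_COLUMNS + (
    "imp_other",
    "imp_none",
    "impairment_data_available",
)


class CohortValidationError(ValueError):
    """Raised when a cohort CSV violates the schema (names the first offender)."""


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table in the fixed CSV dialect (UTF-8, comma, header)."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortValidationError(f"cohort table is missing column {missing[0]!r}")
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raw scores must be integers 0..4 (the first offending row and column are
    named), participant ids must be unique.  When every impairment column is
    absent the cohort is still accepted: the flags are filled with zeros and
    ``impairment_data_available`` is 0 for all rows, with a logged warning.
    """
    df = pd.read_csv(path, encoding="utf-8")
    required = ("participant_id", "months_since_concussion") + scoring.SCORE_COLUMNS
    for col in required:
        if col not in df.columns:
            raise CohortValidationError(f"cohort CSV is missing column {col!r}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise CohortValidationError(f"duplicate participant id {dup!r}")
    for col in scoring.SCORE_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ~vals.isin([0, 1, 2, 3, 4])
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise CohortValidationError(
                f"invalid raw score {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row} (participant {df['participant_id'].iloc[row]!r})"
            )
        df[col] = vals
    if not any(c in df.columns for c in _IMPAIRMENT_BLOCK[:-1]):
        logger.warning(
            "no impairment columns found: accepting cohort with "
            "impairment_data_available = 0 for all rows"
        )
        for col in _IMPAIRMENT_BLOCK:
            df[col] = 0
    else:
        for col in _IMPAIRMENT_BLOCK:
            if col not in df.columns:
                raise CohortValidationError(f"cohort CSV is missing column {col!r}")
    return df.loc[:, list(COHORT_COLUMNS)]


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    input_csv: str | None = None  # None -> simulate with synthetic_config
    synthetic_config: synth.SyntheticConfig | None = None
    group: str = "prolonged"  # "prolonged" or "early"
    linkage: str = "average"
    severity_thresholds: tuple[int, ...] = (membership.MILD, membership.MODERATE)
    alpha: float = 0.05
    presence_threshold: int = 2  # early-vs-prolonged symptom presence cut
    output_dir: str = "rpqcluster_output"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.group not in ("prolonged", "early"):
            raise ValueError("group must be 'prolonged' or 'early'")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise ValueError(f"input CSV {self.input_csv!r} does not exist")
        if self.linkage != "average":
            raise ValueError(
                "only average (UPGMA) linkage is supported by the pipeline run"
            )


def _association_rows(results: list[assoc.AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "cluster": r.cluster,
                "impairment": r.impairment,
                "aggregation": r.criteria.aggregation,
                "severity_threshold": r.criteria.severity_threshold,
                "test": r.test_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "bonferroni_alpha": r.bonferroni_alpha,
                "significant": r.significant,
                "significant_uncorrected": r.significant_uncorrected,
                "sensitivity_robust": r.sensitivity_robust,
            }
        )
    return pd.DataFrame(rows)


def _severity_rows(comparisons: list[assoc.SeverityComparison]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in comparisons])


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis; returns the paths of the written artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        logger.info("pipeline start: seed=%d group=%s alpha=%g", config.seed, config.group, config.alpha)
        if config.input_csv is not None:
            cohort = read_cohort_csv(config.input_csv)
            logger.info("loaded cohort of %d participants from %s", len(cohort), config.input_csv)
        else:
            syn = config.synthetic_config or synth.make_default_config()
            cohort = synth.generate_cohort(syn, seed=config.seed)
            logger.info("simulated cohort of %d participants", len(cohort))

        artifacts["cohort"] = outdir / "cohort.csv"
        write_cohort_csv(cohort, artifacts["cohort"])

        early, prolonged = scoring.split_by_duration(cohort)
        group_df = prolonged if config.group == "prolonged" else early
        logger.info(
            "duration split: early n=%d, prolonged n=%d; analysing %s group",
            len(early), len(prolonged), config.group,
        )
        scored = scoring.score_cohort(group_df)

        # scored cohort CSV with appended columns
        scored_df = group_df.copy()
        keep_ids = set(scored.participant_ids)
        scored_df = scored_df[scored_df["participant_id"].isin(keep_ids)].copy()
        for j, col in enumerate(scoring.SCORE_COLUMNS):
            scored_df[f"corrected_{col[4:]}"] = scored.corrected[:, j]
        scored_df["rpq16_total"] = scored.total
        scored_df["significant_symptoms"] = scored.significant_symptoms.astype(int)
        scored_df["rpq3_total"] = scored.rpq3_total
        scored_df["rpq13_total"] = scored.rpq13_total
        artifacts["scored"] = outdir / "scored_cohort.csv"
        scored_df.to_csv(artifacts["scored"], index=False, encoding="utf-8")

        corr, tree, clusters = clustering.cluster_symptoms(scored.corrected)
        artifacts["correlation"] = outdir / "spearman_correlation.csv"
        pd.DataFrame(corr.values, index=corr.labels, columns=corr.labels).to_csv(
            artifacts["correlation"], encoding="utf-8"
        )
        artifacts["newick"] = outdir / "dendrogram.nwk"
        artifacts["newick"].write_text(clustering.to_newick(tree) + "\n", encoding="utf-8")
        artifacts["clusters"] = outdir / "symptom_clusters.json"
        artifacts["clusters"].write_text(
            json.dumps(
                {
                    "clusters": {k: list(v) for k, v in clusters.clusters.items()},
                    "formation_level": clusters.formation_level,
                    "superclusters": [list(s) for s in clusters.superclusters],
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        logger.info(
            "formed %d symptom clusters at merge level %d: %s",
            clusters.n_clusters, clusters.formation_level, clusters.sizes(),
        )

        # membership under every criteria combination
        member_rows = []
        for threshold in config.severity_thresholds:
            for agg in membership.AGGREGATIONS:
                crit = membership.MembershipCriteria(agg, threshold)
                table = membership.assign_membership(scored, clusters, crit)
                melted = table.memberships.reset_index(names="participant_id").melt(
                    id_vars="participant_id", var_name="cluster", value_name="member"
                )
                melted["aggregation"] = agg
                melted["severity_threshold"] = threshold
                member_rows.append(melted)
        artifacts["membership"] = outdir / "membership.csv"
        pd.concat(member_rows, ignore_index=True).to_csv(
            artifacts["membership"], index=False, encoding="utf-8"
        )

        # association families (one per severity threshold)
        all_results: list[assoc.AssociationResult] = []
        for threshold in config.severity_thresholds:
            results = assoc.membership_association(
                group_df, clusters, threshold, alpha=config.alpha
            )
            logger.info(
                "membership family at threshold %d: %d comparisons, alpha=%.6f",
                threshold, len(results), results[0].bonferroni_alpha,
            )
            all_results.extend(results)
        assoc_df = _association_rows(all_results)
        artifacts["associations_csv"] = outdir / "associations.csv"
        assoc_df.to_csv(artifacts["associations_csv"], index=False, encoding="utf-8")
        artifacts["associations_json"] = outdir / "associations.json"
        artifacts["associations_json"].write_text(
            assoc_df.to_json(orient="records", indent=2), encoding="utf-8"
        )

        # by-functional-impairment severity comparisons
        any_vs_none, comparisons = assoc.severity_by_impairment(
            group_df, clusters, alpha=config.alpha
        )
        if comparisons:
            logger.info(
                "severity family: %d comparisons, alpha=%.6f",
                len(comparisons), comparisons[0].bonferroni_alpha,
            )
        sev_df = _severity_rows(
            ([any_vs_none] if any_vs_none is not None else []) + comparisons
        )
        artifacts["severity"] = outdir / "severity_by_impairment.csv"
        sev_df.to_csv(artifacts["severity"], index=False, encoding="utf-8")

        # per-symptom early vs prolonged baseline comparison
        if len(early) >= 3 and len(prolonged) >= 3:
            comparison = assoc.compare_early_prolonged(
                early, prolonged, presence_threshold=config.presence_threshold
            )
            artifacts["early_vs_prolonged"] = outdir / "early_vs_prolonged.csv"
            comparison.to_csv(artifacts["early_vs_prolonged"], index=False, encoding="utf-8")
        else:
            logger.warning(
                "early-vs-prolonged comparison skipped: a duration group has < 3 rows"
            )

        # Cramér's V screening of the impairment categories
        indicators = assoc.impairment_indicators(cohort)
        artifacts["cramers_v"] = outdir / "cramers_v.csv"
        assoc.cramers_v_matrix(indicators.drop(columns=["imp_none"])).to_csv(
            artifacts["cramers_v"], encoding="utf-8"
        )
        logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    except Exception as exc:  # pragma: no cover - error path message contract
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)
    return artifacts
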