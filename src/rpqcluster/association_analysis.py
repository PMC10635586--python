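"""Association analyses between symptom clusters and functional impairments.

Two perspectives are analysed for the prolonged group:

* **By symptom-cluster membership** (categorical-categorical): each of the
  cluster x impairment 2x2 tables is tested with a Pearson chi-squared test,
  or Fisher's exact test where any expected cell count is under 5, with odds
  ratios and Wald 95% CIs; one Bonferroni family per severity threshold
  (alpha = 0.05 / (clusters x impairments)).  Pairs significant under the
  main (mean) criterion are re-tested under the any/all sensitivity criteria.

* **By functional impairment** (categorical-ordinal): Mann-Whitney U
  comparisons of total RPQ-16 and per-cluster mean severities between
  reporters and non-reporters of each impairment, plus the global
  any-impairment vs no-impairment comparison on the RPQ-16 total;
  Bonferroni at alpha = 0.05 / (scores x impairments).

Cramér's V screens pairwise association among the impairment categories, and
a per-symptom 2x2 comparison contrasts the early and prolonged groups.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .cluster_membership import MembershipCriteria, assign_membership
from .rpq_scoring import RPQ_ITEMS, score_cohort

logger = logging.getLogger("rpqcluster")

ALPHA = 0.05
# Six analysis impairments; "other" is excluded (nonspecific, rarely reported)
# and "none" is kept only for the any-vs-none severity comparison.
IMPAIRMENTS: tuple[str, ...] = (
    "appointments",
    "conversations",
    "driving",
    "math",
    "paperwork",
    "planning",
)
IMPAIRMENT_COLUMNS: tuple[str, ...] = tuple(f"imp_{i}" for i in IMPAIRMENTS)


# ---------------------------------------------------------------------------
# Impairment indicator table
# ---------------------------------------------------------------------------


def impairment_indicators(cohort: pd.DataFrame) -> pd.DataFrame:
    """Binary impairment table for participants who completed the question.

    Keeps the six analysis impairments plus ``none``; drops ``other``.  Rows
    where ``none`` co-occurs with a specific impairment are contradictory and
    excluded with a logged count.
    """
    avail = cohort["impairment_data_available"].astype(int) == 1
    sub = cohort.loc[avail].copy()
    cols = list(IMPAIRMENT_COLUMNS) + ["imp_other", "imp_none"]
    ind = sub[["participant_id"] + cols].set_index("participant_id").astype(int)
    conflict = (ind["imp_none"] == 1) & (ind[cols[:-1]].sum(axis=1) > 0)
    if conflict.any():
        logger.warning(
            "excluding %d rows where 'none' conflicts with a reported impairment",
            int(conflict.sum()),
        )
        ind = ind.loc[~conflict]
    return ind.drop(columns=["imp_other"])


# ---------------------------------------------------------------------------
# Cramér's V
# ---------------------------------------------------------------------------


def cramers_v(x, y) -> float:
    """Cramér's V between two categorical variables.

    V = sqrt(chi2 / (n * min(r-1, c-1))) from the Pearson chi-squared
    statistic without continuity correction.  Undefined for a constant
    variable (returned as NaN with a warning).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        logger.warning("Cramér's V undefined for a constant variable")
        return float("nan")
    table = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    n = table.sum()
    k = min(table.shape[0] - 1, table.shape[1] - 1)
    return float(np.sqrt(chi2 / (n * k)))


def cramers_v_matrix(indicators: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Cramér's V over the columns of a binary indicator table."""
    cols = list(indicators.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        v = cramers_v(indicators[a], indicators[b])
        out.loc[a, b] = out.loc[b, a] = v
    return out


# ---------------------------------------------------------------------------
# 2x2 testing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): exposure rows x outcome columns."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in counts):
            raise ValueError("cell counts must be non-negative integers")
        if sum(counts) < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> np.ndarray:
        r1, r2, c1, c2 = self.margins()
        return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]], dtype=float) / self.n


@dataclass
class TwoByTwoResult:
    test_name: str  # "chi-squared" or "fisher"
    statistic: float  # chi2 statistic, or NaN for Fisher
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool = False


@lru_cache(maxsize=100_000)
def _hypergeom_pmf_table(n: int, r1: int, c1: int) -> tuple[np.ndarray, int, int]:
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    return pmf, lo, hi


def fisher_exact_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums, over the conditional distribution of the (1,1) cell given the
    margins, all probabilities no greater than that of the observed table
    (with a small relative tolerance against floating-point ties).
    """
    r1, _, c1, _ = table.margins()
    pmf, lo, _ = _hypergeom_pmf_table(table.n, r1, c1)
    p_obs = pmf[table.a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def odds_ratio_ci(
    table: ContingencyTable2x2, z: float = 1.959963984540054
) -> tuple[float, float, float, bool]:
    """Odds ratio (ad/bc) with a Wald 95% CI on the log scale.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell) for both the OR and its CI; the result is flagged corrected.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        or_,
        math.exp(math.log(or_) - z * se),
        math.exp(math.log(or_) + z * se),
        corrected,
    )


def two_by_two_test(
    table: ContingencyTable2x2,
    *,
    fisher_expected_threshold: float = 5.0,
    continuity_correction: bool = False,
) -> TwoByTwoResult:
    """Chi-squared or Fisher's exact test of a 2x2 table, with OR and CI.

    Fisher's exact test is selected when any expected cell count falls below
    ``fisher_expected_threshold`` (classical rule of 5); otherwise a Pearson
    chi-squared test, without Yates continuity correction by default.
    """
    r1, r2, c1, c2 = table.margins()
    if 0 in (r1, r2, c1, c2):
        raise ValueError("2x2 table has an empty margin; test undefined")
    use_fisher = bool((table.expected() < fisher_expected_threshold).any())
    if use_fisher:
        p = fisher_exact_p(table)
        stat = float("nan")
        name = "fisher"
    else:
        res = stats.chi2_contingency(
            [[table.a, table.b], [table.c, table.d]], correction=continuity_correction
        )
        stat, p, name = float(res.statistic), float(res.pvalue), "chi-squared"
    or_, lo, hi, corrected = odds_ratio_ci(table)
    return TwoByTwoResult(
        test_name=name,
        statistic=stat,
        p_value=p,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        haldane_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

EXACT_MAX_GROUP = 8  # exact enumeration when both groups are this small


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (first sample) and two-sided p.

    U is computed from midranks (tie-aware).  For group sizes of at most
    8 each, the two-sided p comes from exhaustive enumeration of all
    group-label assignments (tie-exact); otherwise from the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    if max(n1, n2) <= EXACT_MAX_GROUP:
        dev = abs(u1 - mu)
        count = 0
        total = 0
        rank_sum_base = n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - rank_sum_base
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                count += 1
        p = count / total
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:  # all observations tied
            return u1, 1.0
        # continuity-corrected, as in the standard asymptotic implementation
        z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
        p = 2 * stats.norm.sf(z)
    return u1, float(min(1.0, p))


# ---------------------------------------------------------------------------
# By symptom-cluster membership
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    cluster: str
    impairment: str
    criteria: MembershipCriteria
    test_name: str
    statistic: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    bonferroni_alpha: float
    significant: bool
    significant_uncorrected: bool
    sensitivity_robust: bool | None = None  # None when not re-analysed
    table: ContingencyTable2x2 | None = None


def _membership_table(members: pd.Series, impaired: pd.Series) -> ContingencyTable2x2:
    m = members.astype(bool)
    i = impaired.astype(bool)
    return ContingencyTable2x2(
        a=int((m & i).sum()),
        b=int((m & ~i).sum()),
        c=int((~m & i).sum()),
        d=int((~m & ~i).sum()),
    )


def membership_association(
    cohort: pd.DataFrame,
    clusters,
    severity_threshold: int,
    *,
    impairments: tuple[str, ...] = IMPAIRMENTS,
    alpha: float = ALPHA,
) -> list[AssociationResult]:
    """Cluster-membership x impairment associations, one Bonferroni family.

    Builds the 2x2 table (membership under the mean criterion x reported
    impairment) for every cluster x impairment pair among participants with
    impairment data, applies :func:`two_by_two_test`, and flags significance
    at alpha / (n_clusters x n_impairments).  Every pair significant under
    the main criterion is re-analysed under the any/all sensitivity criteria;
    ``sensitivity_robust`` records whether both stay significant.
    """
    indicators = impairment_indicators(cohort)
    scored = score_cohort(cohort)
    # align scores to participants with impairment data
    id_to_row = {pid: i for i, pid in enumerate(scored.participant_ids)}
    keep = [pid for pid in indicators.index if pid in id_to_row]
    indicators = indicators.loc[keep]
    rows = [id_to_row[pid] for pid in keep]
    from .rpq_scoring import CorrectedScores

    sub_scores = CorrectedScores(
        corrected=scored.corrected[rows],
        total=scored.total[rows],
        significant_symptoms=scored.significant_symptoms[rows],
        rpq3_total=scored.rpq3_total[rows],
        rpq13_total=scored.rpq13_total[rows],
        participant_ids=np.asarray(keep),
    )

    family_alpha = alpha / (clusters.n_clusters * len(impairments))
    memberships = {
        agg: assign_membership(
            sub_scores, clusters, MembershipCriteria(agg, severity_threshold)
        ).memberships
        for agg in ("mean", "any", "all")
    }
    results: list[AssociationResult] = []
    for cname in clusters.clusters:
        for imp in impairments:
            impaired = indicators[f"imp_{imp}"]
            tab = _membership_table(memberships["mean"][cname], impaired)
            try:
                res = two_by_two_test(tab)
            except ValueError:
                # degenerate table (empty margin) in a tiny subgroup
                logger.warning(
                    "association %s x %s undefined: empty 2x2 margin", cname, imp
                )
                results.append(
                    AssociationResult(
                        cluster=cname,
                        impairment=imp,
                        criteria=MembershipCriteria("mean", severity_threshold),
                        test_name="undefined",
                        statistic=float("nan"),
                        p_value=float("nan"),
                        odds_ratio=float("nan"),
                        ci_low=float("nan"),
                        ci_high=float("nan"),
                        bonferroni_alpha=family_alpha,
                        significant=False,
                        significant_uncorrected=False,
                        table=tab,
                    )
                )
                continue
            significant = res.p_value < family_alpha
            robust = None
            if significant:
                robust = True
                for agg in ("any", "all"):
                    t2 = _membership_table(memberships[agg][cname], impaired)
                    try:
                        if two_by_two_test(t2).p_value >= family_alpha:
                            robust = False
                    except ValueError:
                        logger.warning(
                            "sensitivity table %s x %s (%s) degenerate", cname, imp, agg
                        )
                        robust = False
            results.append(
                AssociationResult(
                    cluster=cname,
                    impairment=imp,
                    criteria=MembershipCriteria("mean", severity_threshold),
                    test_name=res.test_name,
                    statistic=res.statistic,
                    p_value=res.p_value,
                    odds_ratio=res.odds_ratio,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    bonferroni_alpha=family_alpha,
                    significant=significant,
                    significant_uncorrected=res.p_value < alpha,
                    sensitivity_robust=robust,
                    table=tab,
                )
            )
    return results


# ---------------------------------------------------------------------------
# By functional impairment
# ---------------------------------------------------------------------------


@dataclass
class SeverityComparison:
    impairment: str
    score: str  # "rpq16_total" or a cluster name
    mean_with: float
    mean_without: float
    n_with: int
    n_without: int
    u_statistic: float
    p_value: float
    bonferroni_alpha: float
    significant: bool
    significant_uncorrected: bool


def severity_by_impairment(
    cohort: pd.DataFrame,
    clusters,
    *,
    impairments: tuple[str, ...] = IMPAIRMENTS,
    alpha: float = ALPHA,
) -> tuple[SeverityComparison | None, list[SeverityComparison]]:
    """Severity comparisons by functional impairment.

    Part (i): total RPQ-16 of participants reporting any impairment vs those
    reporting none, over all impairment-question completers (no multiplicity
    family; reported raw).

    Part (ii): among participants who reported at least one impairment
    (excluding "none"), a Mann-Whitney comparison of each score (total RPQ-16
    and each cluster mean) between reporters and non-reporters of each
    impairment; Bonferroni at alpha / (scores x impairments).  Comparisons
    with a group of fewer than 2 are skipped with a log entry.
    """
    indicators = impairment_indicators(cohort)
    scored = score_cohort(cohort)
    id_to_row = {pid: i for i, pid in enumerate(scored.participant_ids)}
    keep = [pid for pid in indicators.index if pid in id_to_row]
    indicators = indicators.loc[keep]
    rows = [id_to_row[pid] for pid in keep]
    total = scored.total[rows]
    from .rpq_scoring import CorrectedScores

    sub_scores = CorrectedScores(
        corrected=scored.corrected[rows],
        total=total,
        significant_symptoms=scored.significant_symptoms[rows],
        rpq3_total=scored.rpq3_total[rows],
        rpq13_total=scored.rpq13_total[rows],
        participant_ids=np.asarray(keep),
    )
    cluster_means = sub_scores.cluster_means(clusters)

    # (i) any impairment vs none, on total RPQ-16
    none_mask = indicators["imp_none"].to_numpy().astype(bool)
    any_mask = ~none_mask
    any_vs_none: SeverityComparison | None = None
    if any_mask.sum() >= 2 and none_mask.sum() >= 2:
        u, p = mann_whitney(total[any_mask], total[none_mask])
        any_vs_none = SeverityComparison(
            impairment="any",
            score="rpq16_total",
            mean_with=float(total[any_mask].mean()),
            mean_without=float(total[none_mask].mean()),
            n_with=int(any_mask.sum()),
            n_without=int(none_mask.sum()),
            u_statistic=u,
            p_value=p,
            bonferroni_alpha=alpha,
            significant=p < alpha,
            significant_uncorrected=p < alpha,
        )
    else:
        logger.warning("any-vs-none comparison skipped: a group has < 2 members")

    # (ii) per impairment, among deficit reporters only
    scores: dict[str, np.ndarray] = {"rpq16_total": total.astype(float)}
    for cname in clusters.clusters:
        scores[cname] = cluster_means[cname].to_numpy()
    reporters = any_mask
    family_alpha = alpha / (len(scores) * len(impairments))
    comparisons: list[SeverityComparison] = []
    for imp in impairments:
        with_mask = reporters & indicators[f"imp_{imp}"].to_numpy().astype(bool)
        without_mask = reporters & ~indicators[f"imp_{imp}"].to_numpy().astype(bool)
        for sname, svals in scores.items():
            if with_mask.sum() < 2 or without_mask.sum() < 2:
                logger.warning(
                    "severity comparison %s x %s skipped: group < 2", imp, sname
                )
                continue
            u, p = mann_whitney(svals[with_mask], svals[without_mask])
            comparisons.append(
                SeverityComparison(
                    impairment=imp,
                    score=sname,
                    mean_with=float(svals[with_mask].mean()),
                    mean_without=float(svals[without_mask].mean()),
                    n_with=int(with_mask.sum()),
                    n_without=int(without_mask.sum()),
                    u_statistic=u,
                    p_value=p,
                    bonferroni_alpha=family_alpha,
                    significant=p < family_alpha,
                    significant_uncorrected=p < alpha,
                )
            )
    return any_vs_none, comparisons


# ---------------------------------------------------------------------------
# Early vs prolonged comparison
# ---------------------------------------------------------------------------


def compare_early_prolonged(
    early: pd.DataFrame, prolonged: pd.DataFrame, *, presence_threshold: int = 2
) -> pd.DataFrame:
    """Per-symptom 2x2 comparison (group x symptom presence) of the two groups.

    Presence defaults to a corrected score of at least 2 (at least a mild
    problem).  One row per RPQ item; no multiplicity correction is applied
    (baseline description).
    """
    s_early = score_cohort(early)
    s_prol = score_cohort(prolonged)
    rows = []
    for j, item in enumerate(RPQ_ITEMS):
        pe = s_early.corrected[:, j] >= presence_threshold
        pp = s_prol.corrected[:, j] >= presence_threshold
        tab = ContingencyTable2x2(
            a=int(pe.sum()),
            b=int((~pe).sum()),
            c=int(pp.sum()),
            d=int((~pp).sum()),
        )
        try:
            res = two_by_two_test(tab)
        except ValueError:  # empty margin (symptom absent or universal)
            logger.warning("symptom %s: degenerate 2x2 table, test undefined", item)
            rows.append(
                {
                    "item": item,
                    "test": "undefined",
                    "statistic": float("nan"),
                    "p_value": float("nan"),
                    "odds_ratio": float("nan"),
                    "ci_low": float("nan"),
                    "ci_high": float("nan"),
                }
            )
            continue
        rows.append(
            {
                "item": item,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)
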