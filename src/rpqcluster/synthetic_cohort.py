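"""Synthetic cohort generator with planted symptom blocks and impairment effects.

Generates participant tables with the statistical structure the downstream
analysis assumes, via a Gaussian copula: each participant draws a 16-dim
standard-normal latent vector whose correlation matrix is block-structured
(``rho_within`` inside a planted symptom block, ``rho_between`` across
blocks); each coordinate is discretized through per-item cutpoints into a raw
0-4 ordinal response.  Functional-impairment flags follow a logistic model on
the mean *corrected* severity of each planted cluster, so cluster-impairment
odds ratios of a chosen magnitude can be planted and later recovered.

The defaults emulate the structure of a prolonged post-concussion cohort:
five correlated symptom blocks (headache-related, sensitivity, sleep-fatigue,
cognitive, emotional), a ~95% prolonged fraction, impairment prevalences in
the 6-45% range, and planted effects on the cluster-impairment pairs where
moderate odds ratios (~2.5-4.5) are plausible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from .cluster_membership import MembershipCriteria
from .rpq_scoring import N_ITEMS, RPQ_ITEMS, SCORE_COLUMNS, correct_scores
from .symptom_clustering import SymptomClusterSet, _name_groups

logger = logging.getLogger("rpqcluster")

# The five canonical symptom blocks, as item indices into RPQ_ITEMS.
DEFAULT_BLOCKS: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 12, 14),  # headache, dizziness, nausea, blurred vision, double vision
    (3, 13),  # noise sensitivity, light sensitivity
    (4, 5),  # sleep disturbance, fatigue
    (9, 10, 11),  # forgetfulness, poor concentration, longer to think
    (6, 7, 8, 15),  # irritability, depression, frustration, restlessness
)

# Default per-item category probabilities for raw levels 0..4, calibrated so
# roughly a third of a prolonged cohort crosses the corrected total >= 16
# marker of significant symptoms.
DEFAULT_CATEGORY_PROBS: tuple[float, ...] = (0.55, 0.15, 0.14, 0.10, 0.06)

# Marginal impairment prevalence targets (fraction reporting each category
# among impairment-question completers); the rare unspecific "other" category
# is generated independently and excluded from analyses.
DEFAULT_IMPAIRMENT_PREVALENCE: dict[str, float] = {
    "appointments": 0.343,
    "conversations": 0.449,
    "driving": 0.059,
    "math": 0.276,
    "paperwork": 0.370,
    "planning": 0.291,
}
DEFAULT_OTHER_RATE = 0.04
DEFAULT_COMPLETION_RATE = 254 / 467  # impairment-question completion
DEFAULT_PROLONGED_FRACTION = 445 / 467

# Planted cluster -> impairment log-odds increments per unit of mean corrected
# cluster severity.  Nonzero entries sit on the pairs where moderate odds
# ratios are plausible for a prolonged cohort; driving gets none.
DEFAULT_SLOPES: dict[tuple[str, str], float] = {
    ("sleep_fatigue", "appointments"): 0.50,
    ("sleep_fatigue", "conversations"): 0.50,
    ("sleep_fatigue", "math"): 0.50,
    ("sleep_fatigue", "paperwork"): 0.50,
    ("cognitive", "appointments"): 0.55,
    ("cognitive", "conversations"): 0.60,
    ("sensitivity", "math"): 0.50,
    ("emotional", "conversations"): 0.45,
    ("emotional", "paperwork"): 0.45,
}


def _cutpoints_from_probs(probs) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.ndim == 1:
        p = np.tile(p, (N_ITEMS, 1))
    if p.shape != (N_ITEMS, 5) or not np.allclose(p.sum(axis=1), 1.0):
        raise ValueError("category probabilities must be (16, 5) rows summing to 1")
    return norm.ppf(np.cumsum(p[:, :4], axis=1))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``marginal_cutpoints`` maps a standard-normal latent value to raw scores
    0-4 per item (4 strictly increasing thresholds per item).
    ``impairment_slopes`` are log-odds increments per unit of mean corrected
    cluster severity, keyed by (cluster name, impairment name);
    ``impairment_intercepts`` are per-impairment log-odds baselines.
    """

    n_participants: int = 467
    prolonged_fraction: float = DEFAULT_PROLONGED_FRACTION
    block_partition: tuple[tuple[int, ...], ...] = DEFAULT_BLOCKS
    rho_within: float = 0.6
    rho_between: float = 0.15
    marginal_cutpoints: np.ndarray = field(
        default_factory=lambda: _cutpoints_from_probs(DEFAULT_CATEGORY_PROBS)
    )
    impairment_intercepts: dict[str, float] = field(default_factory=dict)
    impairment_slopes: dict[tuple[str, str], float] = field(default_factory=dict)
    other_rate: float = DEFAULT_OTHER_RATE
    completion_rate: float = DEFAULT_COMPLETION_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        flat = sorted(i for block in self.block_partition for i in block)
        if flat != list(range(N_ITEMS)):
            raise ValueError("block_partition must cover all 16 items exactly once")
        if not (-1 < self.rho_within < 1 and -1 < self.rho_between < 1):
            raise ValueError("rho_within and rho_between must lie in (-1, 1)")
        self.marginal_cutpoints = np.asarray(self.marginal_cutpoints, dtype=float)
        if self.marginal_cutpoints.shape != (N_ITEMS, 4):
            raise ValueError("marginal_cutpoints must have shape (16, 4)")
        if not (np.diff(self.marginal_cutpoints, axis=1) > 0).all():
            raise ValueError("marginal_cutpoints must be strictly increasing per item")
        if not 0 < self.prolonged_fraction <= 1:
            raise ValueError("prolonged_fraction must lie in (0, 1]")
        # positive definiteness of the implied latent correlation matrix
        try:
            np.linalg.cholesky(self.latent_correlation())
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "implied latent correlation matrix is not positive definite"
            ) from exc

    def latent_correlation(self) -> np.ndarray:
        corr = np.full((N_ITEMS, N_ITEMS), self.rho_between)
        for block in self.block_partition:
            idx = np.asarray(block)
            corr[np.ix_(idx, idx)] = self.rho_within
        np.fill_diagonal(corr, 1.0)
        return corr

    def category_probs(self) -> np.ndarray:
        """Per-item multinomial cell probabilities implied by the cutpoints."""
        cdf = norm.cdf(self.marginal_cutpoints)
        return np.diff(np.concatenate(
            [np.zeros((N_ITEMS, 1)), cdf, np.ones((N_ITEMS, 1))], axis=1
        ), axis=1)

    def expected_item_corrected_mean(self) -> np.ndarray:
        """E[corrected score] per item under the marginal cutpoints."""
        probs = self.category_probs()
        levels = np.array([0.0, 0.0, 2.0, 3.0, 4.0])  # level 1 corrects to 0
        return probs @ levels


def planted_partition(config: SyntheticConfig) -> SymptomClusterSet:
    """The generator's block partition as a named symptom-cluster set."""
    groups = [tuple(sorted(block)) for block in config.block_partition]
    named = _name_groups(sorted(groups), RPQ_ITEMS)
    return SymptomClusterSet(clusters=named, formation_level=None)


def make_default_config(n_participants: int = 467, seed: int = 0) -> SyntheticConfig:
    """Default configuration emulating a prolonged post-concussion cohort.

    Intercepts are centred so that, with the default slopes, marginal
    impairment prevalences land near their targets: each intercept is the
    logit of the target prevalence minus the planted slopes times the
    expected mean cluster severity.
    """
    config = SyntheticConfig(n_participants=n_participants, seed=seed)
    partition = planted_partition(config)
    item_means = config.expected_item_corrected_mean()
    label_to_idx = {lab: i for i, lab in enumerate(RPQ_ITEMS)}
    cluster_mean = {
        name: item_means[[label_to_idx[m] for m in members]].mean()
        for name, members in partition.clusters.items()
    }
    intercepts = {
        imp: float(logit(prev)) for imp, prev in DEFAULT_IMPAIRMENT_PREVALENCE.items()
    }
    # centring: intercept = logit(target) - sum(slope * E[cluster mean])
    for (cname, imp), slope in DEFAULT_SLOPES.items():
        intercepts[imp] -= slope * float(cluster_mean[cname])
    return replace(
        config,
        impairment_intercepts=intercepts,
        impairment_slopes=dict(DEFAULT_SLOPES),
    )


def _cluster_mean_severities(
    config: SyntheticConfig, z: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Raw scores and per-cluster mean corrected severities from latents."""
    raw = np.empty_like(z, dtype=np.int64)
    for j in range(N_ITEMS):
        raw[:, j] = np.searchsorted(config.marginal_cutpoints[j], z[:, j])
    corrected = correct_scores(raw)
    partition = planted_partition(config)
    label_to_idx = {lab: i for i, lab in enumerate(RPQ_ITEMS)}
    means = {
        name: corrected[:, [label_to_idx[m] for m in members]].mean(axis=1)
        for name, members in partition.clusters.items()
    }
    return raw, means


def _impairment_probs(
    config: SyntheticConfig, cluster_means: dict[str, np.ndarray], n: int
) -> dict[str, np.ndarray]:
    probs = {}
    for imp in DEFAULT_IMPAIRMENT_PREVALENCE:
        eta = np.full(n, config.impairment_intercepts.get(imp, logit(0.2)))
        for (cname, islope_imp), slope in config.impairment_slopes.items():
            if islope_imp == imp:
                eta = eta + slope * cluster_means[cname]
        probs[imp] = expit(eta)
    return probs


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table; deterministic given (config, seed).

    Columns follow the cohort CSV schema of :mod:`rpqcluster.pipeline`:
    participant_id, months_since_concussion, 16 ``rpq_*`` raw scores,
    ``imp_*`` binary flags (six analysis categories, other, none), and
    ``impairment_data_available``.
    """
    if config.n_participants < 2:
        raise ValueError("n_participants must be at least 2")
    n = config.n_participants
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    # independent named sub-streams keep each generation stage order-invariant
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("duration", "latent", "impairment", "other", "availability"),
            master.spawn(5),
        )
    }
    prolonged = streams["duration"].random(n) < config.prolonged_fraction
    months = np.where(
        prolonged,
        streams["duration"].uniform(12.0, 120.0, size=n),
        streams["duration"].uniform(0.5, 12.0, size=n),
    )
    chol = np.linalg.cholesky(config.latent_correlation())
    z = streams["latent"].standard_normal((n, N_ITEMS)) @ chol.T
    raw, cluster_means = _cluster_mean_severities(config, z)
    probs = _impairment_probs(config, cluster_means, n)
    flags = {
        imp: (streams["impairment"].random(n) < p).astype(int)
        for imp, p in probs.items()
    }
    other = (streams["other"].random(n) < config.other_rate).astype(int)
    specific_any = np.maximum.reduce(list(flags.values()) + [other])
    none = (specific_any == 0).astype(int)
    available = (streams["availability"].random(n) < config.completion_rate).astype(int)

    data: dict[str, np.ndarray] = {
        "participant_id": np.array([f"P{i + 1:05d}" for i in range(n)]),
        "months_since_concussion": np.round(months, 2),
    }
    for j, col in enumerate(SCORE_COLUMNS):
        data[col] = raw[:, j]
    for imp in DEFAULT_IMPAIRMENT_PREVALENCE:
        data[f"imp_{imp}"] = flags[imp]
    data["imp_other"] = other
    data["imp_none"] = none
    data["impairment_data_available"] = available
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Planted-effect bookkeeping
# ---------------------------------------------------------------------------


def implied_membership_odds_ratio(
    config: SyntheticConfig,
    cluster: str,
    impairment: str,
    criteria: MembershipCriteria | None = None,
    *,
    n_mc: int = 200_000,
    seed: int = 12345,
) -> float:
    """Population odds ratio between cluster membership and an impairment.

    Computed as the exact expectation of the logistic impairment probability
    over a large Monte-Carlo draw of the severity distribution (the only
    sampled part), conditioned on membership status — no impairment noise is
    simulated, so the estimate is low-variance.
    """
    criteria = criteria or MembershipCriteria("mean", 2)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(config.latent_correlation())
    z = rng.standard_normal((n_mc, N_ITEMS)) @ chol.T
    _, cluster_means = _cluster_mean_severities(config, z)
    member = _membership_mask(config, cluster, criteria, z, cluster_means)
    p = _impairment_probs(config, cluster_means, n_mc)[impairment]
    p1, p0 = p[member].mean(), p[~member].mean()
    return float((p1 / (1 - p1)) / (p0 / (1 - p0)))


def _membership_mask(config, cluster, criteria, z, cluster_means):
    partition = planted_partition(config)
    label_to_idx = {lab: i for i, lab in enumerate(RPQ_ITEMS)}
    idx = [label_to_idx[m] for m in partition.clusters[cluster]]
    raw = np.empty((z.shape[0], N_ITEMS), dtype=np.int64)
    for j in range(N_ITEMS):
        raw[:, j] = np.searchsorted(config.marginal_cutpoints[j], z[:, j])
    corrected = correct_scores(raw)[:, idx]
    t = criteria.severity_threshold
    if criteria.aggregation == "mean":
        return corrected.sum(axis=1) >= t * len(idx)
    if criteria.aggregation == "any":
        return corrected.max(axis=1) >= t
    return corrected.min(axis=1) >= t


def calibrate_slope_for_or(
    config: SyntheticConfig,
    cluster: str,
    impairment: str,
    target_or: float,
    criteria: MembershipCriteria | None = None,
    *,
    n_mc: int = 200_000,
    seed: int = 12345,
    tol: float = 1e-3,
) -> SyntheticConfig:
    """Return a config whose single planted slope yields the target membership OR.

    All other slopes are cleared; the implied OR is monotone in the slope, so
    a bisection on [0, 4] converges.  Used to plant effects of a known
    population odds ratio for recovery and CI-coverage experiments.
    """
    criteria = criteria or MembershipCriteria("mean", 2)
    base_intercepts = dict(config.impairment_intercepts) or {
        imp: float(logit(p)) for imp, p in DEFAULT_IMPAIRMENT_PREVALENCE.items()
    }
    lo, hi = 0.0, 4.0
    for _ in range(40):
        mid = (lo + hi) / 2
        trial = replace(
            config,
            impairment_intercepts=base_intercepts,
            impairment_slopes={(cluster, impairment): mid},
        )
        or_mid = implied_membership_odds_ratio(
            trial, cluster, impairment, criteria, n_mc=n_mc, seed=seed
        )
        if abs(or_mid - target_or) < tol:
            return trial
        if or_mid < target_or:
            lo = mid
        else:
            hi = mid
    return trial


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------


def config_to_yaml(config: SyntheticConfig, path) -> None:
    payload = {
        "n_participants": config.n_participants,
        "prolonged_fraction": config.prolonged_fraction,
        "block_partition": [list(b) for b in config.block_partition],
        "rho_within": config.rho_within,
        "rho_between": config.rho_between,
        "marginal_cutpoints": config.marginal_cutpoints.tolist(),
        "impairment_intercepts": dict(config.impairment_intercepts),
        "impairment_slopes": {
            f"{c}:{i}": s for (c, i), s in config.impairment_slopes.items()
        },
        "other_rate": config.other_rate,
        "completion_rate": config.completion_rate,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_from_yaml(path) -> SyntheticConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    payload["block_partition"] = tuple(tuple(b) for b in payload["block_partition"])
    payload["marginal_cutpoints"] = np.asarray(payload["marginal_cutpoints"])
    payload["impairment_slopes"] = {
        tuple(k.split(":")): v for k, v in payload["impairment_slopes"].items()
    }
    return SyntheticConfig(**payload)
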