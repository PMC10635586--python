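"""Spearman correlation profiles, UPGMA agglomeration, and symptom-cluster formation.

Symptoms are clustered by the similarity of their rank-correlation *profiles*:
the pairwise Spearman matrix over corrected item scores is computed, each
item's 16-entry correlation row (self-correlation included) is treated as its
feature vector, and unweighted average-linkage (UPGMA) agglomeration runs on
the Euclidean distances between those rows.  Two symptoms can therefore be
co-clustered even when their direct correlation is modest, provided they
correlate similarly with everything else.

A symptom-cluster set is *formed* at the earliest merge after which no symptom
remains unpaired: with K the smallest merge index leaving no singleton group,
the partition immediately after merge K is returned (16 - K clusters, every
group of size >= 2).  Merges above the cut describe superclusters — the
hierarchical joining of already-formed symptom-clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .rpq_scoring import N_ITEMS, RPQ_ITEMS

logger = logging.getLogger("rpqcluster")

SMALL_N_WARNING_THRESHOLD = 30  # below this, clustering is preliminary

# Canonical five-cluster composition used for naming recovered clusters.
CANONICAL_CLUSTERS: dict[str, frozenset[str]] = {
    "headache_related": frozenset(
        {"headache", "dizziness", "nausea_vomiting", "blurred_vision", "double_vision"}
    ),
    "sensitivity": frozenset({"noise_sensitivity", "light_sensitivity"}),
    "sleep_fatigue": frozenset({"sleep_disturbance", "fatigue"}),
    "cognitive": frozenset({"forgetfulness", "poor_concentration", "longer_to_think"}),
    "emotional": frozenset(
        {"irritability", "depression_tearfulness", "frustration", "restlessness"}
    ),
}


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho between symptom severity columns."""

    values: np.ndarray  # (p, p), symmetric, unit diagonal
    labels: tuple[str, ...]
    n_participants: int

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")


def spearman_matrix(scores, labels: tuple[str, ...] = RPQ_ITEMS) -> CorrelationMatrix:
    """Spearman rank correlation matrix of score columns (midranks for ties).

    ``scores`` is (n, p) with n >= 3 participants.  A constant column makes
    rho undefined; those off-diagonal entries are set to 0.0 with a logged
    warning (no co-ranking information, treated as uninformative).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(labels):
        raise ValueError(f"expected (n, {len(labels)}) score array, got {arr.shape}")
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 participants to correlate, got {n}")
    constant = arr.std(axis=0) == 0
    if constant.any():
        # spearmanr refuses constant input wholesale; fall back to Pearson on
        # midranks (identical definition) and zero the undefined entries
        logger.warning(
            "constant score column(s) %s: undefined Spearman rho set to 0",
            [labels[i] for i in np.flatnonzero(constant)],
        )
        ranks = np.apply_along_axis(stats.rankdata, 0, arr)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
        rho[np.isnan(rho)] = 0.0
    else:
        rho = np.atleast_2d(np.asarray(stats.spearmanr(arr).statistic, dtype=float))
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return CorrelationMatrix(values=rho, labels=tuple(labels), n_participants=n)


def profile_distances(corr: CorrelationMatrix) -> np.ndarray:
    """Euclidean distances between full correlation-matrix rows.

    Each item's profile is its complete row of the correlation matrix,
    *including* the unit self-correlation entry — the row-clustering
    semantics of clustering "on the correlation matrix" with a Euclidean
    metric.  Returns a square (p, p) distance matrix.
    """
    return squareform(pdist(corr.values, metric="euclidean"))


# ---------------------------------------------------------------------------
# UPGMA agglomeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: ``left`` and ``right`` join at ``height``."""

    left: tuple[int, ...]  # sorted leaf indices
    right: tuple[int, ...]
    height: float

    @property
    def members(self) -> tuple[int, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass
class MergeTree:
    """Ordered agglomeration history over the symptom items."""

    merges: list[Merge]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("UPGMA merge heights must be non-decreasing")
        if tuple(sorted(self.merges[-1].members)) != tuple(range(n)):
            raise ValueError("final merge must contain all leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def partition_after(self, k: int) -> list[tuple[int, ...]]:
        """Groups existing immediately after merge ``k`` (1-based; 0 = leaves)."""
        groups: list[tuple[int, ...]] = [(i,) for i in range(self.n_leaves)]
        for merge in self.merges[:k]:
            groups = [g for g in groups if g != merge.left and g != merge.right]
            groups.append(merge.members)
        return sorted(groups)

    def to_linkage(self) -> np.ndarray:
        """Encode the history as a SciPy linkage matrix (for cross-checks)."""
        n = self.n_leaves
        node_of: dict[tuple[int, ...], int] = {(i,): i for i in range(n)}
        Z = np.zeros((n - 1, 4))
        for k, m in enumerate(self.merges):
            i, j = node_of[m.left], node_of[m.right]
            Z[k] = [min(i, j), max(i, j), m.height, len(m.members)]
            node_of[m.members] = n + k
        return Z


def average_linkage(distances: np.ndarray, labels: tuple[str, ...] = RPQ_ITEMS) -> MergeTree:
    """UPGMA agglomeration of a symmetric distance matrix.

    At each step the two closest current groups merge; the distance between
    two groups is the arithmetic mean of all cross-pair leaf distances
    (unweighted average linkage).  Equidistant candidate pairs are broken
    deterministically: the pair whose smallest leaf index is lowest wins,
    then the pair whose other smallest leaf index is lowest.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n != len(labels):
        raise ValueError("labels do not match distance matrix size")

    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    # Pairwise average distances between current clusters, keyed by cluster.
    dist: dict[frozenset[tuple[int, ...]], float] = {
        frozenset((clusters[i], clusters[j])): float(d[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                dij = dist[frozenset((a, b))]
                lo, hi = sorted((a[0], b[0]))
                key = (dij, lo, hi)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, _, _), a, b = best
        height = dist[frozenset((a, b))]
        left, right = sorted((a, b))  # lexicographic: lowest leaf index first
        merged = tuple(sorted(a + b))
        # Lance-Williams update for unweighted average linkage.
        for c in clusters:
            if c is a or c is b:
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dist[frozenset((merged, c))] = (len(a) * dac + len(b) * dbc) / (len(a) + len(b))
        dist.pop(frozenset((a, b)))
        clusters = [c for c in clusters if c is not a and c is not b]
        clusters.append(merged)
        merges.append(Merge(left=left, right=right, height=height))
    return MergeTree(merges=merges, labels=tuple(labels))


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------


@dataclass
class SymptomClusterSet:
    """A named partition of the symptom items into clusters.

    ``formation_level`` is the merge index at which the partition was taken
    (None for planted/externally supplied partitions).  ``superclusters``
    lists, in merge order above the cut, the sets of cluster names each
    higher merge joins.
    """

    clusters: dict[str, tuple[str, ...]]
    formation_level: int | None = None
    superclusters: list[tuple[str, ...]] = field(default_factory=list)
    item_labels: tuple[str, ...] = RPQ_ITEMS

    def __post_init__(self) -> None:
        members = [m for group in self.clusters.values() for m in group]
        if sorted(members) != sorted(self.item_labels):
            raise ValueError("clusters must partition the item set exactly once")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership_vector(self) -> np.ndarray:
        """Integer cluster id per item, in ``item_labels`` order."""
        assign = {}
        for cid, members in enumerate(self.clusters.values()):
            for m in members:
                assign[m] = cid
        return np.array([assign[lab] for lab in self.item_labels])

    def sizes(self) -> dict[str, int]:
        return {name: len(members) for name, members in self.clusters.items()}


def _name_groups(groups: list[tuple[int, ...]], labels: tuple[str, ...]) -> dict[str, tuple[str, ...]]:
    """Name each group by canonical composition match, else by leading member."""
    named: dict[str, tuple[str, ...]] = {}
    for group in groups:
        members = tuple(labels[i] for i in group)
        member_set = frozenset(members)
        name = next(
            (nm for nm, comp in CANONICAL_CLUSTERS.items() if comp == member_set), None
        )
        if name is None or name in named:
            name = f"cluster_{members[0]}"
        named[name] = members
    return named


def form_clusters(tree: MergeTree) -> SymptomClusterSet:
    """Apply the cluster-formation rule to an agglomeration history.

    K is the smallest merge index after which every item is grouped with at
    least one other (no singleton remains); the returned partition is the one
    existing immediately after merge K, so the cluster count is
    ``n_leaves - K``.  A warning is logged when the merge heights at and just
    above the cut tie, since "level" is then ambiguous.
    """
    n = tree.n_leaves
    unpaired = n
    K = None
    seen: set[int] = set()
    for k, merge in enumerate(tree.merges, start=1):
        for side in (merge.left, merge.right):
            if len(side) == 1 and side[0] not in seen:
                unpaired -= 1
                seen.add(side[0])
        if unpaired == 0:
            K = k
            break
    assert K is not None  # final merge contains all leaves
    if K < n - 1 and abs(tree.merges[K].height - tree.merges[K - 1].height) < 1e-12:
        logger.warning(
            "tied merge heights at the formation cut (merge %d); partition taken "
            "by merge index",
            K,
        )
    groups = tree.partition_after(K)
    named = _name_groups(groups, tree.labels)
    # Superclusters: how the formed clusters join in the merges above the cut.
    group_name = {g: nm for g, nm in zip(sorted(groups), named)}
    # map from member tuple to the set of formed-cluster names it contains
    contains: dict[tuple[int, ...], tuple[str, ...]] = {
        g: (nm,) for g, nm in group_name.items()
    }
    superclusters: list[tuple[str, ...]] = []
    for merge in tree.merges[K:]:
        joined = tuple(contains[merge.left] + contains[merge.right])
        contains[merge.members] = joined
        superclusters.append(joined)
    return SymptomClusterSet(
        clusters=named,
        formation_level=K,
        superclusters=superclusters,
        item_labels=tree.labels,
    )


def cluster_symptoms(
    scores, labels: tuple[str, ...] = RPQ_ITEMS
) -> tuple[CorrelationMatrix, MergeTree, SymptomClusterSet]:
    """Full clustering stage: Spearman matrix -> profile UPGMA -> formation rule."""
    n = np.asarray(scores).shape[0]
    if n < SMALL_N_WARNING_THRESHOLD:
        logger.warning(
            "preliminary, small n: clustering %d participants (< %d) — interpret "
            "with caution",
            n,
            SMALL_N_WARNING_THRESHOLD,
        )
    corr = spearman_matrix(scores, labels)
    tree = average_linkage(profile_distances(corr), labels)
    return corr, tree, form_clusters(tree)


# ---------------------------------------------------------------------------
# Export and comparison
# ---------------------------------------------------------------------------


def to_newick(tree: MergeTree) -> str:
    """Rooted Newick string with branch lengths; leaves sit at height 0."""

    subtree: dict[tuple[int, ...], tuple[str, float]] = {
        (i,): (lab, 0.0) for i, lab in enumerate(tree.labels)
    }
    for merge in tree.merges:
        lrep, lh = subtree.pop(merge.left)
        rrep, rh = subtree.pop(merge.right)
        rep = f"({lrep}:{merge.height - lh:.10g},{rrep}:{merge.height - rh:.10g})"
        subtree[merge.members] = (rep, merge.height)
    (rep, _), = subtree.values()
    return rep + ";"


def partition_agreement(a: SymptomClusterSet, b: SymptomClusterSet) -> float:
    """Adjusted Rand index between two partitions of the same item set."""
    if set(a.item_labels) != set(b.item_labels):
        raise ValueError("partitions are over different item sets")
    order = a.item_labels
    assign_b = {}
    for cid, members in enumerate(b.clusters.values()):
        for m in members:
            assign_b[m] = cid
    vec_b = np.array([assign_b[lab] for lab in order])
    return float(adjusted_rand_score(a.membership_vector(), vec_b))
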