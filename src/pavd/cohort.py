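"""Cohort-level analysis: clustering, enrichment, pathway ranking.

Samples are grouped by agglomerative complete-linkage clustering of the
PAVd distance matrix (PAVd is a metric, so any distance-based clusterer is
valid; complete linkage is the convention here).  Clusters are
characterized by one-sided hypergeometric enrichment of per-sample
categorical annotations (e.g. tumor stage), and pathways are ranked by how
far apart their group-average activity distributions sit between two chosen
groups (sqrt of the Jensen-Shannon divergence of the averages).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .activity import ActivityMatrix, SampleDistanceMatrix, group_average_distribution, js_divergence
from .io import SampleAnnotations

__all__ = [
    "ClusterAssignment",
    "EnrichmentResult",
    "cluster_samples",
    "enrichment",
    "rank_pathways",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering of the cohort plus the merge tree it was cut from.

    ``labels`` maps every sample to a cluster label in 1..k; label 1 is the
    largest cluster (ties broken by smallest member index).  ``linkage`` is
    the scipy merge-tree record, kept for dendrogram export.
    """

    sample_ids: tuple[str, ...]
    labels: dict[str, int]
    linkage: np.ndarray
    k: int

    def members(self, label: int) -> list[str]:
        return [s for s in self.sample_ids if self.labels[s] == label]

    def cluster_labels(self) -> list[int]:
        return sorted(set(self.labels.values()))

    def labels_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids])

    def to_newick(self) -> str:
        """Dendrogram in Newick, branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return render(tree, tree.dist) + ";"


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided hypergeometric enrichment of a category within a cluster."""

    cluster: int
    category: str
    n_cluster: int      # n: cluster size
    k_in_cluster: int   # k: category members inside the cluster
    n_cohort: int       # N: all clustered samples
    k_cohort: int       # K: category members in the cohort
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.k_in_cluster <= min(self.n_cluster, self.k_cohort):
            raise ValueError("inconsistent enrichment counts")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} out of (0, 1]")


def cluster_samples(dm: SampleDistanceMatrix, k: int) -> ClusterAssignment:
    """Complete-linkage clustering of the PAVd matrix, cut to k clusters.

    Cluster labels are assigned by decreasing cluster size; among equal
    sizes, the cluster containing the smallest sample index comes first.
    """
    s = len(dm.sample_ids)
    if not 2 <= k <= s:
        raise ValueError(f"k must be in [2, {s}], got {k}")
    condensed = squareform(dm.values, checks=False)
    linkage = hierarchy.linkage(condensed, method="complete")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # relabel: largest cluster first, ties by smallest member index
    raw_labels = sorted(set(flat))
    order = sorted(
        raw_labels,
        key=lambda lab: (-int(np.sum(flat == lab)), int(np.argmax(flat == lab))),
    )
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = {sid: relabel[flat[i]] for i, sid in enumerate(dm.sample_ids)}
    return ClusterAssignment(tuple(dm.sample_ids), labels, linkage, len(raw_labels))


def enrichment(
    assignment: ClusterAssignment,
    annotations: SampleAnnotations,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment for every (cluster, category).

    Background is the full clustered cohort (unannotated samples count
    toward cohort and cluster sizes but toward no category).  The p-value is
    P(X >= k) for X hypergeometric with (N population, K successes, n
    draws).  Raw p-values are reported, with no multiplicity adjustment.
    """
    annotations.validate_against(assignment.sample_ids)
    if not annotations.labels:
        raise ValueError("no annotated samples")
    n_cohort = len(assignment.sample_ids)
    categories = annotations.categories()
    results = []
    for cluster in assignment.cluster_labels():
        members = assignment.members(cluster)
        n_cluster = len(members)
        for category in categories:
            k_cohort = sum(1 for v in annotations.labels.values() if v == category)
            k_in = sum(1 for s in members if annotations.labels.get(s) == category)
            p = float(hypergeom.sf(k_in - 1, n_cohort, k_cohort, n_cluster))
            results.append(
                EnrichmentResult(cluster, category, n_cluster, k_in, n_cohort, k_cohort,
                                 min(p, 1.0))
            )
    return results


def rank_pathways(
    R: ActivityMatrix,
    assignment: ClusterAssignment,
    group_a: int,
    group_b: int,
) -> list[tuple[str, float]]:
    """Rank pathways by between-group activity discrepancy.

    The discrepancy of a pathway is sqrt(JS) between the two groups' average
    activity distributions; pathways are returned sorted by decreasing
    discrepancy, ties broken by pathway id.
    """
    members_a = assignment.members(group_a)
    members_b = assignment.members(group_b)
    if not members_a or not members_b:
        raise ValueError(f"empty group ({group_a}: {len(members_a)}, {group_b}: {len(members_b)})")
    scored = []
    for pid in R.pathway_ids:
        avg_a = group_average_distribution(R, pid, members_a)
        avg_b = group_average_distribution(R, pid, members_b)
        scored.append((pid, float(np.sqrt(js_divergence(avg_a.probs, avg_b.probs)))))
    return sorted(scored, key=lambda t: (-t[1], t[0]))
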