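"""Pathway activity distributions, PAVs, and the PAVd sample distance.

For a pathway with candidate networks g_1..g_N (index 0 = normal) and a
sample s, the *pathway activity distribution* is the vector of leave-one-out
likelihood ratios BDeu(g_k | D) / BDeu(g_k | D - {s}), normalized over the N
candidates (via log-sum-exp) to a probability vector.  The sample's *PAV*
collects these distributions across all pathways; the A x S collection over
a cohort is the activity matrix R.

The distance between two samples is

    PAVd(x, y) = sum_i sqrt(JS(p_i || q_i))

with JS the Jensen-Shannon divergence in base 2 (so each pathway term lies
in [0, 1]).  Since sqrt(JS) is itself a metric on distributions, PAVd is a
metric on PAVs: non-negative, symmetric, zero iff equal, and satisfying the
triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .bdeu import ScoreConfig, node_loo_terms
from .io import BinaryExpressionMatrix
from .networks import CandidateNetworkFamily

__all__ = [
    "ActivityDistribution",
    "PAV",
    "ActivityMatrix",
    "SampleDistanceMatrix",
    "activity_distribution",
    "compute_pav",
    "compute_activity_matrix",
    "js_divergence",
    "pavd",
    "distance_matrix",
    "group_average_distribution",
]


@dataclass(frozen=True)
class ActivityDistribution:
    """Probability vector over one pathway's candidate networks for one sample."""

    pathway_id: str
    candidate_labels: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if len(probs) != len(self.candidate_labels):
            raise ValueError(
                f"{self.pathway_id}: {len(probs)} probabilities for "
                f"{len(self.candidate_labels)} candidates"
            )
        if np.any(probs < 0):
            raise ValueError(f"{self.pathway_id}: negative probability")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ValueError(f"{self.pathway_id}: probabilities sum to {probs.sum()}")

    @property
    def n_candidates(self) -> int:
        return len(self.probs)

    def modal_candidate(self) -> str:
        """Label of the highest-probability candidate (first on ties)."""
        return self.candidate_labels[int(np.argmax(self.probs))]


@dataclass(frozen=True)
class PAV:
    """A sample's pathway activity vector: one distribution per pathway."""

    sample_id: str
    distributions: tuple[ActivityDistribution, ...]

    def __len__(self) -> int:
        return len(self.distributions)


class ActivityMatrix:
    """The A x S activity matrix R; column j is sample j's PAV."""

    def __init__(
        self,
        pathway_ids: list[str],
        sample_ids: list[str],
        candidate_labels: dict[str, tuple[str, ...]],
        probs: dict[str, np.ndarray],
    ) -> None:
        self.pathway_ids = list(pathway_ids)
        self.sample_ids = list(sample_ids)
        self.candidate_labels = dict(candidate_labels)
        self.probs = {p: np.asarray(v, dtype=float) for p, v in probs.items()}
        for pid in self.pathway_ids:
            n = len(self.candidate_labels[pid])
            if self.probs[pid].shape != (len(self.sample_ids), n):
                raise ValueError(
                    f"{pid}: probability block shape {self.probs[pid].shape}, "
                    f"expected ({len(self.sample_ids)}, {n})"
                )
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cell(self, pathway_id: str, sample_id: str) -> ActivityDistribution:
        j = self._sample_index[sample_id]
        return ActivityDistribution(
            pathway_id, self.candidate_labels[pathway_id], self.probs[pathway_id][j]
        )

    def pav(self, sample_id: str) -> PAV:
        return PAV(sample_id, tuple(self.cell(p, sample_id) for p in self.pathway_ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityMatrix):
            return NotImplemented
        return (
            self.pathway_ids == other.pathway_ids
            and self.sample_ids == other.sample_ids
            and self.candidate_labels == other.candidate_labels
            and all(np.array_equal(self.probs[p], other.probs[p]) for p in self.pathway_ids)
        )

    def allclose(self, other: "ActivityMatrix", atol: float = 1e-12) -> bool:
        return (
            self.pathway_ids == other.pathway_ids
            and self.sample_ids == other.sample_ids
            and self.candidate_labels == other.candidate_labels
            and all(
                np.allclose(self.probs[p], other.probs[p], atol=atol, rtol=0)
                for p in self.pathway_ids
            )
        )


@dataclass(frozen=True)
class SampleDistanceMatrix:
    """Symmetric S x S PAVd distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        s = len(self.sample_ids)
        if values.shape != (s, s):
            raise ValueError(f"distance matrix shape {values.shape} for {s} samples")
        if np.any(values < 0):
            raise ValueError("negative distances")
        if not np.array_equal(values, values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("nonzero diagonal")


def _family_log_ratios(
    family: CandidateNetworkFamily,
    data: BinaryExpressionMatrix,
    config: ScoreConfig,
) -> np.ndarray:
    """(S, N) leave-one-out log ratios for every sample x candidate.

    Candidate networks within a family differ from the normal network only
    at the silenced edge's child, so per-node predictive terms are cached by
    (node, parent set) and reused across candidates.
    """
    if data.n_samples < 2:
        raise ValueError("leave-one-out needs >= 2 samples")
    ess = config.ess
    cache: dict[tuple[str, tuple[str, ...]], np.ndarray] = {}

    def terms(node: str, parents: tuple[str, ...]) -> np.ndarray:
        key = (node, parents)
        if key not in cache:
            pv = np.array([data.gene_row(p) for p in parents]) if parents else None
            cache[key] = node_loo_terms(data.gene_row(node), pv, ess)
        return cache[key]

    normal = family.normal
    normal_total = np.zeros(data.n_samples)
    normal_terms: dict[str, np.ndarray] = {}
    for node in normal.nodes:
        normal_terms[node] = terms(node, normal.parents(node))
        normal_total += normal_terms[node]

    log_ratios = np.empty((data.n_samples, family.n_candidates))
    log_ratios[:, 0] = normal_total
    for k, ((u, v), variant) in enumerate(family.variants, start=1):
        # only the silenced edge's child v changes parent set
        log_ratios[:, k] = normal_total - normal_terms[v] + terms(v, variant.parents(v))
    return log_ratios


def activity_distribution(
    family: CandidateNetworkFamily,
    data: BinaryExpressionMatrix,
    sample_id: str,
    config: ScoreConfig = ScoreConfig(),
) -> ActivityDistribution:
    """The sample's normalized distribution over the family's candidates."""
    j = data.sample_position(sample_id)
    log_ratios = _family_log_ratios(family, data, config)[j]
    return ActivityDistribution(
        family.pathway_id, family.candidate_labels, softmax(log_ratios)
    )


def compute_pav(
    families: list[CandidateNetworkFamily],
    data: BinaryExpressionMatrix,
    sample_id: str,
    config: ScoreConfig = ScoreConfig(),
) -> PAV:
    """The sample's pathway activity vector over the given pathway list."""
    return PAV(
        sample_id,
        tuple(activity_distribution(f, data, sample_id, config) for f in families),
    )


def compute_activity_matrix(
    families: list[CandidateNetworkFamily],
    data: BinaryExpressionMatrix,
    config: ScoreConfig = ScoreConfig(),
) -> ActivityMatrix:
    """The full A x S activity matrix R for the cohort."""
    if data.n_samples < 2:
        raise ValueError("activity matrix needs >= 2 samples")
    probs: dict[str, np.ndarray] = {}
    labels: dict[str, tuple[str, ...]] = {}
    for family in families:
        log_ratios = _family_log_ratios(family, data, config)
        probs[family.pathway_id] = softmax(log_ratios, axis=1)
        labels[family.pathway_id] = family.candidate_labels
    return ActivityMatrix(
        [f.pathway_id for f in families], list(data.sample_ids), labels, probs
    )


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence in base 2: JS = H(m) - (H(p) + H(q)) / 2.

    Both arguments must be probability vectors of equal length (entries
    >= 0, summing to 1 within 1e-6); the 0 log 0 terms are 0.  The result
    lies in [0, 1] bits.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    for name, vec in (("p", p), ("q", q)):
        if np.any(vec < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(float(vec.sum()) - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {vec.sum()}, not 1")
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    return max(0.0, 0.5 * _kl(p) + 0.5 * _kl(q))


def pavd(x: PAV, y: PAV) -> float:
    """Pathway activity vector distance: sum over pathways of sqrt(JS)."""
    if len(x) != len(y):
        raise ValueError("PAVs cover different numbers of pathways")
    total = 0.0
    for dx, dy in zip(x.distributions, y.distributions):
        if dx.pathway_id != dy.pathway_id or dx.n_candidates != dy.n_candidates:
            raise ValueError(
                f"pathway mismatch: {dx.pathway_id}({dx.n_candidates}) vs "
                f"{dy.pathway_id}({dy.n_candidates})"
            )
        total += float(np.sqrt(js_divergence(dx.probs, dy.probs)))
    return total


def distance_matrix(R: ActivityMatrix) -> SampleDistanceMatrix:
    """All pairwise PAVd distances between the cohort's samples."""
    if R.n_samples < 2:
        raise ValueError("need >= 2 samples")
    pavs = [R.pav(s) for s in R.sample_ids]
    s = R.n_samples
    values = np.zeros((s, s))
    for l in range(s):
        for m in range(l + 1, s):
            d = pavd(pavs[l], pavs[m])
            values[l, m] = d
            values[m, l] = d
    return SampleDistanceMatrix(list(R.sample_ids), values)


def group_average_distribution(
    R: ActivityMatrix,
    pathway_id: str,
    sample_ids,
) -> ActivityDistribution:
    """Element-wise mean of a group's distributions for one pathway.

    The mean of probability vectors is itself a probability vector; this is
    the group-level activity pattern used to contrast patient groups.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("empty sample group")
    rows = np.vstack([R.cell(pathway_id, s).probs for s in sample_ids])
    mean = rows.mean(axis=0)
    mean = mean / mean.sum()  # renormalize away accumulated rounding
    return ActivityDistribution(pathway_id, R.candidate_labels[pathway_id], mean)
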