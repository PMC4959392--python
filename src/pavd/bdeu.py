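"""BDeu marginal likelihood of candidate networks on binary data.

The Bayesian Dirichlet equivalent uniform (BDeu) score is the log marginal
likelihood of a discrete Bayesian network under a Dirichlet parameter prior
whose total pseudo-count (the *equivalent sample size*, ESS) is spread
uniformly over the parameter cells: for node i with r_i states and q_i
parent configurations, alpha_ijk = ESS / (r_i q_i).  Markov-equivalent
structures receive identical scores under this prior.

A single sample cannot be scored on its own — with a uniform prior every
structure assigns it the same probability — so per-sample structure
likelihoods are obtained as a leave-one-out ratio:

    P(g | s_j) = BDeu(g | D) / BDeu(g | D - {s_j})

which is exactly the posterior-predictive probability of sample s_j under
structure g given the remaining cohort.  The log ratio is computed by
decrementing the held-out sample's cell from the full-data count tables,
which collapses per node to

    ln((alpha_ijk + N_ijk - 1) / (alpha_ij + N_ij - 1))

evaluated at the sample's own (parent configuration, state) cell.  This is
contract-equal to re-running the full score on D - {s_j} and is O(nodes)
per sample.

All arithmetic is in log space (log-gamma); raw BDeu values underflow double
precision for realistic pathway sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io import BinaryExpressionMatrix
from .networks import PathwayNetwork

__all__ = [
    "ScoreConfig",
    "NodeCounts",
    "FamilyCounts",
    "accumulate_counts",
    "bdeu_log_score",
    "loo_log_ratio",
    "node_loo_terms",
]


@dataclass(frozen=True)
class ScoreConfig:
    """BDeu hyperparameters.  ``ess`` is the equivalent sample size (> 0)."""

    ess: float = 1.0

    def __post_init__(self) -> None:
        if not self.ess > 0:
            raise ValueError(f"ess must be positive, got {self.ess}")


@dataclass(frozen=True)
class NodeCounts:
    """Sufficient statistics for one node: N_jk over (parent config, state)."""

    node: str
    parents: tuple[str, ...]
    r: int
    q: int
    n_jk: np.ndarray  # shape (q, r), non-negative integers

    def __post_init__(self) -> None:
        if self.n_jk.shape != (self.q, self.r):
            raise ValueError(f"{self.node}: count table shape {self.n_jk.shape}")
        if np.any(self.n_jk < 0):
            raise ValueError(f"{self.node}: negative counts")

    @property
    def n_j(self) -> np.ndarray:
        return self.n_jk.sum(axis=1)


@dataclass(frozen=True)
class FamilyCounts:
    """Per-node sufficient statistics for a network on a sample subset."""

    nodes: tuple[NodeCounts, ...]
    n_samples: int


def _parent_configs(data: BinaryExpressionMatrix, parents: tuple[str, ...],
                    cols: np.ndarray) -> np.ndarray:
    """Binary-encode each sample's parent value vector (parents sorted)."""
    if not parents:
        return np.zeros(len(cols), dtype=np.int64)
    bits = np.array([data.gene_row(p)[cols] for p in parents], dtype=np.int64)
    weights = 1 << np.arange(len(parents), dtype=np.int64)
    return weights @ bits


def _subset_columns(data: BinaryExpressionMatrix, sample_subset) -> np.ndarray:
    if sample_subset is None:
        return np.arange(data.n_samples)
    return np.array(sorted(data.sample_position(s) for s in sample_subset), dtype=int)


def accumulate_counts(
    network: PathwayNetwork,
    data: BinaryExpressionMatrix,
    sample_subset=None,
) -> FamilyCounts:
    """Exact contingency counts for every node over the sample subset.

    ``sample_subset`` is a collection of sample ids (``None`` = all
    samples); an empty subset yields all-zero tables.
    """
    cols = _subset_columns(data, sample_subset)
    nodes = []
    for node in network.nodes:
        parents = network.parents(node)
        q = 1 << len(parents)
        child = data.gene_row(node)[cols].astype(np.int64)
        config = _parent_configs(data, parents, cols)
        n_flat = np.bincount(config * 2 + child, minlength=q * 2)
        nodes.append(NodeCounts(node, parents, 2, q, n_flat.reshape(q, 2)))
    return FamilyCounts(tuple(nodes), len(cols))


def _node_log_score(counts: NodeCounts, ess: float) -> float:
    a_jk = ess / (counts.r * counts.q)
    a_j = ess / counts.q
    n_j = counts.n_j
    return float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + counts.n_jk) - gammaln(a_jk))
    )


def bdeu_log_score(
    network: PathwayNetwork,
    data: BinaryExpressionMatrix,
    sample_subset=None,
    config: ScoreConfig = ScoreConfig(),
) -> float:
    """Log marginal likelihood of the subset's data under the network.

    Empty subset returns 0 (log of the empty product).  Always <= 0 for
    binary data.
    """
    counts = accumulate_counts(network, data, sample_subset)
    return sum(_node_log_score(nc, config.ess) for nc in counts.nodes)


def node_loo_terms(
    child: np.ndarray,
    parents_values: np.ndarray | None,
    ess: float,
) -> np.ndarray:
    """Per-sample log posterior-predictive term for one node.

    ``child`` is the node's 0/1 row over all S samples; ``parents_values``
    is a (P, S) 0/1 array of its parents' rows (``None`` or empty for a
    root).  Entry s is ln P(child_s | parents_s, D - {s}) under the node's
    Dirichlet posterior — the node's contribution to the leave-one-out log
    ratio of every sample at once.
    """
    child = np.asarray(child, dtype=np.int64)
    n = child.size
    if parents_values is None or len(parents_values) == 0:
        q = 1
        config = np.zeros(n, dtype=np.int64)
    else:
        parents_values = np.asarray(parents_values, dtype=np.int64)
        q = 1 << parents_values.shape[0]
        weights = 1 << np.arange(parents_values.shape[0], dtype=np.int64)
        config = weights @ parents_values
    a_jk = ess / (2 * q)
    a_j = ess / q
    idx = config * 2 + child
    n_flat = np.bincount(idx, minlength=q * 2).astype(float)
    n_j = n_flat.reshape(q, 2).sum(axis=1)
    return np.log(a_jk + n_flat[idx] - 1.0) - np.log(a_j + n_j[config] - 1.0)


def loo_log_ratio(
    network: PathwayNetwork,
    data: BinaryExpressionMatrix,
    sample_id: str,
    config: ScoreConfig = ScoreConfig(),
) -> float:
    """Log of BDeu(g | D) / BDeu(g | D - {s}): the held-out sample's
    log posterior-predictive probability.  Always < 0 for binary data."""
    if data.n_samples < 2:
        raise ValueError("leave-one-out needs >= 2 samples (D - {s} would be empty)")
    j = data.sample_position(sample_id)
    total = 0.0
    for node in network.nodes:
        parents = network.parents(node)
        pv = np.array([data.gene_row(p) for p in parents]) if parents else None
        total += float(node_loo_terms(data.gene_row(node), pv, config.ess)[j])
    return total
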