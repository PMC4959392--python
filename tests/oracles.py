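"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written without the package's numerics:
dict-based counting, math.comb, explicit enumeration.  Slow but obviously
correct at tiny sizes.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict


def sequential_bdeu_log_score(
    parents_map: dict[str, tuple[str, ...]],
    samples: list[dict[str, int]],
    ess: float = 1.0,
) -> float:
    """Marginal likelihood as a sequential product of posterior predictives.

    Processes samples one at a time; each sample's probability is the
    product over nodes of (alpha_jk + n_jk) / (alpha_j + n_j) with counts
    taken over the previously seen samples only.  The product telescopes to
    the BDeu marginal likelihood.
    """
    log_p = 0.0
    counts: dict[str, dict[tuple, list[int]]] = defaultdict(
        lambda: defaultdict(lambda: [0, 0])
    )
    for sample in samples:
        for node, parents in parents_map.items():
            cfg = tuple(sample[p] for p in parents)
            q = 2 ** len(parents)
            a_jk = ess / (2 * q)
            a_j = ess / q
            cell = counts[node][cfg]
            n_k = cell[sample[node]]
            log_p += math.log((a_jk + n_k) / (a_j + cell[0] + cell[1]))
            cell[sample[node]] += 1
    return log_p


def all_three_node_dags(nodes: tuple[str, str, str] = ("A", "B", "C")):
    """Every labeled DAG on three nodes (there are 25)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    dags = []
    for bits in itertools.product([0, 1], repeat=len(pairs)):
        edges = [p for p, b in zip(pairs, bits) if b]
        edge_set = set(edges)
        if any((v, u) in edge_set for u, v in edges):
            continue
        if _is_acyclic(nodes, edges):
            dags.append(tuple(sorted(edges)))
    return dags


def _is_acyclic(nodes, edges) -> bool:
    remaining = set(nodes)
    edge_list = list(edges)
    while remaining:
        sinks = [n for n in remaining if not any(u == n and v in remaining for u, v in edge_list)]
        if not sinks:
            return False
        remaining -= set(sinks)
    return True


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct enumeration."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total
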