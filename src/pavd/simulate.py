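"""Synthetic cohorts with known pathway mechanisms.

Binary expression is drawn by ancestral sampling from discrete Bayesian
networks over designated pathway genes.  Each sample group is generated
under its own mechanism: for every pathway, either the normal network or a
variant with one *silenced* edge, where silencing makes the child node
ignore that parent — the generative mirror of modeling pathway disruption
as removing an interaction.

Conditional probability tables are simple and strongly informative: root
genes are Bernoulli(0.5); a child copies a Boolean aggregate of its parents
(AND or OR, drawn per node from the seed) with probability ``beta`` and
flips otherwise.  ``beta`` must exceed 0.5 so edges carry signal; ``beta``
= 1 is the deterministic limit.

The generator also emits the pathway gene sets (GMT-ready) and the
interaction catalog (SIF-ready, directed relation labels) so the entire
pipeline — network assembly, scoring, distance, clustering — can run
end-to-end against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BinaryExpressionMatrix, GeneSet, InteractionCatalog
from .networks import Edge, PathwayNetwork

__all__ = [
    "NodeCPD",
    "SyntheticCohortSpec",
    "random_cpds",
    "sample_cohort",
    "default_two_group_spec",
    "write_cohort",
]

# direction-preserving SIF label so assembly reconstructs the true DAG
_RELATION = "controls-state-change-of"


@dataclass(frozen=True)
class NodeCPD:
    """One node's conditional distribution: aggregate parents, copy or flip."""

    node: str
    parents: tuple[str, ...]
    aggregator: str  # "and" or "or"; irrelevant for roots and single parents
    beta: float

    def p_one(self, parent_states: np.ndarray | None) -> np.ndarray:
        """P(node = 1) per sample given a (P, n) parent-state array."""
        if parent_states is None or len(parent_states) == 0:
            raise ValueError("root nodes have no conditional distribution")
        if self.aggregator == "and":
            implied = np.min(parent_states, axis=0)
        else:
            implied = np.max(parent_states, axis=0)
        return np.where(implied == 1, self.beta, 1.0 - self.beta)


def random_cpds(network: PathwayNetwork, beta: float, seed: int) -> dict[str, NodeCPD]:
    """Draw conditional probability tables for every non-root node.

    Each child's parent aggregator (AND vs OR) is drawn once from the seed;
    roots are implicit Bernoulli(0.5) and carry no entry.  Deterministic
    given (network, beta, seed).
    """
    if not 0.5 < beta <= 1.0:
        raise ValueError(f"beta must be in (0.5, 1], got {beta}")
    rng = np.random.default_rng(seed)
    cpds: dict[str, NodeCPD] = {}
    for node in sorted(network.nodes):
        parents = network.parents(node)
        if parents:
            aggregator = "and" if rng.random() < 0.5 else "or"
            cpds[node] = NodeCPD(node, parents, aggregator, beta)
    return cpds


@dataclass
class SyntheticCohortSpec:
    """Ground-truth description of a synthetic cohort.

    ``group_mechanisms[label][pathway_id]`` is either the string
    ``"normal"`` or the silenced edge (a (parent, child) tuple that must
    exist in that pathway).  Pathways not named in a group's mechanism run
    normally.
    """

    pathways: list[PathwayNetwork]
    group_mechanisms: dict[str, dict[str, Edge | str]]
    group_sizes: dict[str, int]
    beta: float = 0.9
    n_background: int = 0
    seed: int = 0
    _by_id: dict[str, PathwayNetwork] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.5 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0.5, 1], got {self.beta}")
        self._by_id = {p.pathway_id: p for p in self.pathways}
        if len(self._by_id) != len(self.pathways):
            raise ValueError("duplicate pathway ids")
        if set(self.group_mechanisms) != set(self.group_sizes):
            raise ValueError("group_mechanisms and group_sizes name different groups")
        for label, size in self.group_sizes.items():
            if size < 1:
                raise ValueError(f"group {label!r} has size {size}")
        for label, mechanism in self.group_mechanisms.items():
            for pid, action in mechanism.items():
                if pid not in self._by_id:
                    raise ValueError(f"group {label!r} names unknown pathway {pid!r}")
                if action != "normal":
                    if tuple(action) not in self._by_id[pid].edges:
                        raise ValueError(
                            f"group {label!r}: silenced edge {action} not in {pid!r}"
                        )
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")

    def silenced_edge(self, group: str, pathway_id: str) -> Edge | None:
        action = self.group_mechanisms[group].get(pathway_id, "normal")
        return None if action == "normal" else tuple(action)


def _sample_pathway(
    network: PathwayNetwork,
    cpds: dict[str, NodeCPD],
    silenced: Edge | None,
    n: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Ancestral sampling of n joint states; a silenced edge's child drops
    that parent (falling back to Bernoulli(0.5) if no parent remains)."""
    states: dict[str, np.ndarray] = {}
    for node in network.topological_order():
        cpd = cpds.get(node)
        parents = () if cpd is None else cpd.parents
        if silenced is not None and silenced[1] == node:
            parents = tuple(p for p in parents if p != silenced[0])
        if not parents:
            p_one = np.full(n, 0.5)
        else:
            p_one = cpd.p_one(np.vstack([states[p] for p in parents]))
        states[node] = (rng.random(n) < p_one).astype(np.int8)
    return states


def sample_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[BinaryExpressionMatrix, dict[str, str], list[GeneSet], InteractionCatalog]:
    """Generate the cohort: binary matrix, true group labels, GMT/SIF inputs.

    Sample ids are ``S0000..`` in group order; background genes are
    independent Bernoulli(0.5).  Byte-for-byte reproducible from the spec.
    """
    root = np.random.SeedSequence(spec.seed)
    cpd_seeds, sampling_seed = root.spawn(2)
    cpds = {
        p.pathway_id: random_cpds(p, spec.beta, int(s.generate_state(1)[0] % (2**31)))
        for p, s in zip(spec.pathways, cpd_seeds.spawn(len(spec.pathways)))
    }
    rng = np.random.default_rng(sampling_seed)

    groups = list(spec.group_sizes)
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    columns: dict[str, list[np.ndarray]] = {}
    gene_order: list[str] = []
    for p in spec.pathways:
        gene_order.extend(p.nodes)
    background = [f"BG{i:04d}" for i in range(spec.n_background)]
    gene_order.extend(background)

    blocks: list[np.ndarray] = []
    offset = 0
    for group in groups:
        n = spec.group_sizes[group]
        ids = [f"S{offset + i:04d}" for i in range(n)]
        offset += n
        sample_ids.extend(ids)
        for sid in ids:
            labels[sid] = group
        rows: list[np.ndarray] = []
        for pathway in spec.pathways:
            states = _sample_pathway(
                pathway, cpds[pathway.pathway_id],
                spec.silenced_edge(group, pathway.pathway_id), n, rng,
            )
            rows.extend(states[g] for g in pathway.nodes)
        for _ in background:
            rows.append((rng.random(n) < 0.5).astype(np.int8))
        blocks.append(np.vstack(rows))
    values = np.hstack(blocks)

    gene_sets = [
        GeneSet(p.pathway_id, f"synthetic pathway ({len(p.nodes)} genes)", p.nodes)
        for p in spec.pathways
    ]
    catalog = InteractionCatalog(
        (u, v, _RELATION) for p in spec.pathways for (u, v) in p.edges
    )
    matrix = BinaryExpressionMatrix(gene_order, sample_ids, values)
    return matrix, labels, gene_sets, catalog


def default_two_group_spec(
    seed: int,
    n_pathways: int = 10,
    genes_per_pathway: int = 5,
    group_size: int = 50,
    beta: float = 0.9,
    n_affected: int = 5,
    n_background: int = 20,
) -> SyntheticCohortSpec:
    """The reference two-subtype study design.

    Chain pathways of ``genes_per_pathway`` genes; group A runs every
    pathway normally, group B silences one designated edge in the first
    ``n_affected`` pathways (the edge drawn per pathway from the seed).
    Defaults model a moderately sized two-subtype cohort: 10 pathways of 5
    genes, 50 samples per group, coupling strength 0.9, and 20 unstructured
    background genes.
    """
    if not 1 <= n_affected <= n_pathways:
        raise ValueError("n_affected must be in [1, n_pathways]")
    pathways = []
    for p in range(n_pathways):
        genes = tuple(f"P{p:02d}G{i}" for i in range(genes_per_pathway))
        edges = tuple((genes[i], genes[i + 1]) for i in range(genes_per_pathway - 1))
        pathways.append(PathwayNetwork(f"PATHWAY{p:02d}", genes, edges))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB0)))
    mech_b: dict[str, Edge | str] = {}
    for p in range(n_affected):
        edges = pathways[p].edges
        mech_b[pathways[p].pathway_id] = edges[int(rng.integers(len(edges)))]
    return SyntheticCohortSpec(
        pathways=pathways,
        group_mechanisms={"A": {}, "B": mech_b},
        group_sizes={"A": group_size, "B": group_size},
        beta=beta,
        n_background=n_background,
        seed=seed,
    )


def write_cohort(spec: SyntheticCohortSpec, out_dir) -> None:
    """Write binary.tsv, sets.gmt, interactions.sif, labels.tsv to a directory."""
    from pathlib import Path

    from .io import write_binary_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, labels, gene_sets, catalog = sample_cohort(spec)
    write_binary_tsv(matrix, out / "binary.tsv")
    with open(out / "sets.gmt", "w") as handle:
        for gs in gene_sets:
            handle.write("\t".join([gs.set_id, gs.description, *gs.genes]) + "\n")
    with open(out / "interactions.sif", "w") as handle:
        for source, target, relation in catalog:
            handle.write(f"{source}\t{relation}\t{target}\n")
    with open(out / "labels.tsv", "w") as handle:
        handle.write("sample\tgroup\n")
        for sid in matrix.sample_ids:
            handle.write(f"{sid}\t{labels[sid]}\n")
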