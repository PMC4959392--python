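"""Readers and writers for the standard formats the pipeline touches.

Gene sets arrive as GMT (tab-separated: name, description, member genes),
pairwise genetic interactions as SIF (source, relation, target), expression
data as a genes x samples TSV with a sample header row and a gene-symbol
first column, and per-sample categorical annotations as a two-column TSV.
Intermediate activity matrices use a line-oriented text format defined in
:func:`write_activity_matrix` so every pipeline stage can be run and
inspected independently.

All readers are strict: a line either parses or raises :class:`ParseError`
naming the offending line.  The only silent drops are the documented ones
(self-loop interactions, over-cap gene sets) and those are counted in the
module logger.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "GeneSet",
    "InteractionCatalog",
    "ExpressionMatrix",
    "BinaryExpressionMatrix",
    "SampleAnnotations",
    "read_gmt",
    "read_sif",
    "read_expression_tsv",
    "read_binary_tsv",
    "write_binary_tsv",
    "read_annotations_tsv",
    "write_activity_matrix",
    "read_activity_matrix",
    "write_distance_matrix",
    "read_distance_matrix",
]


class ParseError(ValueError):
    """A file violated its stated grammar; the message names the location."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT line): identifier, description, members."""

    set_id: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.set_id!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


class InteractionCatalog:
    """A set of pairwise genetic interactions (source, target, relation).

    Self-loops are rejected at construction.  Each (source, target,
    relation) triple is stored once; the relation label is preserved for
    provenance but downstream network assembly uses only the gene pair.
    """

    def __init__(self, interactions: Iterable[tuple[str, str, str]] = ()) -> None:
        self._triples: set[tuple[str, str, str]] = set()
        for source, target, relation in interactions:
            if source == target:
                raise ValueError(f"self-loop interaction {source!r}")
            self._triples.add((source, target, relation))

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(sorted(self._triples))

    def __contains__(self, triple: tuple[str, str, str]) -> bool:
        return triple in self._triples

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionCatalog):
            return NotImplemented
        return self._triples == other._triples

    def pairs(self) -> set[tuple[str, str]]:
        """Unordered view of the (source, target) pairs, labels dropped."""
        return {(s, t) for s, t, _ in self._triples}


def _check_axis_unique(labels: list[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} {lab!r}")
        seen.add(lab)


class ExpressionMatrix:
    """Normalized gene-level counts: genes x samples, finite and >= 0."""

    _allow_binary = False

    def __init__(self, gene_ids: Iterable[str], sample_ids: Iterable[str], values) -> None:
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = np.asarray(values, dtype=float)
        _check_axis_unique(self.gene_ids, "gene")
        _check_axis_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


class BinaryExpressionMatrix(ExpressionMatrix):
    """Discretized expression: every value exactly 0 (silent) or 1 (expressed)."""

    def __init__(self, gene_ids, sample_ids, values) -> None:
        super().__init__(gene_ids, sample_ids, values)
        if not np.all((self.values == 0) | (self.values == 1)):
            raise ValueError("binary matrix values must all be 0 or 1")
        self.values = self.values.astype(np.int8)
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(self.sample_ids)}

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def sample_position(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None


@dataclass
class SampleAnnotations:
    """sample_id -> category label; samples may be unannotated."""

    labels: dict[str, str] = field(default_factory=dict)

    def validate_against(self, sample_ids: Iterable[str]) -> None:
        cohort = set(sample_ids)
        unknown = sorted(set(self.labels) - cohort)
        if unknown:
            raise ValueError(f"annotated samples not in cohort: {unknown}")

    def categories(self) -> list[str]:
        return sorted(set(self.labels.values()))


# ---------------------------------------------------------------------------
# readers


def read_gmt(path, max_genes: int | None = None) -> list[GeneSet]:
    """Parse a GMT file into gene sets.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    genes within a line are dropped keeping the first occurrence.  When
    ``max_genes`` is given, sets with more members (after deduplication) are
    excluded entirely rather than truncated; the number of excluded sets is
    logged.
    """
    if max_genes is not None and max_genes <= 0:
        raise ValueError("max_genes must be a positive integer")
    sets: list[GeneSet] = []
    n_dropped = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if max_genes is not None and len(genes) > max_genes:
                n_dropped += 1
                continue
            sets.append(GeneSet(name, description, tuple(genes)))
    if n_dropped:
        logger.info("read_gmt: dropped %d gene sets exceeding %d genes", n_dropped, max_genes)
    return sets


def read_sif(path) -> InteractionCatalog:
    """Parse a SIF file (``source relation target``, tab- or space-separated).

    Self-loop lines are dropped with a logged count; duplicate triples
    collapse by set semantics.
    """
    triples: set[tuple[str, str, str]] = set()
    n_self_loops = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: SIF line needs exactly 3 fields, got {len(fields)}"
                )
            source, relation, target = fields
            if source == target:
                n_self_loops += 1
                continue
            triples.add((source, target, relation))
    if n_self_loops:
        logger.info("read_sif: dropped %d self-loop interactions", n_self_loops)
    return InteractionCatalog(triples)


def _read_matrix_tsv(path) -> tuple[list[str], list[str], np.ndarray]:
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(f"{path}:1: header has no sample columns")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        row: list[float] = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                value = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                ) from None
            if math.isnan(value):
                raise ParseError(f"{path}:{lineno}: NaN value in column {col}")
            row.append(value)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no gene rows")
    try:
        _check_axis_unique(gene_ids, "gene")
        _check_axis_unique(sample_ids, "sample")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    return gene_ids, sample_ids, np.array(rows, dtype=float)


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (sample header row, gene-symbol first column)."""
    gene_ids, sample_ids, values = _read_matrix_tsv(path)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def read_binary_tsv(path) -> BinaryExpressionMatrix:
    """Read a pre-discretized genes x samples TSV of 0/1 values."""
    gene_ids, sample_ids, values = _read_matrix_tsv(path)
    if not np.all((values == 0) | (values == 1)):
        raise ParseError(f"{path}: matrix contains values other than 0 and 1")
    return BinaryExpressionMatrix(gene_ids, sample_ids, values)


def write_binary_tsv(matrix: BinaryExpressionMatrix, path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            handle.write(gene + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_annotations_tsv(path) -> SampleAnnotations:
    """Read a two-column TSV of (sample_id, category label); header optional."""
    labels: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: annotation line needs 2 fields, got {len(fields)}"
                )
            sample_id, label = fields
            if lineno == 1 and sample_id.lower() in {"sample", "sample_id"}:
                continue
            if sample_id in labels:
                raise ParseError(f"{path}:{lineno}: duplicate annotation for {sample_id!r}")
            labels[sample_id] = label
    return SampleAnnotations(labels)


# ---------------------------------------------------------------------------
# activity-matrix serialization
#
# Line-oriented text format, diffable and ragged-N friendly:
#   #pavd-activity-matrix v1
#   @pathway<TAB>pathway_id<TAB>label_1|label_2|...       (one per pathway)
#   pathway_id<TAB>sample_id<TAB>p_1<TAB>p_2<TAB>...      (one per cell)
# Candidate label 0 is always "Normal"; variant labels name the silenced edge.

_MAGIC = "#pavd-activity-matrix v1"


def write_activity_matrix(matrix, path) -> None:
    """Serialize an :class:`pavd.activity.ActivityMatrix` to text.

    Refuses distributions whose probabilities do not sum to 1 within 1e-6.
    """
    with open(path, "w") as handle:
        handle.write(_MAGIC + "\n")
        for pid in matrix.pathway_ids:
            labels = matrix.candidate_labels[pid]
            handle.write("@pathway\t" + pid + "\t" + "|".join(labels) + "\n")
        for pid in matrix.pathway_ids:
            probs = matrix.probs[pid]
            for j, sid in enumerate(matrix.sample_ids):
                row = probs[j]
                total = float(np.sum(row))
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"distribution for pathway {pid!r}, sample {sid!r} "
                        f"sums to {total}, not 1"
                    )
                handle.write(
                    pid + "\t" + sid + "\t" + "\t".join(repr(float(p)) for p in row) + "\n"
                )


def read_activity_matrix(path):
    """Inverse of :func:`write_activity_matrix`; round trips to < 1e-12."""
    from .activity import ActivityMatrix  # local import: io stays a leaf module

    candidate_labels: dict[str, list[str]] = {}
    pathway_ids: list[str] = []
    cells: dict[str, dict[str, np.ndarray]] = {}
    sample_order: list[str] = []
    with open(path) as handle:
        first = handle.readline().rstrip("\n")
        if first != _MAGIC:
            raise ParseError(f"{path}:1: not an activity-matrix file")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[0] == "@pathway":
                if len(fields) != 3:
                    raise ParseError(f"{path}:{lineno}: malformed @pathway line")
                pid, labels = fields[1], fields[2].split("|")
                if pid in candidate_labels:
                    raise ParseError(f"{path}:{lineno}: duplicate pathway {pid!r}")
                candidate_labels[pid] = labels
                pathway_ids.append(pid)
                cells[pid] = {}
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: malformed record line")
            pid, sid = fields[0], fields[1]
            if pid not in candidate_labels:
                raise ParseError(f"{path}:{lineno}: record for undeclared pathway {pid!r}")
            probs = np.array([float(x) for x in fields[2:]], dtype=float)
            if len(probs) != len(candidate_labels[pid]):
                raise ParseError(
                    f"{path}:{lineno}: {len(probs)} probabilities for "
                    f"{len(candidate_labels[pid])} candidates"
                )
            cells[pid][sid] = probs
            if sid not in sample_order:
                sample_order.append(sid)
    probs_by_pathway = {}
    for pid in pathway_ids:
        missing = [s for s in sample_order if s not in cells[pid]]
        if missing:
            raise ParseError(f"{path}: pathway {pid!r} missing samples {missing}")
        probs_by_pathway[pid] = np.vstack([cells[pid][s] for s in sample_order])
    return ActivityMatrix(
        pathway_ids=pathway_ids,
        sample_ids=sample_order,
        candidate_labels={p: tuple(candidate_labels[p]) for p in pathway_ids},
        probs=probs_by_pathway,
    )


def write_distance_matrix(sample_ids: list[str], values: np.ndarray, path) -> None:
    """Write a square sample distance matrix as TSV with a sample header."""
    frame = pd.DataFrame(values, index=sample_ids, columns=sample_ids)
    frame.to_csv(path, sep="\t", index_label="sample")


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ParseError(f"{path}: distance matrix rows and columns differ")
    return list(frame.index), frame.to_numpy(dtype=float)
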