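"""End-to-end estimator: binary expression in, subtype labels out.

:class:`PAVdClustering` follows the scikit-learn clusterer contract so the
whole pipeline — network assembly, candidate enumeration, leave-one-out
BDeu scoring, PAVd distances, complete-linkage clustering — composes with
sklearn model selection and metrics.  Note the method has no out-of-sample
notion: every sample's activity distribution is computed against the rest
of the cohort, so only ``fit`` / ``fit_predict`` are offered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .activity import compute_activity_matrix, distance_matrix
from .bdeu import ScoreConfig
from .cohort import cluster_samples
from .io import BinaryExpressionMatrix, GeneSet, InteractionCatalog
from .networks import build_families

__all__ = ["PAVdClustering"]


class PAVdClustering(ClusterMixin, BaseEstimator):
    """Cluster a binary expression cohort by pathway activity distance.

    Parameters
    ----------
    gene_sets : list of GeneSet
        Pathways to score (e.g. from :func:`pavd.io.read_gmt`).
    interactions : InteractionCatalog
        Genetic interactions connecting the pathway genes.
    n_clusters : int
        Number of groups to cut the complete-linkage dendrogram into.
    ess : float
        BDeu equivalent sample size.
    min_edges : int
        Pathways whose assembled network has fewer edges are dropped.

    Attributes
    ----------
    families_ : list of CandidateNetworkFamily
    activity_matrix_ : ActivityMatrix
        The A x S matrix R of per-sample activity distributions.
    distance_matrix_ : SampleDistanceMatrix
        Pairwise PAVd distances.
    assignment_ : ClusterAssignment
    labels_ : ndarray of shape (n_samples,)
        Cluster label per sample, in cohort order.
    """

    def __init__(self, gene_sets=None, interactions=None, n_clusters: int = 2,
                 ess: float = 1.0, min_edges: int = 1) -> None:
        self.gene_sets = gene_sets
        self.interactions = interactions
        self.n_clusters = n_clusters
        self.ess = ess
        self.min_edges = min_edges

    @staticmethod
    def _coerce(X) -> BinaryExpressionMatrix:
        if isinstance(X, BinaryExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):  # sklearn orientation: samples x genes
            return BinaryExpressionMatrix(
                list(X.columns), list(X.index), X.to_numpy().T
            )
        raise TypeError(
            "X must be a BinaryExpressionMatrix or a samples x genes DataFrame "
            "with gene-symbol columns"
        )

    def fit(self, X, y=None) -> "PAVdClustering":
        if self.gene_sets is None or self.interactions is None:
            raise ValueError("gene_sets and interactions are required")
        data = self._coerce(X)
        config = ScoreConfig(ess=self.ess)
        self.families_ = build_families(
            list(self.gene_sets), self.interactions, data, min_edges=self.min_edges
        )
        if not self.families_:
            raise ValueError("no usable pathways after assembly")
        self.activity_matrix_ = compute_activity_matrix(self.families_, data, config)
        self.distance_matrix_ = distance_matrix(self.activity_matrix_)
        self.assignment_ = cluster_samples(self.distance_matrix_, self.n_clusters)
        self.labels_ = self.assignment_.labels_array()
        self.sample_ids_ = list(data.sample_ids)
        return self
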