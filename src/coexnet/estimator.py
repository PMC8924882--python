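"""Scikit-learn-style front end for the module-detection pipeline.

``CoexpressionModuleDetector`` is a clustering estimator: rows of X are
transcript expression profiles, columns are samples, and ``fit`` assigns
every transcript a co-expression module label by running the full
pipeline — correlation-distance edges at a threshold, Kruskal minimum
spanning forest, Louvain communities on the forest.  It composes with
sklearn model selection and pipelines; ``detect_modules`` is the thin
functional wrapper used by the command line, carrying transcript IDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .community import (
    ModulePartition,
    SpanningForest,
    assign_all_transcripts,
    kruskal_msf,
    louvain,
)
from .graph import WeightedEdgeList, build_edges
from .io import ExpressionMatrix

__all__ = ["CoexpressionModuleDetector", "PipelineResult", "detect_modules"]

_WEIGHTINGS = ("similarity", "unweighted")


class CoexpressionModuleDetector(ClusterMixin, BaseEstimator):
    """Cluster transcripts into co-expression modules.

    Parameters
    ----------
    threshold : float, default=0.1
        Correlation-distance cutoff; transcript pairs with
        ``1 - |pearson corr| <= threshold`` (inclusive) become edges.
        The default matches the cutoff established for multi-tissue
        TPM panels.
    weighting : {"similarity", "unweighted"}, default="similarity"
        Edge weights handed to Louvain: similarity ``1 - distance``
        (= |corr|), or 1 for every forest edge.  Modularity semantics
        require affinity weights, hence the default; the unweighted mode
        exists for sensitivity analysis.
    resolution : float, default=1.0
        Modularity resolution parameter.
    block_size : int, default=2048
        Rows per block in the pairwise-correlation sweep; bounds peak
        memory at O(block_size * n_transcripts).
    log_transform : bool, default=False
        Apply log2(x + 1) to the expression values before correlation.
    random_state : int, default=1
        Seed for the Louvain node-visit order.  Identical seeds give
        identical partitions.

    Attributes
    ----------
    labels_ : ndarray of shape (n_transcripts,)
        Dense module IDs, one per row of X (zero-variance rows become
        singleton modules).
    modularity_ : float
        Final modularity of the Louvain partition on the spanning forest.
    n_modules_ : int
        Number of distinct modules.
    edges_ : WeightedEdgeList
        The thresholded co-expression edge list.
    forest_ : SpanningForest
        The Kruskal minimum spanning forest.
    excluded_ : ndarray
        Indices of zero-variance transcripts excluded from the graph.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> base = rng.lognormal(size=(2, 12))
    >>> X = np.repeat(base, 5, axis=0) * rng.lognormal(0, 0.05, (10, 12))
    >>> det = CoexpressionModuleDetector(threshold=0.1).fit(X)
    >>> det.n_modules_
    2
    """

    def __init__(
        self,
        threshold: float = 0.1,
        weighting: str = "similarity",
        resolution: float = 1.0,
        block_size: int = 2048,
        log_transform: bool = False,
        random_state: int = 1,
    ):
        self.threshold = threshold
        self.weighting = weighting
        self.resolution = resolution
        self.block_size = block_size
        self.log_transform = log_transform
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the pipeline on a transcripts x samples matrix."""
        X = validate_data(self, X, ensure_min_samples=2, ensure_min_features=3)
        if self.weighting not in _WEIGHTINGS:
            raise ValueError(
                f"weighting must be one of {_WEIGHTINGS}, got {self.weighting!r}"
            )
        if np.any(X < 0) or not np.all(np.isfinite(X)):
            raise ValueError("expression values must be finite and non-negative")
        vals = np.log2(X + 1.0) if self.log_transform else X
        seed = int(self.random_state) if self.random_state is not None else 1
        self.edges_ = build_edges(vals, self.threshold, self.block_size)
        self.forest_ = kruskal_msf(self.edges_)
        if self.weighting == "similarity":
            w = 1.0 - self.forest_.weight
        else:
            w = np.ones_like(self.forest_.weight)
        result = louvain(
            self.edges_.n_vertices,
            self.forest_.u,
            self.forest_.v,
            w,
            seed=seed,
            resolution=self.resolution,
        )
        partition = assign_all_transcripts(
            result.labels,
            self.edges_.excluded,
            [str(i) for i in range(self.edges_.n_vertices)],
            modularity=result.modularity,
            seed=seed,
            weighting_mode=self.weighting,
        )
        self.labels_ = partition.labels.copy()
        self.modularity_ = float(result.modularity)
        self.n_modules_ = partition.n_modules
        self.excluded_ = self.edges_.excluded.copy()
        self.converged_ = result.converged
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.positive_only = True
        return tags

    @property
    def n_excluded_(self) -> int:
        check_is_fitted(self)
        return int(len(self.excluded_))


@dataclass
class PipelineResult:
    """Everything one pipeline run produces, keyed by transcript IDs."""

    edges: WeightedEdgeList
    forest: SpanningForest
    partition: ModulePartition


def detect_modules(
    matrix: ExpressionMatrix,
    *,
    threshold: float = 0.1,
    weighting: str = "similarity",
    resolution: float = 1.0,
    block_size: int = 2048,
    log_transform: bool = False,
    seed: int = 1,
) -> PipelineResult:
    """Run edge construction, Kruskal MSF and Louvain on a matrix.

    Unlike the array-facing estimator, this keeps transcript IDs attached
    and uses them for the deterministic Kruskal tie-break, so results are
    reproducible across platforms regardless of row order conventions.
    """
    if weighting not in _WEIGHTINGS:
        raise ValueError(f"weighting must be one of {_WEIGHTINGS}, got {weighting!r}")
    vals = np.log2(matrix.values + 1.0) if log_transform else matrix.values
    edges = build_edges(vals, threshold, block_size)
    forest = kruskal_msf(edges, matrix.transcript_ids)
    w = 1.0 - forest.weight if weighting == "similarity" else np.ones_like(forest.weight)
    result = louvain(
        edges.n_vertices, forest.u, forest.v, w, seed=seed, resolution=resolution
    )
    partition = assign_all_transcripts(
        result.labels,
        edges.excluded,
        matrix.transcript_ids,
        modularity=result.modularity,
        seed=seed,
        weighting_mode=weighting,
    )
    return PipelineResult(edges, forest, partition)
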