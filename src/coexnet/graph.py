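"""Correlation-distance computation and thresholded edge construction.

The co-expression measure between two transcript profiles p and q is

    d(p, q) = 1 - |corr(p, q)|

with corr the Pearson coefficient.  d is 0 for perfectly correlated *or*
perfectly anti-correlated profiles and 1 for uncorrelated ones; a pair is
connected in the co-expression graph when d <= threshold (inclusive, by
convention; the boundary is measure-zero in practice).

All pairwise correlations are computed as inner products of standardized
profiles (mean 0, unit Euclidean norm), in row blocks so the full n x n
correlation matrix is never materialized.  Constant (zero-variance)
profiles have undefined correlation; the corresponding vertices are
excluded from the graph and reported, never silently given a distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightedEdgeList",
    "standardize_profiles",
    "pearson_distance",
    "build_edges",
    "write_edges_tsv",
]


@dataclass
class WeightedEdgeList:
    """Thresholded co-expression edges over vertex indices 0..n_vertices-1.

    Edges are stored with u < v, no duplicates; every edge satisfies
    ``distance == 1 - |corr|`` (to round-off) and ``distance <= threshold``.
    ``excluded`` holds indices of zero-variance vertices, which are
    incident to no edge.
    """

    n_vertices: int
    u: np.ndarray
    v: np.ndarray
    corr: np.ndarray
    distance: np.ndarray
    threshold: float
    excluded: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    @property
    def n_edges(self) -> int:
        return len(self.u)


def standardize_profiles(values: np.ndarray):
    """Center and norm-scale each row; mask zero-variance rows.

    Returns ``(Z, zero_variance_mask)`` where each unmasked row of Z has
    mean 0 and unit Euclidean norm, so ``Z[i] @ Z[j]`` is the Pearson
    correlation of rows i and j to within 1e-12.  Masked rows are set to
    zero.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix of profiles")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    # relative tolerance: a row is constant if its deviations are at
    # round-off level for its magnitude
    scale = np.abs(X).max(axis=1, initial=0.0) + 1.0
    zero_var = norms <= 1e-12 * scale
    safe = np.where(zero_var, 1.0, norms)
    Z = centered / safe[:, None]
    Z[zero_var] = 0.0
    return Z, zero_var


def pearson_distance(x, y) -> tuple[float, float]:
    """Correlation distance and Pearson correlation of two profiles.

    Returns ``(distance, corr)`` with ``distance = 1 - |corr|``.  If
    either profile has zero variance the correlation is undefined and
    ``(nan, nan)`` is returned; callers must exclude such vertices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("profiles must have at least 3 components")
    Z, zero_var = standardize_profiles(np.vstack([x, y]))
    if zero_var.any():
        return float("nan"), float("nan")
    corr = float(np.clip(Z[0] @ Z[1], -1.0, 1.0))
    return 1.0 - abs(corr), corr


def build_edges(
    values: np.ndarray, threshold: float, block_size: int = 2048
) -> WeightedEdgeList:
    """All transcript pairs with correlation distance <= threshold.

    Works in row blocks of ``block_size`` standardized profiles against
    the full standardized matrix, so peak working memory is
    O(block_size * n) rather than O(n^2).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    X = np.asarray(values, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("at least 2 transcripts are required")
    if m < 3:
        raise ValueError("at least 3 samples are required")
    Z, zero_var = standardize_profiles(X)
    if zero_var.all():
        raise ValueError("no usable vertices: every profile has zero variance")

    us, vs, cs = [], [], []
    min_abs_corr = 1.0 - threshold
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = Z[start:stop] @ Z.T  # (b, n)
        absb = np.clip(np.abs(block), 0.0, 1.0)
        rows, cols = np.nonzero(absb >= min_abs_corr)
        # upper triangle only (u < v); zero-variance vertices carry no edges
        keep = (cols > rows + start) & ~zero_var[cols] & ~zero_var[rows + start]
        rows, cols = rows[keep], cols[keep]
        if rows.size:
            us.append(rows + start)
            vs.append(cols)
            cs.append(np.clip(block[rows, cols], -1.0, 1.0))
    if us:
        u = np.concatenate(us).astype(np.intp)
        v = np.concatenate(vs).astype(np.intp)
        corr = np.concatenate(cs)
    else:
        u = np.empty(0, dtype=np.intp)
        v = np.empty(0, dtype=np.intp)
        corr = np.empty(0, dtype=float)
    distance = 1.0 - np.abs(corr)
    return WeightedEdgeList(
        n_vertices=n,
        u=u,
        v=v,
        corr=corr,
        distance=distance,
        threshold=float(threshold),
        excluded=np.flatnonzero(zero_var).astype(np.intp),
    )


def write_edges_tsv(edges: WeightedEdgeList, transcript_ids, path) -> None:
    """Write the edge list as ``u_id v_id corr distance``.

    Rows are sorted by (distance, u_id, v_id) ascending.
    """
    ids = np.asarray(transcript_ids, dtype=object)
    uid = ids[edges.u]
    vid = ids[edges.v]
    order = np.lexsort((vid, uid, edges.distance))
    with open(path, "w") as fh:
        fh.write("u_id\tv_id\tcorr\tdistance\n")
        for k in order:
            fh.write(
                f"{uid[k]}\t{vid[k]}\t{edges.corr[k]:.10g}\t{edges.distance[k]:.10g}\n"
            )
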