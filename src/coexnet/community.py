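"""Minimum spanning forest reduction and Louvain module assignment.

The thresholded co-expression graph is reduced with Kruskal's algorithm
(chosen because vertices far outnumber edges once a tight distance
threshold is applied) to a minimum spanning forest — one minimum spanning
tree per connected component.  The Louvain method is then run on the
forest to give every transcript a module (community) ID.

Everything here is deterministic: Kruskal ties are broken lexicographically
on (weight, u_id, v_id), and the Louvain node-visit order is drawn from a
caller-supplied seed, so identical seeds give identical partitions on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpanningForest",
    "ModulePartition",
    "LouvainResult",
    "kruskal_msf",
    "louvain",
    "modularity",
    "assign_all_transcripts",
    "write_forest_tsv",
    "write_partition_tsv",
    "load_partition_tsv",
]


class _UnionFind:
    """Union-find with path halving and union by rank (near-linear)."""

    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        parent = self.parent
        while parent[x] != x:
            parent[x] = parent[parent[x]]  # path halving
            x = parent[x]
        return x

    def union(self, x: int, y: int) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        if self.rank[rx] < self.rank[ry]:
            rx, ry = ry, rx
        self.parent[ry] = rx
        if self.rank[rx] == self.rank[ry]:
            self.rank[rx] += 1
        return True


@dataclass
class SpanningForest:
    """Acyclic minimum-weight subgraph: one spanning tree per component.

    ``component_ids`` labels every vertex (0..n_vertices-1) with a dense
    component index; isolated vertices are their own components.
    """

    n_vertices: int
    u: np.ndarray
    v: np.ndarray
    weight: np.ndarray
    component_ids: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.u)

    @property
    def n_components(self) -> int:
        return int(self.component_ids.max()) + 1 if self.n_vertices else 0

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())


@dataclass
class ModulePartition:
    """Total transcript -> module assignment with run provenance.

    Module IDs are dense integers 0..n_modules-1, numbered by first
    appearance in transcript order.  Every transcript of the input matrix
    — including excluded zero-variance ones — has exactly one module ID.
    """

    transcript_ids: list[str]
    labels: np.ndarray
    modularity: float
    seed: int
    weighting_mode: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.intp)
        if len(self.labels) != len(self.transcript_ids):
            raise ValueError("labels and transcript_ids lengths differ")

    @property
    def n_modules(self) -> int:
        return int(len(np.unique(self.labels)))

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.transcript_ids, (int(x) for x in self.labels)))

    def members(self, module_id: int) -> list[str]:
        return [
            t for t, lab in zip(self.transcript_ids, self.labels) if lab == module_id
        ]

    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules)

    @property
    def n_multi_member_modules(self) -> int:
        return int((self.module_sizes() >= 2).sum())


def kruskal_msf(edges, transcript_ids=None) -> SpanningForest:
    """Kruskal minimum spanning forest of a weighted edge list.

    ``edges`` is a :class:`~coexnet.graph.WeightedEdgeList` (distance is
    the weight).  Ties are broken by (weight, u_id, v_id) lexicographic
    order so the forest is deterministic even with equal weights.
    """
    n = edges.n_vertices
    if transcript_ids is None:
        width = len(str(max(n - 1, 0)))
        transcript_ids = [f"{i:0{width}d}" for i in range(n)]
    ids = np.asarray(transcript_ids, dtype=str)
    if len(ids) != n:
        raise ValueError("transcript_ids length does not match n_vertices")
    order = np.lexsort((ids[edges.v], ids[edges.u], edges.distance))
    uf = _UnionFind(n)
    keep = []
    for k in order:
        if uf.union(int(edges.u[k]), int(edges.v[k])):
            keep.append(k)
    keep = np.asarray(keep, dtype=np.intp)
    roots = np.fromiter((uf.find(i) for i in range(n)), dtype=np.intp, count=n)
    # dense component labels by first appearance
    _, component_ids = np.unique(roots, return_inverse=True)
    first_seen: dict[int, int] = {}
    dense = np.empty(n, dtype=np.intp)
    for i, r in enumerate(roots):
        if r not in first_seen:
            first_seen[r] = len(first_seen)
        dense[i] = first_seen[r]
    return SpanningForest(
        n_vertices=n,
        u=edges.u[keep].copy(),
        v=edges.v[keep].copy(),
        weight=edges.distance[keep].copy(),
        component_ids=dense,
    )


def modularity(n_vertices, u, v, w, labels, resolution: float = 1.0) -> float:
    """Newman–Girvan weighted modularity of a vertex partition.

    Q = sum_c [ W_in(c)/W - resolution * (S_c / 2W)^2 ] with W the total
    edge weight, W_in(c) the weight inside community c and S_c the sum of
    vertex strengths.  An edgeless graph has Q = 0 by convention.
    """
    labels = np.asarray(labels)
    if len(labels) != n_vertices:
        raise ValueError("every vertex must be assigned a community")
    u = np.asarray(u, dtype=np.intp)
    v = np.asarray(v, dtype=np.intp)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative edge weight")
    W = float(w.sum())
    if W == 0.0:
        return 0.0
    _, dense = np.unique(labels, return_inverse=True)
    ncomm = dense.max() + 1
    internal = np.bincount(
        dense[u], weights=np.where(dense[u] == dense[v], w, 0.0), minlength=ncomm
    )
    strength = np.zeros(n_vertices)
    np.add.at(strength, u, w)
    np.add.at(strength, v, w)
    S = np.bincount(dense, weights=strength, minlength=ncomm)
    return float((internal / W).sum() - resolution * ((S / (2.0 * W)) ** 2).sum())


@dataclass
class LouvainResult:
    labels: np.ndarray
    modularity: float
    n_levels: int
    converged: bool  # terminated because no single move had positive gain


def _louvain_level(n, adj, k, W, rng, resolution):
    """One Louvain level: greedy single-node moves until no positive gain.

    Returns (community labels, whether any node moved).  Candidate
    communities are scanned in sorted order and moves require strictly
    positive gain, so ties resolve to the smallest community label.
    """
    comm = np.arange(n)
    Stot = k.copy()
    moved_any = False
    while True:
        moved = False
        for i in rng.permutation(n):
            ci = int(comm[i])
            wlinks: dict[int, float] = {}
            for j, wij in adj[i]:
                cj = int(comm[j])
                wlinks[cj] = wlinks.get(cj, 0.0) + wij
            Stot[ci] -= k[i]
            best_c = ci
            best_gain = wlinks.get(ci, 0.0) - resolution * k[i] * Stot[ci] / (2.0 * W)
            for c in sorted(wlinks):
                if c == ci:
                    continue
                gain = wlinks[c] - resolution * k[i] * Stot[c] / (2.0 * W)
                if gain > best_gain + 1e-15:
                    best_gain, best_c = gain, c
            comm[i] = best_c
            Stot[best_c] += k[i]
            if best_c != ci:
                moved = moved_any = True
        if not moved:
            return comm, moved_any


def louvain(
    n_vertices,
    u,
    v,
    w,
    *,
    seed: int = 1,
    resolution: float = 1.0,
    tol: float = 1e-7,
    max_levels: int = 100,
) -> LouvainResult:
    """Classic two-phase Louvain community detection.

    Phase 1 repeats greedy single-node moves (visit order shuffled by
    ``seed``) until no move has positive modularity gain; phase 2
    aggregates communities into a super-graph; the two phases repeat
    until the modularity gain of a full level drops below ``tol``.
    Isolated vertices stay singleton communities.  Identical seeds give
    identical partitions.
    """
    u = np.asarray(u, dtype=np.intp)
    v = np.asarray(v, dtype=np.intp)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative edge weight")
    if np.any(u == v):
        raise ValueError("self-loops are not allowed in the input graph")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rng = np.random.default_rng(seed)
    W = float(w.sum())
    if W == 0.0:
        return LouvainResult(np.arange(n_vertices, dtype=np.intp), 0.0, 0, True)

    # current aggregated graph; loops[i] = internal weight of super-node i
    cur_n = n_vertices
    cur_edges: dict[tuple[int, int], float] = {}
    for a, b, wt in zip(u, v, w):
        key = (int(a), int(b)) if a < b else (int(b), int(a))
        cur_edges[key] = cur_edges.get(key, 0.0) + float(wt)
    cur_loops = np.zeros(cur_n)
    node_map = np.arange(n_vertices, dtype=np.intp)  # original -> current node

    q_prev = modularity(n_vertices, u, v, w, node_map, resolution)
    converged = False
    levels = 0
    for _ in range(max_levels):
        adj = [[] for _ in range(cur_n)]
        k = 2.0 * cur_loops.copy()
        for (a, b), wt in cur_edges.items():
            adj[a].append((b, wt))
            adj[b].append((a, wt))
            k[a] += wt
            k[b] += wt
        comm, moved = _louvain_level(cur_n, adj, k, W, rng, resolution)
        levels += 1
        if not moved:
            converged = True
            break
        _, dense = np.unique(comm, return_inverse=True)
        node_map = dense[node_map]
        q_new = modularity(n_vertices, u, v, w, node_map, resolution)
        # aggregate
        new_n = int(dense.max()) + 1
        new_loops = np.zeros(new_n)
        for i in range(cur_n):
            new_loops[dense[i]] += cur_loops[i]
        new_edges: dict[tuple[int, int], float] = {}
        for (a, b), wt in cur_edges.items():
            ca, cb = int(dense[a]), int(dense[b])
            if ca == cb:
                new_loops[ca] += wt
            else:
                key = (ca, cb) if ca < cb else (cb, ca)
                new_edges[key] = new_edges.get(key, 0.0) + wt
        cur_n, cur_edges, cur_loops = new_n, new_edges, new_loops
        if q_new - q_prev < tol:
            q_prev = max(q_prev, q_new)
            break
        q_prev = q_new

    q_final = modularity(n_vertices, u, v, w, node_map, resolution)
    return LouvainResult(node_map.copy(), q_final, levels, converged)


def assign_all_transcripts(
    labels,
    excluded,
    transcript_ids,
    *,
    modularity: float,
    seed: int,
    weighting_mode: str,
) -> ModulePartition:
    """Extend a graph-vertex partition to a total transcript partition.

    Excluded (zero-variance) transcripts become singleton modules; module
    IDs are re-densified by first appearance in transcript order.
    ``labels`` may cover all transcripts (excluded positions overwritten
    with fresh singletons) or only the non-excluded ones in index order.
    """
    n = len(transcript_ids)
    excluded = np.asarray(sorted(int(e) for e in np.asarray(excluded, dtype=np.intp)))
    labels = np.asarray(labels, dtype=np.intp)
    full = np.empty(n, dtype=np.intp)
    if len(labels) == n:
        full[:] = labels
    elif len(labels) == n - len(excluded):
        mask = np.ones(n, dtype=bool)
        mask[excluded] = False
        full[mask] = labels
    else:
        raise ValueError(
            f"labels length {len(labels)} matches neither all {n} transcripts "
            f"nor the {n - len(excluded)} non-excluded ones"
        )
    # fresh singleton IDs for excluded transcripts
    next_id = int(full.max(initial=-1)) + 1 if n else 0
    for e in excluded:
        full[e] = next_id
        next_id += 1
    # densify by first appearance
    remap: dict[int, int] = {}
    dense = np.empty(n, dtype=np.intp)
    for i, lab in enumerate(full):
        lab = int(lab)
        if lab not in remap:
            remap[lab] = len(remap)
        dense[i] = remap[lab]
    return ModulePartition(
        list(transcript_ids), dense, float(modularity), int(seed), weighting_mode
    )


def write_forest_tsv(forest: SpanningForest, transcript_ids, path) -> None:
    ids = np.asarray(transcript_ids, dtype=object)
    order = np.lexsort((ids[forest.v], ids[forest.u], forest.weight))
    with open(path, "w") as fh:
        fh.write("u_id\tv_id\tdistance\tcomponent\n")
        for k in order:
            fh.write(
                f"{ids[forest.u[k]]}\t{ids[forest.v[k]]}\t{forest.weight[k]:.10g}"
                f"\t{forest.component_ids[forest.u[k]]}\n"
            )


def write_partition_tsv(partition: ModulePartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tmodule_id\n")
        for tid, lab in zip(partition.transcript_ids, partition.labels):
            fh.write(f"{tid}\t{int(lab)}\n")


def load_partition_tsv(path, *, seed: int = -1, weighting_mode: str = "unknown"):
    """Read a ``transcript_id<TAB>module_id`` table back as a partition."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "module_id": int})
    if not {"transcript_id", "module_id"}.issubset(df.columns):
        raise ValueError("partition file must have transcript_id and module_id columns")
    return ModulePartition(
        [str(t) for t in df["transcript_id"]],
        df["module_id"].to_numpy(),
        float("nan"),
        seed,
        weighting_mode,
    )
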