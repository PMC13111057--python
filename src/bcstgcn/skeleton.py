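"""Pig skeleton topology and partitioned, normalized graph construction.

The skeleton is a fixed 17-keypoint lateral-view scheme connected by 16
anatomical edges (a spanning tree).  Spatial graph convolutions consume one
adjacency matrix per neighborhood partition (ST-GCN style), each symmetrically
normalized by inverse square-root degree.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Keypoint names in scheme order (index 0 = keypoint 1).
KEYPOINT_NAMES = (
    "Nose",
    "Between the ears",
    "Neck base",
    "Shoulder midpoint",
    "Left forelimb base",
    "Left front knee",
    "Left front hoof",
    "Right forelimb base",
    "Right front knee",
    "Right front hoof",
    "Right hindlimb base",
    "Right hind knee",
    "Right hind hoof",
    "Left hindlimb base",
    "Left hind knee",
    "Left hind hoof",
    "Tail root",
)

#: The 16 skeleton edges as 1-based keypoint index pairs: head-neck chain,
#: two forelimb chains, the trunk axis, and two hindlimb chains.
SKELETON_EDGES = (
    (1, 2), (2, 3), (3, 4),
    (4, 5), (5, 6), (6, 7),
    (4, 8), (8, 9), (9, 10),
    (4, 17),
    (17, 11), (11, 12), (12, 13),
    (17, 14), (14, 15), (15, 16),
)

_REGIONS = {
    1: "head", 2: "head", 3: "head",
    4: "trunk", 17: "tail",
    5: "forelimb-L", 6: "forelimb-L", 7: "forelimb-L",
    8: "forelimb-R", 9: "forelimb-R", 10: "forelimb-R",
    11: "hindlimb-R", 12: "hindlimb-R", 13: "hindlimb-R",
    14: "hindlimb-L", 15: "hindlimb-L", 16: "hindlimb-L",
}

PARTITION_STRATEGIES = ("uniform", "distance", "spatial-configuration")

#: Trunk joints defining the gravity center for the spatial-configuration
#: partition (shoulder midpoint and tail root span the trunk axis).
DEFAULT_CENTER_JOINTS = (4, 17)

DEGREE_EPS = 1e-6


@dataclass(frozen=True)
class KeypointScheme:
    """Named keypoints, skeleton edges (1-based pairs) and region tags."""

    names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    regions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        if len(set(self.names)) != n:
            raise ValueError("keypoint names must be unique")
        for i, j in self.edges:
            if not (1 <= i <= n and 1 <= j <= n):
                raise ValueError(f"edge ({i},{j}) out of range 1..{n}")
            if i == j:
                raise ValueError("self-loop edges are not allowed")

    @property
    def n_joints(self) -> int:
        return len(self.names)

    def adjacency(self) -> np.ndarray:
        """Binary V x V adjacency matrix (no self loops)."""
        V = self.n_joints
        A = np.zeros((V, V))
        for i, j in self.edges:
            A[i - 1, j - 1] = 1.0
            A[j - 1, i - 1] = 1.0
        return A

    def is_tree(self) -> bool:
        """True iff the edge set forms a connected acyclic graph."""
        V = self.n_joints
        if len(self.edges) != V - 1:
            return False
        A = self.adjacency()
        seen = {0}
        queue = deque([0])
        while queue:
            u = queue.popleft()
            for v in np.flatnonzero(A[u]):
                if v not in seen:
                    seen.add(int(v))
                    queue.append(int(v))
        return len(seen) == V


@dataclass(frozen=True)
class AdjacencySet:
    """Partitioned adjacency matrices A_k and their normalizations.

    ``A`` stacks the K_v binary partition matrices (K, V, V); ``A_norm`` holds
    the symmetric normalizations D^{-1/2} A_k D^{-1/2}.
    """

    A: np.ndarray
    A_norm: np.ndarray
    strategy: str
    degree_eps: float = DEGREE_EPS

    @property
    def K(self) -> int:
        return self.A.shape[0]

    @property
    def V(self) -> int:
        return self.A.shape[1]


@dataclass(frozen=True)
class SpatioTemporalGraph:
    """Skeleton graph unrolled over T frames with temporal reach k_max."""

    scheme: KeypointScheme
    T: int
    k_max: int = 1


def build_pig_scheme() -> KeypointScheme:
    """Return the fixed 17-keypoint / 16-edge lateral-view pig scheme."""
    return KeypointScheme(names=KEYPOINT_NAMES, edges=SKELETON_EDGES,
                          regions=dict(_REGIONS))


def normalize_adjacency(A: np.ndarray, eps: float = DEGREE_EPS) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2}.

    Rows/columns with zero degree map to zero (``eps`` guards the inversion so
    fully occluded, isolated joints do not produce NaNs).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    deg = A.sum(axis=1)
    dinv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, eps)), 0.0)
    return dinv[:, None] * A * dinv[None, :]


def _hop_distances(A: np.ndarray, sources: list[int]) -> np.ndarray:
    """BFS hop distance from each node to the nearest source node."""
    V = A.shape[0]
    dist = np.full(V, np.inf)
    queue = deque()
    for s in sources:
        dist[s] = 0
        queue.append(s)
    while queue:
        u = queue.popleft()
        for v in np.flatnonzero(A[u]):
            if dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(int(v))
    return dist


def build_adjacency(
    scheme: KeypointScheme,
    strategy: str = "spatial-configuration",
    center_joints: tuple[int, ...] = DEFAULT_CENTER_JOINTS,
    eps: float = DEGREE_EPS,
) -> AdjacencySet:
    """Partition the 1-neighborhood of every joint into K_v adjacency matrices.

    Strategies (ST-GCN conventions adapted to the quadruped skeleton):

    - ``uniform``: K_v = 1, a single matrix A + I.
    - ``distance``: K_v = 2, the root (identity) and the 1-hop neighbors.
    - ``spatial-configuration``: K_v = 3, splitting neighbors into root,
      centripetal (closer to the trunk center) and centrifugal (farther).
      Closeness is hop distance in the skeleton tree to the nearest of
      ``center_joints``.

    In every case the partitions tile the neighbor set:
    sum_k A_k = adjacency + identity.
    """
    if strategy not in PARTITION_STRATEGIES:
        raise ValueError(
            f"unknown partition strategy {strategy!r}; "
            f"expected one of {PARTITION_STRATEGIES}")
    V = scheme.n_joints
    A_full = scheme.adjacency()
    I = np.eye(V)

    if strategy == "uniform":
        parts = [A_full + I]
    elif strategy == "distance":
        parts = [I, A_full]
    else:
        if not center_joints:
            raise ValueError("spatial-configuration requires center_joints")
        for c in center_joints:
            if not (1 <= c <= V):
                raise ValueError(f"center joint {c} out of range 1..{V}")
        dist = _hop_distances(A_full, [c - 1 for c in center_joints])
        root = I.copy()
        centripetal = np.zeros((V, V))
        centrifugal = np.zeros((V, V))
        for k in range(V):
            for l in np.flatnonzero(A_full[k]):
                if dist[l] < dist[k]:
                    centripetal[k, l] = 1.0
                elif dist[l] > dist[k]:
                    centrifugal[k, l] = 1.0
                else:
                    root[k, l] = 1.0
        parts = [root, centripetal, centrifugal]

    A = np.stack(parts)
    A_norm = np.stack([normalize_adjacency(p, eps) for p in parts])
    return AdjacencySet(A=A, A_norm=A_norm, strategy=strategy, degree_eps=eps)


def temporal_edges(graph: SpatioTemporalGraph) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Temporal edges ((joint, t), (joint, t+k)) for k = 1..k_max.

    Each joint is linked to the same joint k frames later; for T < 2 the list
    is empty.  The count is V * sum_{k=1..k_max} (T - k).
    """
    V = graph.scheme.n_joints
    out = []
    for k in range(1, graph.k_max + 1):
        for t in range(graph.T - k):
            for v in range(V):
                out.append(((v + 1, t), (v + 1, t + k)))
    return out


def scheme_to_yaml(scheme: KeypointScheme, path) -> None:
    """Write a scheme as a plain-text YAML mapping (names, edges, regions)."""
    payload = {
        "names": list(scheme.names),
        "edges": [list(e) for e in scheme.edges],
        "regions": {int(k): v for k, v in scheme.regions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def scheme_from_yaml(path) -> KeypointScheme:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return KeypointScheme(
        names=tuple(payload["names"]),
        edges=tuple(tuple(e) for e in payload["edges"]),
        regions={int(k): v for k, v in payload.get("regions", {}).items()},
    )


def edges_to_tsv(scheme: KeypointScheme, path) -> None:
    """Emit the edge list as a two-column TSV of 1-based indices."""
    with open(path, "w") as fh:
        for i, j in scheme.edges:
            fh.write(f"{i}\t{j}\n")
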