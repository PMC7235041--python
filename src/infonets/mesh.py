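"""Subdivided-icosahedron cortical surface meshes and their adjacency.

All surface maps in the pipeline live on a standard mesh built by linear
(edge-wise) subdivision of the base icosahedron: each of the 20 base faces
is divided into ``L**2`` sub-triangles and every vertex is projected onto
the unit sphere.  This scheme yields ``10 * L**2 + 2`` nodes per hemisphere,
so ``L = 32`` gives the standard 10,242-node hemisphere mesh and a
20,484-node whole-brain surface.

Node ordering is deterministic: the 12 base vertices first, then edge
interior points (edges in sorted order, points walking from the lower- to
the higher-indexed endpoint), then face interior points in barycentric
row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cs_connected_components

from .exceptions import InvalidParameterError

__all__ = [
    "SurfaceMesh",
    "WholeBrainSurface",
    "Neighborhood",
    "build_icosahedral_mesh",
    "build_whole_brain_surface",
    "node_neighborhood",
    "connected_components",
]

# Base icosahedron: golden-ratio vertex coordinates and the canonical 20 faces.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_BASE_VERTICES = np.array(
    [
        [-1.0, _PHI, 0.0],
        [1.0, _PHI, 0.0],
        [-1.0, -_PHI, 0.0],
        [1.0, -_PHI, 0.0],
        [0.0, -1.0, _PHI],
        [0.0, 1.0, _PHI],
        [0.0, -1.0, -_PHI],
        [0.0, 1.0, -_PHI],
        [_PHI, 0.0, -1.0],
        [_PHI, 0.0, 1.0],
        [-_PHI, 0.0, -1.0],
        [-_PHI, 0.0, 1.0],
    ]
)
_BASE_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class Neighborhood:
    """A k-ring searchlight patch around a center node."""

    center_node: int
    member_nodes: frozenset[int]
    rings: int

    def __post_init__(self) -> None:
        if self.center_node not in self.member_nodes:
            raise ValueError("center node must be a member of its neighborhood")


@dataclass
class SurfaceMesh:
    """A closed triangulated sphere mesh for one hemisphere.

    Parameters
    ----------
    hemisphere
        ``"left"`` or ``"right"``.
    node_coords
        ``(n_nodes, 3)`` unit-sphere positions (arbitrary units).
    faces
        ``(n_faces, 3)`` node-index triples.
    linear_divisions
        The subdivision factor ``L``; node count is ``10 * L**2 + 2``.
    """

    hemisphere: str
    node_coords: np.ndarray
    faces: np.ndarray
    linear_divisions: int
    _adjacency: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return int(self.node_coords.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an ``(n_edges, 2)`` sorted-index array."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean node adjacency (shared mesh edge)."""
        if self._adjacency is None:
            e = self.edges()
            n = self.n_nodes
            data = np.ones(2 * len(e), dtype=np.int8)
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            self._adjacency = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        return self._adjacency

    def k_ring_members(self, node: int, rings: int) -> np.ndarray:
        """Sorted node indices within ``rings`` edge hops of ``node``."""
        if not (0 <= node < self.n_nodes):
            raise IndexError(f"node {node} out of range for mesh with {self.n_nodes} nodes")
        if rings < 0:
            raise InvalidParameterError("rings must be non-negative")
        adj = self.adjacency
        indptr, indices = adj.indptr, adj.indices
        visited = {node}
        frontier = [node]
        for _ in range(rings):
            nxt = []
            for u in frontier:
                for v in indices[indptr[u]:indptr[u + 1]]:
                    if v not in visited:
                        visited.add(int(v))
                        nxt.append(int(v))
            if not nxt:
                break
            frontier = nxt
        return np.array(sorted(visited), dtype=np.int64)

    def all_neighborhoods(self, rings: int) -> list[np.ndarray]:
        """k-ring member arrays for every node (searchlight support)."""
        return [self.k_ring_members(i, rings) for i in range(self.n_nodes)]


def _subdivided_counts(L: int) -> int:
    return 10 * L * L + 2


def build_icosahedral_mesh(linear_divisions: int, hemisphere: str = "left") -> SurfaceMesh:
    """Build the standard subdivided-icosahedron sphere mesh.

    Each base face is linearly divided into ``L**2`` sub-triangles; shared
    vertices along base edges are deduplicated structurally (by their exact
    position on the base edge), so the construction is bitwise deterministic.
    """
    L = linear_divisions
    if not isinstance(L, (int, np.integer)) or L < 1:
        raise InvalidParameterError(f"linear_divisions must be a positive integer, got {L!r}")
    if hemisphere not in ("left", "right"):
        raise InvalidParameterError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    L = int(L)

    # Canonical ids: base vertices, then edge interiors, then face interiors.
    base_edges = {}
    e = np.concatenate(
        [_BASE_FACES[:, [0, 1]], _BASE_FACES[:, [1, 2]], _BASE_FACES[:, [2, 0]]]
    )
    e.sort(axis=1)
    for a, b in np.unique(e, axis=0):
        base_edges[(int(a), int(b))] = len(base_edges)

    n_edge_pts = L - 1
    n_face_pts = (L - 1) * (L - 2) // 2
    n_nodes = 12 + 30 * n_edge_pts + 20 * n_face_pts
    assert n_nodes == _subdivided_counts(L)

    coords = np.empty((n_nodes, 3), dtype=np.float64)
    coords[:12] = _BASE_VERTICES / np.linalg.norm(_BASE_VERTICES, axis=1, keepdims=True)

    def edge_point_id(a: int, b: int, t: int) -> int:
        # t in 1..L-1, measured from a toward b
        if a > b:
            a, b, t = b, a, L - t
        return 12 + base_edges[(a, b)] * n_edge_pts + (t - 1)

    # Interior points of face f at barycentric (i, j): i, j >= 1, i + j <= L - 1,
    # point = (corner0 * (L - i - j) + corner1 * i + corner2 * j) / L.
    def face_interior_base(f: int) -> int:
        return 12 + 30 * n_edge_pts + f * n_face_pts

    def face_point_offset(i: int, j: int) -> int:
        # row-major over i = 1..L-2, j = 1..L-1-i
        return (i - 1) * (L - 1) - (i - 1) * i // 2 + (j - 1)

    faces_out = np.empty((20 * L * L, 3), dtype=np.int64)
    n_out = 0
    edge_filled = np.zeros(30, dtype=bool)

    for f, (A, B, C) in enumerate(_BASE_FACES):
        A, B, C = int(A), int(B), int(C)
        pa, pb, pc = _BASE_VERTICES[A], _BASE_VERTICES[B], _BASE_VERTICES[C]
        # grid[i][j] for i + j <= L
        grid = np.empty((L + 1, L + 1), dtype=np.int64)
        for i in range(L + 1):
            for j in range(L + 1 - i):
                k = L - i - j
                if k == L:
                    nid = A
                elif i == L:
                    nid = B
                elif j == L:
                    nid = C
                elif j == 0:  # edge A-B, parameter i from A
                    nid = edge_point_id(A, B, i)
                elif i == 0:  # edge A-C, parameter j from A
                    nid = edge_point_id(A, C, j)
                elif k == 0:  # edge B-C, parameter j from B
                    nid = edge_point_id(B, C, j)
                else:
                    nid = face_interior_base(f) + face_point_offset(i, j)
                    p = (pa * k + pb * i + pc * j) / L
                    coords[nid] = p / np.linalg.norm(p)
                grid[i, j] = nid
        # fill edge-point coordinates once per edge (canonical direction)
        for (a, b), eidx in base_edges.items():
            if edge_filled[eidx]:
                continue
            if {a, b} <= {A, B, C}:
                va, vb = _BASE_VERTICES[a], _BASE_VERTICES[b]
                for t in range(1, L):
                    p = (va * (L - t) + vb * t) / L
                    coords[12 + eidx * n_edge_pts + (t - 1)] = p / np.linalg.norm(p)
                edge_filled[eidx] = True
        # sub-triangles
        for i in range(L):
            for j in range(L - i):
                faces_out[n_out] = (grid[i, j], grid[i + 1, j], grid[i, j + 1])
                n_out += 1
                if i + j < L - 1:
                    faces_out[n_out] = (grid[i + 1, j], grid[i + 1, j + 1], grid[i, j + 1])
                    n_out += 1
    assert n_out == 20 * L * L
    return SurfaceMesh(
        hemisphere=hemisphere,
        node_coords=coords,
        faces=faces_out,
        linear_divisions=L,
    )


@dataclass
class WholeBrainSurface:
    """Two hemisphere meshes with a global node index (left first)."""

    left: SurfaceMesh
    right: SurfaceMesh

    @property
    def node_index_offset(self) -> int:
        return self.left.n_nodes

    @property
    def n_nodes(self) -> int:
        return self.left.n_nodes + self.right.n_nodes

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Block-diagonal adjacency; no edges cross hemispheres."""
        return sparse.block_diag(
            (self.left.adjacency, self.right.adjacency), format="csr"
        )

    def hemisphere_of(self, node: int) -> str:
        return "left" if node < self.node_index_offset else "right"

    def k_ring_members(self, node: int, rings: int) -> np.ndarray:
        off = self.node_index_offset
        if node < off:
            return self.left.k_ring_members(node, rings)
        return self.right.k_ring_members(node - off, rings) + off

    def all_neighborhoods(self, rings: int) -> list[np.ndarray]:
        off = self.node_index_offset
        out = self.left.all_neighborhoods(rings)
        out.extend(nb + off for nb in self.right.all_neighborhoods(rings))
        return out


@lru_cache(maxsize=8)
def _cached_whole_brain(linear_divisions: int) -> WholeBrainSurface:
    return WholeBrainSurface(
        left=build_icosahedral_mesh(linear_divisions, "left"),
        right=build_icosahedral_mesh(linear_divisions, "right"),
    )


def build_whole_brain_surface(linear_divisions: int) -> WholeBrainSurface:
    """Left + right standard meshes; ``L = 32`` gives 20,484 nodes total."""
    return _cached_whole_brain(int(linear_divisions))


def node_neighborhood(mesh, node: int, rings: int) -> Neighborhood:
    """Breadth-first k-ring neighborhood over mesh edges.

    ``rings=0`` returns only the center node.  Works on a single hemisphere
    or a whole-brain surface.
    """
    members = mesh.k_ring_members(node, rings)
    return Neighborhood(
        center_node=int(node),
        member_nodes=frozenset(int(m) for m in members),
        rings=int(rings),
    )


def connected_components(node_set, mesh) -> list[set[int]]:
    """Partition ``node_set`` into maximal edge-connected components.

    Components are ordered by decreasing size, ties broken by the smallest
    member index.  An empty set yields an empty list.
    """
    nodes = np.array(sorted(set(int(n) for n in node_set)), dtype=np.int64)
    if len(nodes) == 0:
        return []
    adj = mesh.adjacency
    sub = adj[nodes][:, nodes]
    n_comp, labels = _cs_connected_components(sub, directed=False)
    comps = [set() for _ in range(n_comp)]
    for local, lab in enumerate(labels):
        comps[lab].add(int(nodes[local]))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps
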