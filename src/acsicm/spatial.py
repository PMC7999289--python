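"""Voxel grid, chequerboard partition, spatial clustering and model-order estimate.

Cortical locations live at arbitrary 3-D coordinates; for the Potts prior they
are binned into a regular axis-aligned voxel grid with 6-connectivity.  The
grid's two-colouring (chequerboard) makes same-colour voxels conditionally
independent under a first-order neighbourhood, so each colour can be relabelled
simultaneously.
"""
from __future__ import annotations

import dataclasses
import json
from typing import List, Tuple

import numpy as np
from scipy import sparse
from sklearn.cluster import KMeans

from .model import InputError, _check_one_hot


@dataclasses.dataclass(eq=False)
class VoxelGrid:
    """Regular 3-D voxel grid with a location->voxel map.

    Voxel indices are C-ordered over integer cells ``(ix, iy, iz)`` of shape
    ``dims``; ``v[j]`` is the voxel containing cortical location ``j``;
    ``edges`` lists each unordered 6-connected neighbour pair once (i < j);
    ``parity`` is the chequerboard colour ``(ix+iy+iz) mod 2``; ``counts[k]``
    is the number of cortical locations in voxel ``k``.
    """

    dims: Tuple[int, int, int]
    v: np.ndarray
    edges: np.ndarray
    parity: np.ndarray
    counts: np.ndarray

    _adj: sparse.csr_matrix = dataclasses.field(default=None, repr=False, compare=False)

    @property
    def N_v(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def P(self) -> int:
        return self.v.shape[0]

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 voxel adjacency (built lazily from the edge list)."""
        if self._adj is None:
            n = self.N_v
            if self.edges.size:
                i = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
                j = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
                data = np.ones(i.shape[0])
                self._adj = sparse.csr_matrix((data, (i, j)), shape=(n, n))
            else:
                self._adj = sparse.csr_matrix((n, n))
        return self._adj

    def voxel_coords(self) -> np.ndarray:
        """Integer (ix, iy, iz) cell coordinates of every voxel, N_v x 3."""
        idx = np.arange(self.N_v)
        return np.stack(np.unravel_index(idx, self.dims), axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "dims": list(self.dims),
                "v": self.v.tolist(),
                "edges": self.edges.tolist(),
                "parity": self.parity.tolist(),
                "counts": self.counts.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "VoxelGrid":
        d = json.loads(text)
        return cls(
            dims=tuple(d["dims"]),
            v=np.asarray(d["v"], dtype=np.int64),
            edges=np.asarray(d["edges"], dtype=np.int64).reshape(-1, 2),
            parity=np.asarray(d["parity"], dtype=np.int8),
            counts=np.asarray(d["counts"], dtype=np.int64),
        )


@dataclasses.dataclass
class ClusterMap:
    """Partition of the P cortical locations into J spatial clusters.

    Locations within a cluster are constrained to share one source time
    course, reducing the dimension of the source update.
    """

    J: int
    assignment: np.ndarray

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.assignment.ndim != 1:
            raise InputError("assignment must be a 1-D array over locations")
        if self.J < 1 or self.J > self.assignment.shape[0]:
            raise InputError("need 1 <= J <= P")
        used = np.unique(self.assignment)
        if used.min() < 0 or used.max() >= self.J or used.shape[0] != self.J:
            raise InputError("cluster ids must be 0..J-1 with every cluster non-empty")

    @property
    def members(self) -> List[np.ndarray]:
        order = np.argsort(self.assignment, kind="stable")
        bounds = np.searchsorted(self.assignment[order], np.arange(self.J + 1))
        return [order[bounds[c]:bounds[c + 1]] for c in range(self.J)]

    def to_json(self) -> str:
        return json.dumps({"J": self.J, "assignment": self.assignment.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ClusterMap":
        d = json.loads(text)
        return cls(J=int(d["J"]), assignment=np.asarray(d["assignment"], dtype=np.int64))


def singleton_clusters(P: int) -> ClusterMap:
    """The trivial J = P clustering (no dimension reduction)."""
    return ClusterMap(J=P, assignment=np.arange(P))


def build_grid(coords: np.ndarray, dims: Tuple[int, int, int]) -> VoxelGrid:
    """Bin P cortical locations into a regular ``dims`` voxel grid.

    The axis-aligned bounding box of ``coords`` is split into equal cells;
    cells are half-open ``[lo, hi)`` with the last cell closed, so boundary
    points fall in the lower cell except at the top face.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.size == 0:
        raise InputError("coords must be non-empty")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError("coords must be P x 3")
    if not np.all(np.isfinite(coords)):
        raise InputError("coords contain non-finite values")
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise InputError("dims must be three positive integers")

    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    width = hi - lo
    cell_idx = np.zeros_like(coords, dtype=np.int64)
    for ax in range(3):
        if width[ax] > 0:
            raw = np.floor((coords[:, ax] - lo[ax]) / (width[ax] / dims[ax]))
            cell_idx[:, ax] = np.clip(raw.astype(np.int64), 0, dims[ax] - 1)
    v = np.ravel_multi_index((cell_idx[:, 0], cell_idx[:, 1], cell_idx[:, 2]), dims)

    nx, ny, nz = dims
    ix, iy, iz = np.unravel_index(np.arange(nx * ny * nz), dims)
    parity = ((ix + iy + iz) % 2).astype(np.int8)

    edges = []
    for ax, n in enumerate(dims):
        if n < 2:
            continue
        keep = [ix, iy, iz][ax] < n - 1
        a = np.flatnonzero(keep)
        step = {0: ny * nz, 1: nz, 2: 1}[ax]
        edges.append(np.stack([a, a + step], axis=1))
    edges = np.concatenate(edges, axis=0) if edges else np.empty((0, 2), dtype=np.int64)

    counts = np.bincount(v, minlength=nx * ny * nz).astype(np.int64)
    return VoxelGrid(dims=dims, v=v, edges=edges, parity=parity, counts=counts)


def chequerboard_partition(grid: VoxelGrid) -> Tuple[np.ndarray, np.ndarray]:
    """Voxel indices of the two chequerboard colours (black = parity 0)."""
    black = np.flatnonzero(grid.parity == 0)
    white = np.flatnonzero(grid.parity == 1)
    return black, white


def _farthest_point_centers(coords: np.ndarray, J: int) -> np.ndarray:
    """Greedy farthest-point seeds; the first is the point farthest from the centroid.

    Purely geometric (no randomness), so the seeding is canonical: permuting
    the input rows yields the same set of centers.
    """
    centroid = coords.mean(axis=0)
    d = np.linalg.norm(coords - centroid, axis=1)
    chosen = [int(np.argmax(d))]
    dist = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    for _ in range(1, J):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(coords - coords[nxt], axis=1))
    return coords[chosen]


def cluster_locations(coords: np.ndarray, J: int, seed: int = 0) -> ClusterMap:
    """Lloyd-style K-means clustering of cortical locations into J spatial clusters.

    Initialization is deterministic (greedy farthest-point seeding), so the
    result is reproducible and equivariant under permutations of the input
    rows.  The ``seed`` is accepted for interface symmetry; the procedure
    itself draws no random numbers.
    """
    coords = np.asarray(coords, dtype=np.float64)
    P = coords.shape[0]
    if J < 1 or J > P:
        raise InputError(f"need 1 <= J <= P, got J={J}, P={P}")
    if J == P:
        # canonical singleton labelling: cluster ids ordered by location index
        return ClusterMap(J=J, assignment=np.arange(P))
    centers = _farthest_point_centers(coords, J)
    km = KMeans(n_clusters=J, init=centers, n_init=1, random_state=int(seed) % (2**31))
    labels = km.fit_predict(coords)
    # guard against empty clusters (sklearn relocates, so this should not trigger)
    used, labels = np.unique(labels, return_inverse=True)
    return ClusterMap(J=len(used), assignment=labels)


def estimate_K(Z: np.ndarray) -> int:
    """Number of non-empty mixture components: K_hat = sum_l I{sum_v Z_vl != 0}.

    Fitting with a deliberately generous K leaves redundant components with no
    assigned voxel; counting the occupied ones estimates the model order.
    """
    Z = _check_one_hot(Z)
    return int(np.count_nonzero(Z.sum(axis=0)))
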