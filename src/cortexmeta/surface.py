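"""Triangulated cortical surfaces and per-vertex scalar maps.

The mesh is the geometric substrate of the whole pipeline: it carries the
native (mm) vertex positions used for areas and smoothing, a matched
unit-sphere registration used by the spin test, and a boolean cortex mask
(the medial-wall analogue) that restricts every analysis to cortical
vertices.  Synthetic spheres built by :func:`build_icosphere` stand in for
a registered cortical template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SurfaceMesh",
    "VertexMap",
    "build_icosphere",
    "vertex_areas",
    "smooth_map",
    "smoothing_operator",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian = sigma * sqrt(8 ln 2)
_FWHM_FACTOR = float(np.sqrt(8.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Convert a full width at half maximum to the Gaussian sigma."""
    return fwhm_mm / _FWHM_FACTOR


@dataclass
class SurfaceMesh:
    """A triangulated surface with spherical registration and cortex mask.

    Parameters
    ----------
    vertex_coords : (V, 3) float array
        Native-space positions in mm.
    triangles : (F, 3) int array
        Vertex index triples.
    sphere_coords : (V, 3) float array
        Matched positions on the unit sphere (one per vertex).
    cortex_mask : (V,) bool array
        True for vertices inside the analysis domain.
    hemisphere : (V,) array of "L"/"R", optional
        Per-vertex hemisphere label for bilateral meshes.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    sphere_coords: np.ndarray
    cortex_mask: np.ndarray
    hemisphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=np.float64)
        self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        nv = self.n_vertices
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise ValueError("vertex_coords must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= nv:
                raise ValueError("triangle indices out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise ValueError("degenerate triangle with repeated vertex index")
        if self.sphere_coords.shape != (nv, 3):
            raise ValueError("sphere_coords must match vertex count")
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("sphere_coords must have unit norm (tolerance 1e-9)")
        if self.cortex_mask.shape != (nv,):
            raise ValueError("cortex_mask length must equal vertex count")
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
            if self.hemisphere.shape != (nv,):
                raise ValueError("hemisphere labels must match vertex count")

    # -- basic geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) int array with i < j."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        d = self.vertex_coords[self.edges[:, 0]] - self.vertex_coords[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @cached_property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex adjacency matrix."""
        e = self.edges
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix(
            (np.ones(i.size), (i, j)), shape=(self.n_vertices, self.n_vertices)
        )

    def cortex_connected(self) -> bool:
        """Report whether the triangle graph restricted to the mask is connected."""
        idx = np.flatnonzero(self.cortex_mask)
        if idx.size == 0:
            return True
        sub = self.adjacency[idx][:, idx]
        n, _ = connected_components(sub, directed=False)
        return n == 1

    def angular_distance(self, vertex: int) -> np.ndarray:
        """Great-circle distance (radians) from one vertex to all vertices."""
        c = np.clip(self.sphere_coords @ self.sphere_coords[vertex], -1.0, 1.0)
        return np.arccos(c)


@dataclass
class VertexMap:
    """One scalar per vertex plus a validity mask.

    Non-finite values are only allowed where ``valid_mask`` is False; the
    constructor enforces this so downstream reductions never silently
    swallow NaNs.
    """

    values: np.ndarray
    valid_mask: np.ndarray | None = None
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask must match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite values inside the valid mask")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def bound_to(self, mesh: SurfaceMesh) -> None:
        if self.n_vertices != mesh.n_vertices:
            raise ValueError(
                f"map has {self.n_vertices} vertices, mesh has {mesh.n_vertices}"
            )


# ---------------------------------------------------------------------------
# Icosphere construction
# ---------------------------------------------------------------------------

def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Canonical unit icosahedron (fixed orientation, fixed vertex order)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def build_icosphere(subdivision_level: int, radius_mm: float = 100.0) -> SurfaceMesh:
    """Build a geodesic sphere by midpoint subdivision of an icosahedron.

    The mesh has ``10 * 4**L + 2`` vertices and ``20 * 4**L`` triangles.
    Vertex order is deterministic (midpoint cache keyed by sorted edge), so
    seeded simulations on the sphere are bit-reproducible.  The cortex mask
    starts all-true.
    """
    level = int(subdivision_level)
    if level < 0:
        raise ValueError("subdivision_level must be non-negative")
    if level > 7:
        raise ValueError("subdivision_level > 7 would build an excessively large mesh")
    if not (radius_mm > 0):
        raise ValueError("radius_mm must be positive")

    verts, faces = _base_icosahedron()
    verts = list(map(tuple, verts))
    for _ in range(level):
        cache: dict[tuple[int, int], int] = {}
        new_faces = []

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            idx = cache.get(key)
            if idx is None:
                m = np.add(verts[a], verts[b]) / 2.0
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                idx = len(verts) - 1
                cache[key] = idx
            return idx

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=np.int64)

    unit = np.asarray(verts, dtype=np.float64)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    return SurfaceMesh(
        vertex_coords=unit * float(radius_mm),
        triangles=faces,
        sphere_coords=unit,
        cortex_mask=np.ones(len(unit), dtype=bool),
    )


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def vertex_areas(mesh: SurfaceMesh) -> VertexMap:
    """Per-vertex surface area in mm^2 (one third of incident triangle areas).

    The sum over vertices equals the total mesh area exactly, mirroring the
    way local surface area tiles the cortical sheet.
    """
    if mesh.n_triangles == 0:
        raise ValueError("mesh has no triangles")
    p = mesh.vertex_coords[mesh.triangles]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(areas, mesh.triangles[:, k], tri_area / 3.0)
    return VertexMap(areas, np.ones(mesh.n_vertices, bool), name="vertex_area", units="mm^2")


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smoothing_operator(
    mesh: SurfaceMesh,
    fwhm_mm: float,
    valid_mask: np.ndarray | None = None,
) -> tuple[sparse.csr_matrix, int]:
    """Iterated-diffusion smoothing operator calibrated to a geodesic FWHM.

    Returns the one-step operator ``W`` and the iteration count ``n`` such
    that ``W**n`` spreads a point source to approximately the requested
    FWHM.  ``W`` keeps half the mass on the vertex itself and distributes
    the other half over valid first-ring neighbours with symmetric
    Metropolis weights (1/max(deg_i, deg_j), remainder to the diagonal), so
    ``W`` is symmetric and doubly stochastic: constants are fixed points,
    the mean over the valid mask is preserved exactly and the variance can
    only decrease.  Iterated diffusion tends to a Gaussian whose per-axis
    variance grows by the kernel's per-axis second moment each step, so the
    iteration count is ``n = round(sigma^2 / v1)`` with
    ``sigma = FWHM / sqrt(8 ln 2)`` and
    ``v1 = mean_i sum_j W_ij |x_j - x_i|^2 / 2`` (the /2 converts the 2-D
    squared displacement on the surface to a per-axis variance).  The
    point-source FWHM test verifies the calibration empirically.

    Vertices outside ``valid_mask`` neither contribute nor receive weight
    (their rows are identity), which avoids attenuation at mask borders.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if valid_mask is None:
        valid_mask = np.ones(mesh.n_vertices, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)

    nv = mesh.n_vertices
    e = mesh.edges
    keep = valid_mask[e[:, 0]] & valid_mask[e[:, 1]]
    e = e[keep]
    lengths = mesh.edge_lengths[keep]

    if fwhm_mm == 0 or e.size == 0:
        return sparse.identity(nv, format="csr"), 0

    deg = np.zeros(nv, dtype=np.int64)
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    w = 1.0 / np.maximum(deg[e[:, 0]], deg[e[:, 1]])
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    vals = np.concatenate([w, w])
    a = sparse.csr_matrix((vals, (rows, cols)), shape=(nv, nv))
    diag = 1.0 - np.asarray(a.sum(axis=1)).ravel()
    a = a + sparse.diags(diag)
    w_op = (0.5 * sparse.identity(nv) + 0.5 * a).tocsr()

    # per-axis variance added by one iteration, from the kernel itself
    row_d2 = np.zeros(nv)
    half = 0.5 * np.concatenate([w, w])  # off-diagonal weights of W
    np.add.at(row_d2, rows, half * np.concatenate([lengths, lengths]) ** 2)
    v1 = float(row_d2[valid_mask].mean()) / 2.0
    sigma2 = fwhm_to_sigma(fwhm_mm) ** 2
    n_iter = int(round(sigma2 / v1))
    return w_op, n_iter


def smooth_map(vmap: VertexMap, mesh: SurfaceMesh, fwhm_mm: float) -> VertexMap:
    """Smooth a vertex map along the mesh to the requested geodesic FWHM.

    A zero FWHM returns the input unchanged; masked vertices are carried
    through untouched.
    """
    vmap.bound_to(mesh)
    w_op, n_iter = smoothing_operator(mesh, fwhm_mm, vmap.valid_mask)
    values = vmap.values.copy()
    if n_iter:
        work = np.where(vmap.valid_mask, values, 0.0)
        for _ in range(n_iter):
            work = w_op @ work
        values[vmap.valid_mask] = work[vmap.valid_mask]
    return VertexMap(values, vmap.valid_mask.copy(), name=vmap.name, units=vmap.units)


def smooth_matrix(
    data: np.ndarray,
    mesh: SurfaceMesh,
    fwhm_mm: float,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Smooth many maps at once; ``data`` is (n_maps, V), rows are maps."""
    w_op, n_iter = smoothing_operator(mesh, fwhm_mm, valid_mask)
    out = np.asarray(data, dtype=np.float64)
    for _ in range(n_iter):
        out = (w_op @ out.T).T
    return out


def smoothed_noise_sd(
    mesh: SurfaceMesh,
    fwhm_mm: float,
    valid_mask: np.ndarray | None = None,
    chunk: int = 1024,
) -> np.ndarray:
    """Per-vertex SD of unit white noise after smoothing (row norms of W^n)."""
    w_op, n_iter = smoothing_operator(mesh, fwhm_mm, valid_mask)
    nv = mesh.n_vertices
    if n_iter == 0:
        return np.ones(nv)
    out = np.zeros(nv)
    for start in range(0, nv, chunk):
        block = np.zeros((nv, min(chunk, nv - start)))
        block[np.arange(start, start + block.shape[1]), np.arange(block.shape[1])] = 1.0
        for _ in range(n_iter):
            block = w_op @ block
        out += np.sum(block * block, axis=1)
    return np.sqrt(out)
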