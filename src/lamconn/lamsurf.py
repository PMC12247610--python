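"""Laminar surface geometry: equi-volume cortical depths, volume-to-surface
sampling, within-depth smoothing, and depth-specific surface registration.

The cortical ribbon is represented as a family of ``n_depths`` surfaces that
share one triangulation (a :class:`LaminarMesh`).  Depth index 0 is the
white-matter boundary side and depth ``n_depths - 1`` the pial side; all
laminar profiles produced by this package follow that deep-to-superficial
ordering.  Intermediate surfaces are placed with the equi-volume rule: the
tissue volume between consecutive surfaces is constant at every vertex,
where local volume is modelled by linear interpolation of the inner/outer
one-ring vertex areas (the standard quadratic-in-depth volume model).

Group analysis relies on a :class:`RegistrationMap`, a sparse
individual-to-template vertex correspondence applied to every depth
separately, so laminar profiles are never mixed across depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "SurfaceMesh",
    "LaminarMesh",
    "LaminarDataset",
    "RegistrationMap",
    "icosahedron",
    "icosphere",
    "refine_mesh",
    "equivolume_depth_fraction",
    "build_depth_surfaces",
    "sample_volume_to_surface",
    "smooth_within_depth",
    "apply_registration",
]


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """A closed triangle mesh (vertices in mm, consistently oriented)."""

    vertices: np.ndarray  # (V, 3) float
    triangles: np.ndarray  # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[0] < e[1]."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def triangle_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        v = self.vertices if vertices is None else vertices
        a = v[self.triangles[:, 1]] - v[self.triangles[:, 0]]
        b = v[self.triangles[:, 2]] - v[self.triangles[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def vertex_areas(self, vertices: np.ndarray | None = None) -> np.ndarray:
        """Per-vertex area share: one third of each incident triangle."""
        ta = self.triangle_areas(vertices)
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.triangles[:, k], ta / 3.0)
        return va

    def vertex_normals(self, vertices: np.ndarray | None = None) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v = self.vertices if vertices is None else vertices
        a = v[self.triangles[:, 1]] - v[self.triangles[:, 0]]
        b = v[self.triangles[:, 2]] - v[self.triangles[:, 0]]
        fn = np.cross(a, b)  # magnitude = 2 * area
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex adjacency matrix."""
        e = self.edges()
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.n_vertices, self.n_vertices)
        )

    def mean_sq_edge_length(self, vertices: np.ndarray | None = None) -> float:
        v = self.vertices if vertices is None else vertices
        e = self.edges()
        d = v[e[:, 0]] - v[e[:, 1]]
        return float(np.mean(np.sum(d * d, axis=1)))

    def validate(self) -> None:
        """Reject degenerate triangles and inconsistent orientation."""
        if np.any(self.triangle_areas() <= 0):
            raise ValueError("mesh contains degenerate triangles")
        # closed + consistently oriented <=> every directed edge appears once
        t = self.triangles
        de = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        _, counts = np.unique(de, axis=0, return_counts=True)
        if np.any(counts != 1):
            raise ValueError("mesh is not a closed, consistently oriented surface")


@dataclass
class LaminarMesh:
    """Family of depth surfaces sharing one triangulation.

    ``coords[v, d]`` is the position of vertex ``v`` on depth surface ``d``;
    depth 0 lies on the white surface side, depth ``n_depths - 1`` on the
    pial side.  ``depth_fractions[d]`` is the cumulative volume fraction
    alpha_d at which the surface was placed (bin centers ``(d + 0.5) / D``).
    """

    base: SurfaceMesh
    coords: np.ndarray  # (V, D, 3)
    depth_fractions: np.ndarray  # (D,)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.depth_fractions = np.asarray(self.depth_fractions, dtype=float)
        if self.coords.shape[0] != self.base.n_vertices:
            raise ValueError("coords/base vertex count mismatch")
        if self.coords.shape[1] != len(self.depth_fractions):
            raise ValueError("coords/depth_fractions mismatch")

    @property
    def n_vertices(self) -> int:
        return self.base.n_vertices

    @property
    def n_depths(self) -> int:
        return self.coords.shape[1]

    def depth_surface(self, d: int) -> SurfaceMesh:
        return SurfaceMesh(self.coords[:, d, :], self.base.triangles)


@dataclass
class LaminarDataset:
    """Values sampled on a laminar mesh: (vertex, depth, time) or (vertex, depth)."""

    values: np.ndarray
    mesh: LaminarMesh
    session_id: str = ""
    n_missing: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.mesh.n_vertices:
            raise ValueError("values/mesh vertex count mismatch")
        if self.values.shape[1] != self.mesh.n_depths:
            raise ValueError("values/mesh depth count mismatch")


# --------------------------------------------------------------------------
# primitive meshes and refinement
# --------------------------------------------------------------------------

def icosahedron(radius: float = 1.0) -> SurfaceMesh:
    """Regular icosahedron with vertices on a sphere of the given radius."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts *= radius / np.linalg.norm(verts[0])
    tris = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return SurfaceMesh(verts, tris)


def refine_mesh(
    mesh: SurfaceMesh,
    iterations: int = 1,
    *,
    project_radius: float | None = None,
    return_prolongation: bool = False,
):
    """Midpoint (loop-topology) subdivision: V' = V + E, F' = 4F per iteration.

    Existing vertices keep their index and position; each new vertex is the
    midpoint of an edge.  With ``project_radius`` set, all vertices are
    re-projected to that sphere radius after each iteration (icosphere
    construction).  With ``return_prolongation=True``, also returns a sparse
    (V_new, V_old) matrix that interpolates vertex data onto the refined
    mesh (old vertices preserved, new vertices averaged from edge endpoints).
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    prol = sparse.identity(mesh.n_vertices, format="csr")
    for _ in range(iterations):
        v, t = mesh.vertices, mesh.triangles
        e = mesh.edges()
        n_v = len(v)
        mid_index = {(int(a), int(b)): n_v + k for k, (a, b) in enumerate(e)}
        new_v = np.vstack([v, 0.5 * (v[e[:, 0]] + v[e[:, 1]])])
        if project_radius is not None:
            new_v *= project_radius / np.linalg.norm(new_v, axis=1, keepdims=True)

        def mid(a: int, b: int) -> int:
            return mid_index[(a, b) if a < b else (b, a)]

        new_t = []
        for a, b, c in t:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_t += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        mesh = SurfaceMesh(new_v, np.array(new_t, dtype=np.int64))
        if return_prolongation:
            rows = np.concatenate([np.arange(n_v), np.repeat(np.arange(n_v, len(new_v)), 2)])
            cols = np.concatenate([np.arange(n_v), e.ravel()])
            vals = np.concatenate([np.ones(n_v), np.full(2 * len(e), 0.5)])
            step = sparse.csr_matrix((vals, (rows, cols)), shape=(len(new_v), n_v))
            prol = step @ prol
    if return_prolongation:
        return mesh, prol
    return mesh


def icosphere(subdivisions: int = 2, radius: float = 1.0) -> SurfaceMesh:
    """Icosahedron subdivided and projected onto a sphere."""
    return refine_mesh(icosahedron(radius), subdivisions, project_radius=radius)


# --------------------------------------------------------------------------
# equi-volume depths
# --------------------------------------------------------------------------

def equivolume_depth_fraction(a_w, a_p, alpha):
    """Distance fraction rho between white (0) and pial (1) surfaces at which
    the cumulative tissue volume fraction equals ``alpha``.

    The local cross-sectional area is modelled as linear in rho between the
    inner one-ring area ``a_w`` and the outer area ``a_p``, so the cumulative
    volume is quadratic in rho and

        rho = (-a_w + sqrt((1 - alpha) a_w^2 + alpha a_p^2)) / (a_p - a_w)

    with the equidistant limit rho = alpha when a_w == a_p.  Vectorized over
    all arguments.
    """
    a_w = np.asarray(a_w, dtype=float)
    a_p = np.asarray(a_p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(a_w <= 0) or np.any(a_p <= 0):
        raise ValueError("areas must be positive")
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise ValueError("alpha must lie in [0, 1]")
    a_w, a_p, alpha = np.broadcast_arrays(a_w, a_p, alpha)
    diff = a_p - a_w
    scale = np.maximum(a_w, a_p)
    flat = np.abs(diff) < 1e-12 * scale
    safe_diff = np.where(flat, 1.0, diff)
    rad = (1.0 - alpha) * a_w**2 + alpha * a_p**2
    rho = np.where(flat, alpha, (-a_w + np.sqrt(rad)) / safe_diff)
    out = np.clip(rho, 0.0, 1.0)
    return out if out.ndim else float(out)


def build_depth_surfaces(white: SurfaceMesh, pial: SurfaceMesh, n_depths: int = 18) -> LaminarMesh:
    """Place ``n_depths`` equi-volume surfaces between white and pial.

    Depth d sits at cumulative volume fraction alpha_d = (d + 0.5) / D (bin
    centers), converted per vertex to a distance fraction along the
    white-to-pial segment using the vertex's one-ring area on each boundary
    surface.
    """
    if white.n_vertices != pial.n_vertices or not np.array_equal(
        white.triangles, pial.triangles
    ):
        raise ValueError("white and pial surfaces must share topology")
    if n_depths < 2:
        raise ValueError("n_depths must be >= 2")
    a_w = white.vertex_areas()
    a_p = pial.vertex_areas()
    alphas = (np.arange(n_depths) + 0.5) / n_depths
    rho = equivolume_depth_fraction(a_w[:, None], a_p[:, None], alphas[None, :])  # (V, D)
    seg = pial.vertices - white.vertices  # (V, 3)
    coords = white.vertices[:, None, :] + rho[:, :, None] * seg[:, None, :]
    return LaminarMesh(base=white, coords=coords, depth_fractions=alphas)


# --------------------------------------------------------------------------
# volume -> surface sampling
# --------------------------------------------------------------------------

def _trilinear(data: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Trilinear sampling of ``data`` (X, Y, Z[, T]) at fractional voxel
    coordinates ``ijk`` (P, 3).  Points outside the grid return NaN.

    NaN-aware across space: a corner voxel that is NaN at every time point
    (e.g. outside an analysis mask) is dropped and the remaining corner
    weights are renormalized, so sampling near a mask edge degrades to a
    weighted mean of the valid corners instead of NaN.  Time points that are
    NaN everywhere (censored) stay NaN.
    """
    shape = np.array(data.shape[:3])
    out_shape = (len(ijk),) + data.shape[3:]
    out = np.full(out_shape, np.nan)
    inside = np.all((ijk >= 0) & (ijk <= shape - 1), axis=1)
    if not np.any(inside):
        return out
    p = ijk[inside]
    i0 = np.floor(p).astype(int)
    i0 = np.minimum(i0, shape - 2)  # keep the +1 corner in range
    f = p - i0
    acc = np.zeros((len(p),) + data.shape[3:])
    wsum = np.zeros(len(p))
    tail = (1,) * (data.ndim - 3)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                vals = data[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                if data.ndim == 3:
                    valid = np.isfinite(vals)
                else:
                    valid = np.any(np.isfinite(vals), axis=-1)
                wv = w * valid
                acc += wv.reshape((-1,) + tail) * np.where(
                    valid.reshape((-1,) + tail), vals, 0.0
                )
                wsum += wv
    ok = wsum > 1e-12
    acc[ok] /= wsum[ok].reshape((-1,) + tail)
    acc[~ok] = np.nan
    out[inside] = acc
    return out


def sample_volume_to_surface(
    data: np.ndarray,
    affine: np.ndarray,
    lmesh: LaminarMesh,
    mode: str = "trilinear",
    session_id: str = "",
) -> LaminarDataset:
    """Sample a volume (X, Y, Z) or series (X, Y, Z, T) at every (vertex,
    depth) coordinate of the laminar mesh.

    Coordinates are in mm and converted to voxel space through the NIfTI
    affine.  ``mode='trilinear'`` interpolates directly;
    ``mode='upsample5_nearest'`` emulates 5x grid upsampling followed by
    nearest-neighbour lookup by snapping the sampling point to the 5x-finer
    voxel lattice before interpolating.  Vertices falling outside the volume
    yield NaN and are counted in ``n_missing``.
    """
    data = np.asarray(data, dtype=float)
    V, D = lmesh.n_vertices, lmesh.n_depths
    pts = lmesh.coords.reshape(-1, 3)
    inv = np.linalg.inv(affine)
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    if mode == "upsample5_nearest":
        ijk = np.round(ijk * 5.0) / 5.0
    elif mode != "trilinear":
        raise ValueError(f"unknown sampling mode: {mode!r}")
    sampled = _trilinear(data, ijk)
    values = sampled.reshape((V, D) + data.shape[3:])
    # a point is missing when no time point could be sampled (censored pairs
    # are NaN at every location and must not count)
    n_missing = int(np.sum(np.all(~np.isfinite(sampled.reshape(len(ijk), -1)), axis=1)))
    if n_missing:
        warnings.warn(f"{n_missing} surface sample points fell outside the volume")
    return LaminarDataset(values=values, mesh=lmesh, session_id=session_id, n_missing=n_missing)


# --------------------------------------------------------------------------
# within-depth smoothing
# --------------------------------------------------------------------------

def smooth_within_depth(data: LaminarDataset, fwhm: float = 3.0) -> LaminarDataset:
    """Heat-kernel (iterated neighbour-averaging) smoothing along each depth
    surface independently; depths never exchange signal.

    Each iteration moves a fraction lambda of every vertex value to the mean
    of its neighbours, adding per-axis positional variance lambda * h2 / 2
    where h2 is the mean squared edge length of that depth surface.  The
    iteration count and lambda are calibrated so the total kernel standard
    deviation matches sigma = fwhm / 2.3548.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return LaminarDataset(data.values.copy(), data.mesh, data.session_id, data.n_missing)
    mesh = data.mesh
    adj = mesh.base.adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    W = sparse.diags(1.0 / deg) @ adj  # row-stochastic neighbour average
    sigma2 = (fwhm / 2.3548) ** 2
    out = np.array(data.values, dtype=float, copy=True)
    flat = out.reshape(mesh.n_vertices, mesh.n_depths, -1)
    for d in range(mesh.n_depths):
        h2 = mesh.base.mean_sq_edge_length(mesh.coords[:, d, :])
        target = 2.0 * sigma2 / h2  # required n * lambda
        n_iter = max(1, int(np.ceil(target / 0.5)))
        lam = target / n_iter
        x = flat[:, d, :]
        for _ in range(n_iter):
            x = (1.0 - lam) * x + lam * (W @ x)
        flat[:, d, :] = x
    return LaminarDataset(out, mesh, data.session_id, data.n_missing)


# --------------------------------------------------------------------------
# depth-specific registration
# --------------------------------------------------------------------------

@dataclass
class RegistrationMap:
    """Individual-to-template surface correspondence, one map for all depths.

    Row t of ``matrix`` holds the nonnegative interpolation weights of
    template vertex t over individual vertices; rows sum to 1.
    """

    matrix: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        if np.any(self.matrix.data < 0):
            raise ValueError("registration weights must be nonnegative")
        rs = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.any(np.abs(rs - 1.0) > 1e-6):
            warnings.warn("registration weights did not sum to 1; renormalizing")
            bad = rs <= 0
            if np.any(bad):
                raise ValueError("registration map has empty rows")
            self.matrix = sparse.diags(1.0 / rs) @ self.matrix
            self.matrix = sparse.csr_matrix(self.matrix)

    @classmethod
    def identity(cls, n: int) -> "RegistrationMap":
        return cls(sparse.identity(n, format="csr"))

    @classmethod
    def from_permutation(cls, perm: np.ndarray) -> "RegistrationMap":
        """Template vertex t corresponds to individual vertex perm[t]."""
        perm = np.asarray(perm, dtype=int)
        n = len(perm)
        return cls(sparse.csr_matrix((np.ones(n), (np.arange(n), perm)), shape=(n, n)))

    @property
    def n_template(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_individual(self) -> int:
        return self.matrix.shape[1]


def apply_registration(
    regmap: RegistrationMap,
    data: LaminarDataset,
    template_mesh: LaminarMesh | None = None,
) -> LaminarDataset:
    """Resample laminar data onto the template, depth by depth.

    The same vertex correspondence is used at every depth, so the transform
    is block-diagonal over depths and cannot blur laminar profiles.
    """
    if regmap.n_individual != data.mesh.n_vertices:
        raise ValueError("registration map does not match data mesh")
    vals = data.values
    V, D = vals.shape[0], vals.shape[1]
    flat = vals.reshape(V, -1)
    out = regmap.matrix @ flat
    out = out.reshape((regmap.n_template, D) + vals.shape[2:])
    mesh = template_mesh if template_mesh is not None else data.mesh
    return LaminarDataset(out, mesh, data.session_id, data.n_missing)
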