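"""Cortical mesh model and laminar geometry.

A cortical hemisphere is a pair of triangulated surfaces (white and pial)
sharing one triangulation, so every vertex defines a white-to-pial
trajectory.  This module places intermediate *equivolume* depth surfaces
along those trajectories, samples image volumes onto them with a
ribbon-weighted scheme, and provides the vertexwise geometric covariates
(thickness, curvature) and geodesic distances used downstream.

Equivolume depths: the cross-sectional area of the cortical wedge over a
vertex's one-ring interpolates quadratically between the white and pial
vertex areas, A(t) = ((1-t) sqrt(A_w) + t sqrt(A_p))^2 with t the
normalized distance along the trajectory.  A surface at *volume* fraction
f is placed at the t whose cumulative wedge volume is f of the total —
this compensates the curvature dependence of laminar thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix, coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "CorticalMesh",
    "QVolume",
    "DepthSurfaceSet",
    "VertexMetricMap",
    "RibbonGeometry",
    "equivolume_t",
    "equivolume_fraction_to_position",
    "build_depth_set",
    "ribbon_sample",
    "ribbon_sample_weights",
    "vertex_thickness",
    "vertex_curvature",
    "geodesic_distance",
    "ribbon_geometry",
    "point_trajectory_coords",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorticalMesh:
    """Triangulated cortical surface in world millimetres."""

    vertices: np.ndarray  # (N, 3) float
    triangles: np.ndarray  # (M, 3) int
    hemisphere: str = "right"  # {"left", "right"}

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= len(
            self.vertices
        ):
            raise ValueError("triangle indices out of range")
        self._cache: dict = {}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    # -- derived combinatorics, cached per mesh ---------------------------

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2), sorted pairs."""
        if "edges" not in self._cache:
            t = self.triangles
            e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
            e = np.sort(e, axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    @property
    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric one-ring vertex areas (a third of each incident triangle)."""
        if "vertex_areas" not in self._cache:
            areas = np.zeros(self.n_vertices)
            np.add.at(
                areas, self.triangles.ravel(), np.repeat(self.triangle_areas / 3.0, 3)
            )
            self._cache["vertex_areas"] = areas
        return self._cache["vertex_areas"]

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        if "vertex_normals" not in self._cache:
            v = self.vertices[self.triangles]
            fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
            normals = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(normals, self.triangles[:, k], fn)
            norms = np.linalg.norm(normals, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._cache["vertex_normals"] = normals / norms
        return self._cache["vertex_normals"]

    @property
    def adjacency(self) -> csr_matrix:
        """Sparse vertex adjacency weighted by edge length (symmetric)."""
        if "adjacency" not in self._cache:
            e = self.edges
            w = self.edge_lengths
            n = self.n_vertices
            a = coo_matrix(
                (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                shape=(n, n),
            )
            self._cache["adjacency"] = a.tocsr()
        return self._cache["adjacency"]

    @property
    def geodesic_adjacency(self) -> csr_matrix:
        """Edge graph augmented with across-edge shortcuts.

        For every interior edge the two opposite triangle corners are
        connected with their distance in the plane obtained by unfolding
        the two triangles about the shared edge (only when the unfolded
        segment actually crosses the edge).  This reduces the metrication
        bias of plain edge-graph Dijkstra.
        """
        if "geo_adjacency" in self._cache:
            return self._cache["geo_adjacency"]
        t = self.triangles
        v = self.vertices
        e = np.sort(np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
        opp = np.concatenate([t[:, 2], t[:, 0], t[:, 1]])
        order = np.lexsort((e[:, 1], e[:, 0]))
        e, opp = e[order], opp[order]
        same = np.all(e[1:] == e[:-1], axis=1)
        i0 = np.flatnonzero(same)  # paired rows: interior edges
        u, w = e[i0, 0], e[i0, 1]
        a, b = opp[i0], opp[i0 + 1]
        L = np.linalg.norm(v[w] - v[u], axis=1)
        ua = np.linalg.norm(v[a] - v[u], axis=1)
        va = np.linalg.norm(v[a] - v[w], axis=1)
        ub = np.linalg.norm(v[b] - v[u], axis=1)
        vb = np.linalg.norm(v[b] - v[w], axis=1)
        xa = (ua**2 + L**2 - va**2) / (2 * L)
        xb = (ub**2 + L**2 - vb**2) / (2 * L)
        ya = np.sqrt(np.maximum(ua**2 - xa**2, 0.0))
        yb = np.sqrt(np.maximum(ub**2 - xb**2, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            xc = xa + (xb - xa) * ya / np.maximum(ya + yb, 1e-300)
        crosses = (xc >= 0) & (xc <= L) & (ya + yb > 0)
        d = np.sqrt((xa - xb) ** 2 + (ya + yb) ** 2)
        a, b, d = a[crosses], b[crosses], d[crosses]
        n = self.n_vertices
        base = self.adjacency.tocoo()
        rows = np.r_[base.row, a, b]
        cols = np.r_[base.col, b, a]
        data = np.r_[base.data, d, d]
        # keep the minimum weight where a shortcut duplicates an edge
        key = rows * n + cols
        order2 = np.argsort(key, kind="stable")
        key, rows, cols, data = key[order2], rows[order2], cols[order2], data[order2]
        starts = np.r_[0, np.flatnonzero(np.diff(key)) + 1]
        dmin = np.minimum.reduceat(data, starts)
        g = coo_matrix((dmin, (rows[starts], cols[starts])), shape=(n, n)).tocsr()
        self._cache["geo_adjacency"] = g
        return g

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Vertices on an open boundary (edges with one incident triangle)."""
        if "boundary" not in self._cache:
            t = self.triangles
            e = np.sort(np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            self._cache["boundary"] = np.unique(uniq[counts == 1])
        return self._cache["boundary"]

    def validate(self) -> None:
        """Reject non-manifold edges and degenerate triangles."""
        t = self.triangles
        e = np.sort(np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise ValueError("non-manifold edge (more than two incident triangles)")
        if np.any(self.triangle_areas <= 0):
            raise ValueError("degenerate (zero-area) triangle")


@dataclass
class QVolume:
    """3D scalar image with a voxel-to-world affine.

    Voxel centers sit at ``affine @ (i, j, k, 1)`` in world millimetres
    (RAS); surfaces and volumes share this world space.
    """

    data: np.ndarray
    affine: np.ndarray
    tag: str = "qT1"  # {"qT1", "qT2", "M0", other}

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class VertexMetricMap:
    """Per-vertex scalar map (qT1/qT2 at a depth, thickness, curvature, ...)."""

    values: np.ndarray
    name: str = ""
    units: str = ""
    valid: np.ndarray | None = None  # False where flagged (missing / boundary)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)


@dataclass
class DepthSurfaceSet:
    """Equivolume depth surfaces over one white/pial pair.

    ``levels`` are floats: values in [0, 1] are equivolume volume fractions
    (0 = WM/GM boundary, 1 = pial); negative values are millimetres below
    the WM/GM boundary (-1.0 means 1 mm inward along the white normal).
    """

    white: CorticalMesh
    pial: CorticalMesh
    levels: tuple[float, ...]
    coords: dict[float, np.ndarray] = field(default_factory=dict)
    flagged: np.ndarray | None = None  # vertices with degenerate trajectories

    def mesh_at(self, level: float) -> CorticalMesh:
        return CorticalMesh(
            self.coords[level], self.white.triangles, self.white.hemisphere
        )


# ---------------------------------------------------------------------------
# equivolume construction


def equivolume_t(area_white, area_pial, fraction) -> np.ndarray:
    """Normalized trajectory parameter t at cortical volume fraction f.

    With a = sqrt(A_w), b = sqrt(A_p) and quadratic area profile
    A(t) = (a + (b-a) t)^2, cumulative volume from the white surface is
    V(t) = ((a + (b-a)t)^3 - a^3) / (3 (b-a)); setting V(t)/V(1) = f gives

        t(f) = ((a^3 + f (b^3 - a^3))^{1/3} - a) / (b - a)

    which reduces to t = f when the areas are equal (flat slab).
    """
    a = np.sqrt(np.asarray(area_white, dtype=float))
    b = np.sqrt(np.asarray(area_pial, dtype=float))
    f = np.asarray(fraction, dtype=float)
    if np.any((a == 0) & (b == 0)):
        raise ValueError("degenerate wedge: both vertex areas are zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (np.cbrt(a**3 + f * (b**3 - a**3)) - a) / (b - a)
    equal = np.isclose(a, b, rtol=1e-12)
    if np.ndim(t) == 0:
        return np.asarray(f) if equal else t
    t = np.where(equal, np.broadcast_to(f, t.shape), t)
    return t


def equivolume_fraction_to_position(
    white: CorticalMesh, pial: CorticalMesh, fraction: float
) -> np.ndarray:
    """Vertex coordinates of the equivolume surface at one volume fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if white.triangles.shape != pial.triangles.shape or np.any(
        white.triangles != pial.triangles
    ):
        raise ValueError("white and pial must share one triangulation")
    if fraction == 0.0:
        return white.vertices.copy()
    if fraction == 1.0:
        return pial.vertices.copy()
    t = equivolume_t(white.vertex_areas, pial.vertex_areas, fraction)
    return white.vertices + t[:, None] * (pial.vertices - white.vertices)


def build_depth_set(
    white: CorticalMesh,
    pial: CorticalMesh,
    fractions=(0.2, 0.4, 0.6, 0.8),
    sub_wm_mm: float = 0.0,
) -> DepthSurfaceSet:
    """Equivolume surfaces at the requested fractions plus an optional
    sub-white level ``sub_wm_mm`` millimetres inward along the white normal.

    Vertices whose trajectory is degenerate (pial not strictly outside the
    white surface along its normal) are flagged, not silently accepted.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    if sub_wm_mm < 0:
        raise ValueError("sub_wm_mm must be >= 0")
    levels = list(fractions)
    coords = {f: equivolume_fraction_to_position(white, pial, f) for f in fractions}
    if sub_wm_mm > 0:
        lvl = -float(sub_wm_mm)
        coords[lvl] = white.vertices - sub_wm_mm * white.vertex_normals
        levels.append(lvl)
    levels = tuple(sorted(levels))
    offset = np.einsum("ij,ij->i", pial.vertices - white.vertices, white.vertex_normals)
    flagged = offset <= 0
    return DepthSurfaceSet(
        white=white, pial=pial, levels=levels, coords=coords, flagged=flagged
    )


# ---------------------------------------------------------------------------
# ribbon-constrained volume-to-surface sampling


def _one_ring_points(mesh_coords: np.ndarray, triangles: np.ndarray):
    """Quadrature points tiling each vertex's one-ring cell at one surface.

    For every corner of every triangle: the corner itself, the midpoints of
    the two edges leaving it, and the triangle centroid — a 4-point proxy
    for the barycentric cell of that vertex.  Returns the point array and
    the owning vertex of each point.
    """
    tri = mesh_coords[triangles]  # (M, 3, 3)
    cent = tri.mean(axis=1)
    pts = []
    owners = []
    for k in range(3):
        v = tri[:, k]
        m1 = 0.5 * (tri[:, k] + tri[:, (k + 1) % 3])
        m2 = 0.5 * (tri[:, k] + tri[:, (k + 2) % 3])
        pts.append(np.stack([v, m1, m2, cent], axis=1).reshape(-1, 3))
        owners.append(np.repeat(triangles[:, k], 4))
    return np.concatenate(pts), np.concatenate(owners)


def ribbon_sample_weights(
    volume: QVolume,
    depth_set: DepthSurfaceSet,
    level: float,
    band_halfwidth_fraction: float = 0.1,
    n_band_steps: int = 5,
):
    """Voxel weights of the per-vertex ribbon polyhedron at one level.

    The polyhedron spanned by a vertex's one-ring between levels
    ``level - band`` and ``level + band`` is approximated by deterministic
    quadrature points (one-ring cell points at ``n_band_steps`` sub-levels);
    each voxel's weight is the fraction of the vertex's points falling in
    it, an estimate of the polyhedron/voxel overlap volume.  Sampling is
    ribbon-constrained: voxels whose center lies outside the cortical
    ribbon (above the pial surface, or above the white surface for sub-WM
    levels) receive no weight.  Weights are >= 0 and sum to 1 per valid
    vertex.

    Returns ``(flat_voxel_index, owner_vertex, weight, valid)`` where
    ``valid`` is False for vertices whose polyhedron intersects no usable
    voxel center.
    """
    white, pial = depth_set.white, depth_set.pial
    n_vert = white.n_vertices
    if level >= 0:
        sub = np.linspace(
            max(level - band_halfwidth_fraction, 0.0),
            min(level + band_halfwidth_fraction, 1.0),
            n_band_steps,
        )
        level_sets = [equivolume_fraction_to_position(white, pial, s) for s in sub]
    else:
        # sub-WM level: band expressed in millimetres along the white normal
        band_mm = band_halfwidth_fraction * float(
            np.median(vertex_thickness(white, pial).values)
        )
        sub = np.linspace(level - band_mm, min(level + band_mm, 0.0), n_band_steps)
        level_sets = [white.vertices + s * white.vertex_normals for s in sub]

    pts_list, owner_list = [], []
    for coords in level_sets:
        p, o = _one_ring_points(coords, white.triangles)
        pts_list.append(p)
        owner_list.append(o)
    pts = np.concatenate(pts_list)
    owners = np.concatenate(owner_list)

    ijk = np.rint(volume.world_to_voxel(pts)).astype(np.int64)
    shape = volume.data.shape
    inside = np.all((ijk >= 0) & (ijk < np.array(shape)), axis=1)
    ijk = ijk[inside]
    owners = owners[inside]
    flat = np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), shape)
    nvox = int(np.prod(shape))
    key = owners.astype(np.int64) * nvox + flat
    uniq, counts = np.unique(key, return_counts=True)
    owner_u = (uniq // nvox).astype(np.int64)
    flat_u = (uniq % nvox).astype(np.int64)

    # ribbon constraint on the unique candidate voxel centers
    cand_flat, inv = np.unique(flat_u, return_inverse=True)
    cand_ijk = np.stack(np.unravel_index(cand_flat, shape), axis=1).astype(float)
    centers = volume.voxel_to_world(cand_ijk)
    t_cand, _, _ = point_trajectory_coords(white, pial, centers)
    keep_cand = (t_cand >= 0.0) & (t_cand <= 1.0) if level >= 0 else t_cand <= 0.0
    keep = keep_cand[inv]
    owner_u, flat_u, counts = owner_u[keep], flat_u[keep], counts[keep]

    kept_counts = np.zeros(n_vert)
    np.add.at(kept_counts, owner_u, counts)
    valid = kept_counts > 0
    weights = counts / np.maximum(kept_counts[owner_u], 1)
    return flat_u, owner_u, weights, valid


def ribbon_sample(
    volume: QVolume,
    depth_set: DepthSurfaceSet,
    level: float,
    band_halfwidth_fraction: float = 0.1,
) -> VertexMetricMap:
    """Sample a volume onto the surface at one depth with ribbon weighting.

    Each vertex value is the overlap-weighted average of the voxels its
    ribbon polyhedron intersects; vertices whose polyhedron leaves the
    grid are flagged invalid (NaN).
    """
    flat, owner, w, valid = ribbon_sample_weights(
        volume, depth_set, level, band_halfwidth_fraction
    )
    n_vert = depth_set.white.n_vertices
    acc = np.zeros(n_vert)
    wsum = np.zeros(n_vert)
    np.add.at(acc, owner, w * volume.data.ravel()[flat])
    np.add.at(wsum, owner, w)
    values = np.full(n_vert, np.nan)
    ok = valid & (wsum > 0)
    values[ok] = acc[ok] / wsum[ok]
    return VertexMetricMap(
        values=values, name=f"{volume.tag}@{level:g}", units="ms", valid=ok
    )


# ---------------------------------------------------------------------------
# geometric covariates


def vertex_thickness(white: CorticalMesh, pial: CorticalMesh) -> VertexMetricMap:
    """Euclidean white-to-pial distance per corresponding vertex (mm)."""
    if white.n_vertices != pial.n_vertices:
        raise ValueError("meshes must share vertex correspondence")
    d = np.linalg.norm(pial.vertices - white.vertices, axis=1)
    return VertexMetricMap(values=d, name="thickness", units="mm")


def _mixed_voronoi_areas(mesh: CorticalMesh) -> np.ndarray:
    """Meyer-style mixed Voronoi cell areas, the consistent normalization
    for the cotangent Laplacian (falls back to area/2 vs area/4 splits in
    obtuse triangles)."""
    v = mesh.vertices
    t = mesh.triangles
    areas = np.zeros(mesh.n_vertices)
    tri_area = mesh.triangle_areas
    corners = []
    for k in range(3):
        a = v[t[:, k]]
        b = v[t[:, (k + 1) % 3]]
        c = v[t[:, (k + 2) % 3]]
        cosang = np.einsum("ij,ij->i", b - a, c - a)
        corners.append(cosang)  # unnormalized cos sign suffices for obtuse test
    obtuse_at = np.stack([c < 0 for c in corners])  # (3, M)
    any_obtuse = obtuse_at.any(axis=0)
    for k in range(3):
        i = t[:, k]
        a = v[i]
        b = v[t[:, (k + 1) % 3]]
        c = v[t[:, (k + 2) % 3]]
        # Voronoi contribution: (|ab|^2 cot C + |ac|^2 cot B) / 8
        def cot(p, q, r):  # angle at p in triangle (p, q, r)
            u, w = q - p, r - p
            return np.einsum("ij,ij->i", u, w) / np.maximum(
                np.linalg.norm(np.cross(u, w), axis=1), 1e-300
            )
        vor = (
            np.einsum("ij,ij->i", b - a, b - a) * cot(c, a, b)
            + np.einsum("ij,ij->i", c - a, c - a) * cot(b, c, a)
        ) / 8.0
        contrib = np.where(
            any_obtuse, np.where(obtuse_at[k], tri_area / 2.0, tri_area / 4.0), vor
        )
        np.add.at(areas, i, contrib)
    return areas


def vertex_curvature(mesh: CorticalMesh) -> VertexMetricMap:
    """Discrete mean curvature (1/mm) via the cotangent Laplace-Beltrami.

    H_i = -(L x)_i . n_i / 2 with L the cotangent Laplacian normalized by
    mixed Voronoi cell areas; positive for a sphere with outward normals,
    sign flips with orientation.  Open-boundary vertices are flagged
    invalid.
    """
    v = mesh.vertices
    t = mesh.triangles
    n = mesh.n_vertices
    lap = np.zeros_like(v)
    for k in range(3):
        i = t[:, k]
        j = t[:, (k + 1) % 3]
        o = t[:, (k + 2) % 3]  # vertex opposite edge (i, j)
        e1 = v[i] - v[o]
        e2 = v[j] - v[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-300)
        for a, b in ((i, j), (j, i)):
            np.add.at(lap, a, 0.5 * cot[:, None] * (v[b] - v[a]))
    area = _mixed_voronoi_areas(mesh)
    with np.errstate(invalid="ignore", divide="ignore"):
        lap = lap / area[:, None]
    h = -0.5 * np.einsum("ij,ij->i", lap, mesh.vertex_normals)
    valid = np.ones(n, dtype=bool)
    valid[mesh.boundary_vertices] = False
    h[~valid] = np.nan
    return VertexMetricMap(values=h, name="curvature", units="1/mm", valid=valid)


def geodesic_distance(mesh: CorticalMesh, source_vertex: int) -> VertexMetricMap:
    """Edge-graph shortest-path (Dijkstra) distance from a source vertex (mm).

    Unreachable vertices (disconnected components) get +inf and are flagged.
    """
    if not 0 <= source_vertex < mesh.n_vertices:
        raise ValueError("source vertex out of range")
    d = dijkstra(mesh.geodesic_adjacency, directed=False, indices=source_vertex)
    valid = np.isfinite(d)
    return VertexMetricMap(values=d, name="geodesic", units="mm", valid=valid)


# ---------------------------------------------------------------------------
# per-point laminar coordinates (used by the synthetic generator and lesions)


@dataclass
class RibbonGeometry:
    """Laminar coordinates of every voxel center of a grid.

    ``fraction``: equivolume volume fraction in [0, 1] inside the ribbon;
    negative values are the (negative) distance fraction below the white
    surface in thickness units; +inf outside the pial surface.
    ``depth_mm``: signed distance along the trajectory, negative below white.
    ``nearest_vertex``: owning vertex trajectory per voxel.
    """

    fraction: np.ndarray
    depth_mm: np.ndarray
    nearest_vertex: np.ndarray
    shape: tuple
    affine: np.ndarray


def point_trajectory_coords(
    white: CorticalMesh,
    pial: CorticalMesh,
    points: np.ndarray,
    k_candidates: int = 6,
):
    """Attribute world points to white-to-pial vertex trajectories.

    Each point is assigned the segment minimizing point-to-segment
    distance among ``k_candidates`` nearest candidates (segment-midpoint
    KD-tree).  Returns ``(t, depth_mm, vertex)``: the normalized position
    along the segment (may fall outside [0, 1]), the signed distance in
    millimetres, and the owning vertex.
    """
    pts = np.asarray(points, dtype=float)
    w = white.vertices
    d = pial.vertices - w
    seg_len2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-300)
    mid = w + 0.5 * d
    tree = cKDTree(mid)
    k = min(k_candidates, len(mid))
    _, cand = tree.query(pts, k=k)
    if k == 1:
        cand = cand[:, None]

    best_dist = np.full(len(pts), np.inf)
    best_t = np.zeros(len(pts))
    best_v = np.zeros(len(pts), dtype=np.int64)
    for c in range(k):
        vi = cand[:, c]
        rel = pts - w[vi]
        t = np.einsum("ij,ij->i", rel, d[vi]) / seg_len2[vi]
        proj = w[vi] + np.clip(t, 0.0, 1.0)[:, None] * d[vi]
        dist = np.linalg.norm(pts - proj, axis=1)
        better = dist < best_dist
        best_dist[better] = dist[better]
        best_t[better] = t[better]
        best_v[better] = vi[better]
    thick = np.sqrt(seg_len2)[best_v]
    return best_t, best_t * thick, best_v


def ribbon_geometry(
    white: CorticalMesh,
    pial: CorticalMesh,
    shape: tuple,
    affine: np.ndarray,
    k_candidates: int = 6,
) -> RibbonGeometry:
    """Assign each voxel center of a grid its equivolume laminar coordinate.

    Voxels are attributed to trajectories by nearest-segment projection
    (:func:`point_trajectory_coords`); the normalized position along the
    segment is converted from distance fraction to equivolume fraction.
    """
    vol = QVolume(np.zeros(shape), affine, "aux")
    ijk = np.indices(shape).reshape(3, -1).T
    pts = vol.voxel_to_world(ijk.astype(float))
    best_t, depth_mm, best_v = point_trajectory_coords(white, pial, pts, k_candidates)
    frac = np.empty(len(pts))
    inside = (best_t >= 0.0) & (best_t <= 1.0)
    a = np.sqrt(white.vertex_areas[best_v][inside])
    b = np.sqrt(pial.vertex_areas[best_v][inside])
    tt = best_t[inside]
    num = (a + (b - a) * tt) ** 3 - a**3
    den = b**3 - a**3
    with np.errstate(invalid="ignore", divide="ignore"):
        f_in = np.where(np.abs(den) < 1e-30, tt, num / den)
    frac[inside] = f_in
    frac[best_t < 0] = best_t[best_t < 0]  # thickness-normalized, negative
    frac[best_t > 1] = np.inf  # outside pial
    return RibbonGeometry(
        fraction=frac.reshape(shape),
        depth_mm=depth_mm.reshape(shape),
        nearest_vertex=best_v.reshape(shape),
        shape=tuple(shape),
        affine=np.asarray(affine, dtype=float),
    )
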