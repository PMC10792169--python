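"""Per-vertex discrete differential geometry of the triangulated membrane.

Curvature is estimated with an edge-dihedral shape operator: each one-ring
edge contributes its integrated curvature ``h_e = 2 |e| sin(alpha_e/2)``
(``alpha_e`` the signed dihedral between the adjacent face normals, positive
for convex folds) along the edge binormal direction, and the operator is
normalized by the mixed Voronoi vertex area.  Diagonalizing the operator in
the tangent plane yields the principal curvatures ``c1 >= c2`` and
orthonormal principal directions ``T1``, ``T2``.  A sphere meshed at
icosphere subdivision 3 reproduces ``c1 = c2 = 1/R`` to a few permille and
Gauss-Bonnet to better than 0.1%.

The barycentric vertex area ``A_v`` (one third of the incident triangle
areas, so that ``sum_v A_v`` equals the total surface area exactly) is the
area element used by every energy integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .mesh import Mesh


@dataclass
class VertexGeometry:
    """Geometry of a single vertex: area (l_dts^2), outward unit normal,
    principal curvatures (1/l_dts) with c1 >= c2 and principal directions."""

    area: float
    normal: np.ndarray
    c1: float
    c2: float
    t1: np.ndarray
    t2: np.ndarray

    @property
    def mean_curvature(self) -> float:
        return 0.5 * (self.c1 + self.c2)

    @property
    def gaussian_curvature(self) -> float:
        return self.c1 * self.c2


class SurfaceGeometry:
    """Geometry caches for a whole mesh (triangle and vertex level)."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        n, t = mesh.n_vertices, mesh.n_triangles
        self.tri_area = np.empty(t)
        self.tri_norm = np.empty((t, 3))
        self.tri_vol = np.empty(t)
        self.area = np.empty(n)      # barycentric A_v
        self.amix = np.empty(n)      # mixed Voronoi area (operator norm)
        self.normal = np.empty((n, 3))
        self.c1 = np.empty(n)
        self.c2 = np.empty(n)
        self.t1 = np.empty((n, 3))
        self.t2 = np.empty((n, 3))
        self.recompute()

    def recompute(self) -> None:
        m = self.mesh
        K.all_tris_update(m.pos, m.tris, m.box.lengths, m.box.periodic,
                          self.tri_area, self.tri_norm, self.tri_vol)
        K.all_geometry(m.pos, m.neigh, m.deg, m.vtris, m.tris,
                       m.box.lengths, m.box.periodic,
                       self.tri_area, self.tri_norm,
                       self.area, self.amix, self.normal,
                       self.c1, self.c2, self.t1, self.t2)

    def refresh_vertices(self, verts) -> None:
        m = self.mesh
        for v in np.asarray(verts, dtype=np.int64):
            K.vertex_geometry(int(v), m.pos, m.neigh, m.deg, m.vtris, m.tris,
                              m.box.lengths, m.box.periodic,
                              self.tri_area, self.tri_norm,
                              self.area, self.amix, self.normal,
                              self.c1, self.c2, self.t1, self.t2)

    @property
    def mean_curvature(self) -> np.ndarray:
        """H_v = (c1 + c2) / 2."""
        return 0.5 * (self.c1 + self.c2)

    @property
    def gaussian_curvature(self) -> np.ndarray:
        return self.c1 * self.c2

    @property
    def total_area(self) -> float:
        return float(self.tri_area.sum())

    @property
    def total_mean_curvature(self) -> float:
        """M = sum_v 2 H_v A_v, the integrated mean curvature."""
        return float(((self.c1 + self.c2) * self.area).sum())

    def vertex(self, v: int) -> VertexGeometry:
        return VertexGeometry(float(self.area[v]), self.normal[v].copy(),
                              float(self.c1[v]), float(self.c2[v]),
                              self.t1[v].copy(), self.t2[v].copy())


def compute_vertex_geometry(mesh: Mesh, v: int,
                            geom: SurfaceGeometry | None = None) -> VertexGeometry:
    """Geometry of one vertex; builds (or refreshes) caches as needed."""
    if geom is None:
        geom = SurfaceGeometry(mesh)
    else:
        geom.refresh_vertices([v])
    return geom.vertex(v)


def refresh_region(mesh: Mesh, geom: SurfaceGeometry, moved) -> np.ndarray:
    """Recompute exactly the vertices whose geometry depends on the moved
    vertices: the moved set plus its one-rings.  Triangle caches of the
    incident triangles are refreshed first.  Returns the refreshed ids."""
    moved = np.atleast_1d(np.asarray(moved, dtype=np.int64))
    if moved.size == 0:
        return moved
    region: set[int] = set()
    tris: set[int] = set()
    for v in moved:
        v = int(v)
        region.add(v)
        d = int(mesh.deg[v])
        region.update(int(u) for u in mesh.neigh[v, :d])
        tris.update(int(t) for t in mesh.vtris[v, :d])
    for t in tris:
        K.tri_update(t, mesh.pos, mesh.tris, mesh.box.lengths,
                     mesh.box.periodic, geom.tri_area, geom.tri_norm,
                     geom.tri_vol)
    out = np.array(sorted(region), dtype=np.int64)
    geom.refresh_vertices(out)
    return out


def euler_directional_curvatures(c1, c2, theta):
    """Directional curvatures along and across an in-plane direction at
    angle ``theta`` from the first principal direction (Euler's formula):

    C_par  = c1 cos^2(theta) + c2 sin^2(theta)
    C_perp = c1 sin^2(theta) + c2 cos^2(theta)
    """
    ct2 = np.cos(theta) ** 2
    st2 = np.sin(theta) ** 2
    return c1 * ct2 + c2 * st2, c1 * st2 + c2 * ct2


def parallel_transport(mesh: Mesh, geom: SurfaceGeometry,
                       v_from: int, v_to: int, vec: np.ndarray) -> np.ndarray:
    """Discrete parallel transport of a tangent vector along one edge.

    The connecting edge is projected into the tangent plane at either end;
    the transported vector keeps its signed angle with (and its component
    along) that projected direction, so norms are preserved exactly.
    """
    d = int(mesh.deg[v_from])
    if v_to not in mesh.neigh[v_from, :d]:
        raise ValueError("parallel_transport requires adjacent vertices")
    r = mesh.min_image(mesh.pos[v_to] - mesh.pos[v_from])
    n_f = geom.normal[v_from]
    n_t = geom.normal[v_to]
    p_f = r - (r @ n_f) * n_f
    p_t = r - (r @ n_t) * n_t
    if np.linalg.norm(p_f) < 1e-12 or np.linalg.norm(p_t) < 1e-12:
        raise ValueError("edge is parallel to a vertex normal")
    p_f = p_f / np.linalg.norm(p_f)
    p_t = p_t / np.linalg.norm(p_t)
    a = float(vec @ p_f)
    b = float(vec @ np.cross(n_f, p_f))
    c = float(vec @ n_f)  # normal component carried over unchanged
    return a * p_t + b * np.cross(n_t, p_t) + c * n_t


def pair_angles(mesh: Mesh, geom: SurfaceGeometry,
                host_i: int, dir_i: np.ndarray,
                host_j: int, dir_j: np.ndarray) -> tuple[float, float]:
    """(Theta, gamma) between two oriented inclusions on adjacent vertices.

    Theta = Theta_2 - Theta_1 where Theta_k is the signed angle from the
    in-plane projection of the connecting line to the inclusion direction.
    gamma is the angle between the two vertex normals, positive when the
    tips of the unit normals placed at the vertices are farther apart than
    the edge length (ridge) and negative otherwise (valley).
    """
    d = int(mesh.deg[host_i])
    if host_j not in mesh.neigh[host_i, :d]:
        raise ValueError("pair_angles requires adjacent host vertices")
    r = mesh.min_image(mesh.pos[host_j] - mesh.pos[host_i])
    n_i = geom.normal[host_i]
    n_j = geom.normal[host_j]
    p_i = r - (r @ n_i) * n_i
    p_j = r - (r @ n_j) * n_j
    p_i = p_i / np.linalg.norm(p_i)
    p_j = p_j / np.linalg.norm(p_j)
    th1 = np.arctan2(dir_i @ np.cross(n_i, p_i), dir_i @ p_i)
    th2 = np.arctan2(dir_j @ np.cross(n_j, p_j), dir_j @ p_j)
    cg = float(np.clip(n_i @ n_j, -1.0, 1.0))
    tip2 = float(((r + n_j - n_i) ** 2).sum())
    base2 = float((r ** 2).sum())
    sign = 1.0 if tip2 >= base2 else -1.0
    return float(th2 - th1), sign * float(np.arccos(cg))
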