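"""Triangulated-surface data structure, generators and topology operations.

A membrane is represented as a closed, orientable triangle mesh.  Each vertex
stands for a patch of membrane containing on the order of hundreds of lipids;
the simulation length unit ``l_dts`` is the minimum allowed vertex-vertex
distance.  Connectivity is stored in flat arrays (struct-of-arrays) so the
Monte Carlo kernels can operate on it without boxing:

* ``pos``   -- (N, 3) float64 vertex positions, kept unwrapped; all distances
  use minimum-image displacements on periodic axes.
* ``neigh`` -- (N, MAXD) ordered one-ring of each vertex, counter-clockwise
  when viewed from the outward normal; padded with -1.
* ``vtris`` -- (N, MAXD) incident triangles aligned with the ring:
  ``vtris[v, i]`` is the triangle (v, neigh[v, i], neigh[v, i+1]).
* ``vedge`` -- (N, MAXD) edge ids aligned with the ring.
* ``tris``  -- (T, 3) vertex ids in consistent winding (outward normals).
* ``edges`` -- (E, 2) canonical (min id, max id) endpoints.
* ``etris`` -- (E, 2) the two incident triangles of each edge.

The number of vertices, edges and triangles is constant for the lifetime of a
mesh; only connectivity (through link flips) and positions change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: one-ring capacity; the hard-core + edge-window constraints keep physical
#: degrees well below this.
MAXD = 20

SQRT3 = math.sqrt(3.0)


@dataclass
class Box:
    """Simulation frame: edge lengths (l_dts) and per-axis periodic flags.

    For framed (flat) membranes x and y are periodic and ``Lx * Ly`` is the
    projected area A_p, the degree of freedom of the box move.  Closed
    surfaces ignore periodicity; the box is then only an envelope used for
    spatial hashing.
    """

    lengths: np.ndarray
    periodic: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        self.periodic = np.asarray(self.periodic, dtype=np.bool_)
        if self.lengths.shape != (3,) or self.periodic.shape != (3,):
            raise ValueError("Box needs 3 lengths and 3 periodic flags")
        if not np.all(self.lengths > 0):
            raise ValueError("box lengths must be positive")

    @property
    def projected_area(self) -> float:
        return float(self.lengths[0] * self.lengths[1])

    def copy(self) -> "Box":
        return Box(self.lengths.copy(), self.periodic.copy())


@dataclass
class ValidityReport:
    ok: bool
    n_vertices: int
    n_edges: int
    n_triangles: int
    euler_characteristic: int
    genus: int
    edge_manifold: bool
    orientation_consistent: bool
    rings_closed: bool
    min_degree_ok: bool
    edge_window_violations: int
    dihedral_violations: int
    messages: list = field(default_factory=list)


class Mesh:
    """A closed orientable triangulated surface with cached connectivity."""

    def __init__(self, pos: np.ndarray, tris: np.ndarray, box: Box,
                 domain: np.ndarray | None = None):
        self.pos = np.ascontiguousarray(pos, dtype=np.float64)
        self.tris = np.ascontiguousarray(tris, dtype=np.int32)
        self.box = box
        n = len(self.pos)
        self.domain = (np.zeros(n, dtype=np.int32) if domain is None
                       else np.asarray(domain, dtype=np.int32).copy())
        if self.pos.ndim != 2 or self.pos.shape[1] != 3:
            raise ValueError("pos must be (N, 3)")
        if self.tris.ndim != 2 or self.tris.shape[1] != 3:
            raise ValueError("tris must be (T, 3)")
        self._build_connectivity()

    # -- basic counts -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.pos)

    @property
    def n_triangles(self) -> int:
        return len(self.tris)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_triangles

    @property
    def genus(self) -> int:
        """Genus derived from the Euler characteristic (single source of truth)."""
        return 1 - self.euler_characteristic // 2

    @property
    def closed_in_3d(self) -> bool:
        """True when no edge relies on periodic wrapping (vesicle, torus)."""
        return bool(self._closed3d)

    # -- connectivity -----------------------------------------------------

    def _build_connectivity(self) -> None:
        n, t = self.n_vertices, self.n_triangles
        edge_map: dict[tuple[int, int], int] = {}
        etris_l: list[list[int]] = []
        directed: set[tuple[int, int]] = set()
        for ti, (a, b, c) in enumerate(self.tris):
            for u, w in ((a, b), (b, c), (c, a)):
                u, w = int(u), int(w)
                if u == w:
                    raise ValueError(f"degenerate triangle {ti}")
                if (u, w) in directed:
                    raise ValueError(
                        f"inconsistent winding: directed edge ({u},{w}) repeated")
                directed.add((u, w))
                key = (u, w) if u < w else (w, u)
                ei = edge_map.get(key)
                if ei is None:
                    edge_map[key] = len(etris_l)
                    etris_l.append([ti])
                else:
                    etris_l[ei].append(ti)
        for key, ts in zip(edge_map, etris_l):
            if len(ts) != 2:
                raise ValueError(f"edge {key} has {len(ts)} incident triangles; "
                                 "mesh must be closed")
        self.edges = np.array(sorted(edge_map, key=edge_map.get),
                              dtype=np.int32).reshape(-1, 2)
        self.etris = np.array(etris_l, dtype=np.int32)

        # ordered rings: triangle (v, p, q) cyclic => ring successor p -> q
        succ: list[dict[int, tuple[int, int]]] = [dict() for _ in range(n)]
        for ti, tri in enumerate(self.tris):
            for k in range(3):
                v, p, q = int(tri[k]), int(tri[(k + 1) % 3]), int(tri[(k + 2) % 3])
                succ[v][p] = (q, ti)
        self.neigh = np.full((n, MAXD), -1, dtype=np.int32)
        self.vtris = np.full((n, MAXD), -1, dtype=np.int32)
        self.vedge = np.full((n, MAXD), -1, dtype=np.int32)
        self.deg = np.zeros(n, dtype=np.int32)
        for v in range(n):
            ring = succ[v]
            d = len(ring)
            if d < 3:
                raise ValueError(f"vertex {v} has degree {d} < 3")
            if d > MAXD:
                raise ValueError(f"vertex {v} degree {d} exceeds capacity {MAXD}")
            start = next(iter(ring))
            u, cnt = start, 0
            while True:
                q, ti = ring[u]
                self.neigh[v, cnt] = u
                self.vtris[v, cnt] = ti
                self.vedge[v, cnt] = edge_map[(v, u) if v < u else (u, v)]
                cnt += 1
                u = q
                if u == start:
                    break
                if cnt > d:
                    raise ValueError(f"vertex {v}: one-ring is not a single cycle")
            if cnt != d:
                raise ValueError(f"vertex {v}: one-ring is not a single cycle")
            self.deg[v] = d

        self._closed3d = not any(
            self._edge_wraps(int(e[0]), int(e[1])) for e in self.edges
        ) if self.box.periodic.any() else True

    def _edge_wraps(self, u: int, w: int) -> bool:
        d = self.pos[w] - self.pos[u]
        dmi = self.min_image(d)
        return not np.allclose(d, dmi)

    # -- geometry helpers --------------------------------------------------

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied on periodic axes (vectorized)."""
        d = np.array(d, dtype=np.float64, copy=True)
        L = self.box.lengths
        for ax in range(3):
            if self.box.periodic[ax]:
                d[..., ax] -= L[ax] * np.round(d[..., ax] / L[ax])
        return d

    def edge_vectors(self) -> np.ndarray:
        return self.min_image(self.pos[self.edges[:, 1]] - self.pos[self.edges[:, 0]])

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def triangle_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        p0 = self.pos[self.tris[:, 0]]
        e1 = self.min_image(self.pos[self.tris[:, 1]] - p0)
        e2 = self.min_image(self.pos[self.tris[:, 2]] - p0)
        cr = np.cross(e1, e2)
        a2 = np.linalg.norm(cr, axis=1)
        if np.any(a2 <= 0):
            raise ValueError("zero-area triangle")
        return cr / a2[:, None], a2 / 2.0

    def edge_dihedral_cos(self) -> np.ndarray:
        """cos of the angle between the two face normals of every edge."""
        nrm, _ = self.triangle_normals_areas()
        return np.einsum("ij,ij->i", nrm[self.etris[:, 0]], nrm[self.etris[:, 1]])

    def copy(self) -> "Mesh":
        m = object.__new__(Mesh)
        m.pos = self.pos.copy()
        m.tris = self.tris.copy()
        m.box = self.box.copy()
        m.domain = self.domain.copy()
        for name in ("edges", "etris", "neigh", "vtris", "vedge", "deg"):
            setattr(m, name, getattr(self, name).copy())
        m._closed3d = self._closed3d
        return m

    def canonicalize(self) -> None:
        """Rebuild edge numbering and ring order deterministically from the
        triangle list (the labeling a freshly loaded mesh would carry).
        Link flips permute these labels in place; canonicalizing before a
        checkpoint makes a file-restarted run bit-identical to the
        uninterrupted one."""
        self._build_connectivity()

    # -- topology: the Alexander link flip ---------------------------------

    def flip_edge(self, edge_id: int) -> None:
        """Replace edge (a,b) by the opposite diagonal (c,d) of its quad.

        Purely topological: cached quantities held elsewhere must be refreshed
        by the caller.  Whether the flip is *energetically* or *geometrically*
        admissible (edge window, dihedral bound) is the sampler's business.

        Raises ``ValueError`` if the flip would create a duplicate edge or
        drop an endpoint below degree 3.
        """
        from . import _kernels as K

        ok = K.topo_flip(int(edge_id), self.tris, self.neigh, self.deg,
                         self.vtris, self.vedge, self.edges, self.etris)
        if ok == -1:
            raise ValueError("flip would drop a vertex below degree 3 "
                             "or overflow ring capacity")
        if ok == -2:
            raise ValueError("flip would duplicate an existing edge")

    # -- validation --------------------------------------------------------

    def validate(self, l_min: float = 1.0, l_max: float = SQRT3,
                 min_dihedral_cos: float = 0.0) -> ValidityReport:
        msgs: list[str] = []
        edge_manifold = orientation = rings = True
        try:
            tmp = Mesh(self.pos, self.tris, self.box)
            rings = True
            same = (np.array_equal(np.sort(tmp.edges, axis=1),
                                   np.sort(self.edges, axis=1)))
            if not same:
                msgs.append("edge table out of sync with triangles")
        except ValueError as exc:
            msg = str(exc)
            msgs.append(msg)
            if "incident triangles" in msg:
                edge_manifold = False
            elif "winding" in msg:
                orientation = False
            else:
                rings = False
        lens = self.edge_lengths()
        ewv = int(np.sum((lens < l_min - 1e-12) | (lens > l_max + 1e-12)))
        dhv = int(np.sum(self.edge_dihedral_cos() < min_dihedral_cos - 1e-12))
        min_deg_ok = bool(np.all(self.deg >= 3))
        chi = self.euler_characteristic
        ok = edge_manifold and orientation and rings and min_deg_ok
        return ValidityReport(
            ok=ok, n_vertices=self.n_vertices, n_edges=self.n_edges,
            n_triangles=self.n_triangles, euler_characteristic=chi,
            genus=1 - chi // 2, edge_manifold=edge_manifold,
            orientation_consistent=orientation, rings_closed=rings,
            min_degree_ok=min_deg_ok, edge_window_violations=ewv,
            dihedral_violations=dhv, messages=msgs)


# -- generators -------------------------------------------------------------


def _brick_faces(n1: int, n2: int) -> np.ndarray:
    """Faces of a periodic 'brick' grid: rows offset by half a step, giving a
    near-equilateral triangulation once positions carry the offset."""
    def vid(i: int, j: int) -> int:
        return (j % n2) * n1 + (i % n1)

    faces = []
    for j in range(n2):
        for i in range(n1):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i, j + 1), vid(i + 1, j + 1)
            if j % 2 == 0:
                faces += [[a, b, c], [b, d, c]]
            else:
                faces += [[a, b, d], [a, d, c]]
    return np.array(faces, dtype=np.int32)


def _check_window(mesh: Mesh, l_min: float, l_max: float, what: str) -> None:
    lens = mesh.edge_lengths()
    if lens.min() < l_min - 1e-9 or lens.max() > l_max + 1e-9:
        raise ValueError(
            f"{what}: edge lengths [{lens.min():.3f}, {lens.max():.3f}] violate "
            f"the window [{l_min:.3f}, {l_max:.3f}]")


def build_flat_grid(nx: int, ny: int, spacing: float = 1.2,
                    lz: float | None = None,
                    l_min: float = 1.0, l_max: float = SQRT3) -> Mesh:
    """Flat periodic sheet in the xy-plane (torus topology under PBC).

    Each unit cell is split into two triangles; rows are offset by half a
    spacing so triangles are equilateral.  ``ny`` must be even so the offset
    pattern closes under the periodic wrap.
    """
    if nx < 3 or ny < 3:
        raise ValueError("nx and ny must be >= 3")
    if ny % 2:
        raise ValueError("ny must be even for the periodic row offset to close")
    h = spacing * SQRT3 / 2.0
    lzv = float(lz) if lz is not None else max(nx * spacing, ny * h)
    box = Box(np.array([nx * spacing, ny * h, lzv]),
              np.array([True, True, False]))
    pos = np.empty((nx * ny, 3))
    for j in range(ny):
        for i in range(nx):
            pos[j * nx + i] = ((i + 0.5 * (j % 2)) * spacing, j * h, lzv / 2.0)
    mesh = Mesh(pos, _brick_faces(nx, ny), box)
    _check_window(mesh, l_min, l_max, "flat grid")
    return mesh


def build_icosphere(subdivisions: int, radius: float | None = None,
                    l_min: float = 1.0, l_max: float = SQRT3,
                    check_window: bool = True) -> Mesh:
    """Closed genus-0 vesicle mesh with outward normals.

    With ``radius=None`` the sphere is scaled so the shortest edge sits
    comfortably above ``l_min`` (at 1.15 l_dts), leaving room for the edge
    window on both sides during sampling.
    """
    import trimesh

    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    pos = np.asarray(tm.vertices, dtype=np.float64)
    tris = np.asarray(tm.faces, dtype=np.int32)
    emin = _min_edge(pos, tris)
    r = 1.15 * l_min / emin if radius is None else float(radius)
    pos = pos * r
    side = 4.0 * r + 8.0
    box = Box(np.array([side, side, side]), np.array([False, False, False]))
    pos += side / 2.0
    mesh = Mesh(pos, tris, box)
    if check_window:
        _check_window(mesh, l_min, l_max, "icosphere")
    return mesh


def _min_edge(pos: np.ndarray, tris: np.ndarray) -> float:
    seen = set()
    m = np.inf
    for a, b, c in tris:
        for u, w in ((a, b), (b, c), (c, a)):
            key = (min(u, w), max(u, w))
            if key not in seen:
                seen.add(key)
                m = min(m, float(np.linalg.norm(pos[u] - pos[w])))
    return m


def build_tube(n_axial: int, n_circ: int, radius: float | None = None,
               length: float | None = None,
               l_min: float = 1.0, l_max: float = SQRT3) -> Mesh:
    """Cylinder periodic along its (z) axis; chi = 0.

    Defaults pick the radius from ``n_circ`` at a circumferential spacing of
    1.2 l_dts and a row height keeping triangles equilateral.
    """
    if n_axial < 3 or n_circ < 3:
        raise ValueError("n_axial and n_circ must be >= 3")
    if n_axial % 2:
        raise ValueError("n_axial must be even for the periodic row offset")
    s = 1.2 if radius is None else 2.0 * math.pi * radius / n_circ
    r = n_circ * s / (2.0 * math.pi)
    h = (length / n_axial) if length is not None else s * SQRT3 / 2.0
    side = 4.0 * r + 8.0
    box = Box(np.array([side, side, n_axial * h]),
              np.array([False, False, True]))
    pos = np.empty((n_circ * n_axial, 3))
    for j in range(n_axial):
        for i in range(n_circ):
            phi = (i + 0.5 * (j % 2)) * 2.0 * math.pi / n_circ
            pos[j * n_circ + i] = (side / 2 + r * math.cos(phi),
                                   side / 2 + r * math.sin(phi), j * h)
    mesh = Mesh(pos, _brick_faces(n_circ, n_axial), box)
    _check_window(mesh, l_min, l_max, "tube")
    return mesh


def build_torus(n_major: int, n_minor: int, r_major: float, r_minor: float,
                check_window: bool = False,
                l_min: float = 1.0, l_max: float = SQRT3) -> Mesh:
    """Closed genus-1 surface of revolution; chi = 0, outward normals."""
    if r_minor >= r_major:
        raise ValueError("r_minor must be smaller than r_major")
    if n_major < 3 or n_minor < 3:
        raise ValueError("n_major and n_minor must be >= 3")
    if n_minor % 2:
        raise ValueError("n_minor must be even for the brick offset")
    side = 2.5 * (r_major + r_minor) + 8.0
    box = Box(np.array([side, side, side]), np.array([False, False, False]))
    pos = np.empty((n_major * n_minor, 3))
    for j in range(n_minor):
        th = 2.0 * math.pi * j / n_minor
        for i in range(n_major):
            ph = 2.0 * math.pi * (i + 0.5 * (j % 2)) / n_major
            rr = r_major + r_minor * math.cos(th)
            pos[j * n_major + i] = (side / 2 + rr * math.cos(ph),
                                    side / 2 + rr * math.sin(ph),
                                    side / 2 + r_minor * math.sin(th))
    mesh = Mesh(pos, _brick_faces(n_major, n_minor), box)
    if check_window:
        _check_window(mesh, l_min, l_max, "torus")
    return mesh


def validate(mesh: Mesh, l_min: float = 1.0, l_max: float = SQRT3,
             min_dihedral_cos: float = 0.0) -> ValidityReport:
    """Module-level alias of :meth:`Mesh.validate`."""
    return mesh.validate(l_min, l_max, min_dihedral_cos)
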