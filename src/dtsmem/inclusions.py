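"""Vertex-bound protein inclusions and their energies.

A protein is an in-plane inclusion living on a single vertex with a unit
tangent orientation D.  At most one inclusion per vertex — excluded volume
in the membrane plane falls out of the occupancy rule.  Two membrane
coupling classes exist:

* type 1 (isotropic, e.g. Shiga/cholera toxin-like):
      e = [ 2 dk H^2 - 2 (dk + kappa) c0 H - dkg K ] A_v
  dk and dkg act as local increments of the bending rigidity and Gaussian
  modulus, c0 as a locally imprinted curvature.

* type 2 (anisotropic, e.g. BAR-domain-like):
      e = [ k1/2 (C_par - C_par0)^2 + k2/2 (C_perp - C_perp0)^2 ] A_v
  with C_par/C_perp the directional curvatures along/across D from Euler's
  formula.  The energy is invariant under D -> -D (nematic symmetry).

Inclusions on edge-adjacent vertices additionally interact through a
lowest-order Fourier pair potential

      e(Theta, gamma) = -A_ij - B_ij cos[n (Theta - Theta_0)]
                              - C_ij cos(gamma - gamma_0)

where Theta is the in-plane angle mismatch measured against the projected
connector (parallel-transport consistent) and gamma the signed normal-normal
angle.  n is the least common multiple of the two proteins' in-plane
symmetry degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import SurfaceGeometry, VertexGeometry, pair_angles
from .mesh import Mesh


@dataclass
class InclusionType:
    """Parameter set of one protein species (exactly one class active)."""

    name: str
    kind: int  # 1 isotropic, 2 anisotropic
    # type 1
    dkappa: float = 0.0
    dkappa_g: float = 0.0
    c0: float = 0.0
    # type 2
    k1: float = 0.0
    k2: float = 0.0
    c_par0: float = 0.0
    c_perp0: float = 0.0
    #: in-plane symmetry degree (2 for nematic rods); feeds the pair n
    symmetry: int = 2

    def __post_init__(self) -> None:
        if self.kind not in (1, 2):
            raise ValueError("kind must be 1 or 2")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1, k2 must be non-negative")
        if self.kind == 1 and (self.k1 or self.k2 or self.c_par0 or self.c_perp0):
            raise ValueError("type-1 inclusion carries type-2 parameters")
        if self.kind == 2 and (self.dkappa or self.dkappa_g or self.c0):
            raise ValueError("type-2 inclusion carries type-1 parameters")


@dataclass
class PairPotential:
    """Interaction coefficients for one (unordered) pair of species."""

    type_i: str
    type_j: str
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    n: int | None = None      # default: lcm of the species' symmetries
    theta0: float = 0.0
    gamma0: float = 0.0


@dataclass
class Inclusion:
    """One protein: species, host vertex and in-plane unit orientation."""

    type_name: str
    vertex: int
    direction: np.ndarray


class InclusionField:
    """All inclusions of a state in kernel-ready flat arrays."""

    def __init__(self, mesh: Mesh, types: list[InclusionType] | None = None,
                 pair_potentials: list[PairPotential] | None = None):
        self.mesh = mesh
        self.types = list(types) if types else []
        self._tindex = {t.name: i for i, t in enumerate(self.types)}
        if len(self._tindex) != len(self.types):
            raise ValueError("duplicate inclusion type names")
        nt = max(1, len(self.types))
        self.tp_kind = np.ones(nt, dtype=np.int32)
        self.tp_par = np.zeros((nt, 4))
        for i, t in enumerate(self.types):
            self.tp_kind[i] = t.kind
            if t.kind == 1:
                self.tp_par[i, :3] = (t.dkappa, t.dkappa_g, t.c0)
            else:
                self.tp_par[i] = (t.k1, t.k2, t.c_par0, t.c_perp0)
        self.pp_a = np.zeros((nt, nt))
        self.pp_b = np.zeros((nt, nt))
        self.pp_c = np.zeros((nt, nt))
        self.pp_n = np.ones((nt, nt))
        self.pp_th0 = np.zeros((nt, nt))
        self.pp_g0 = np.zeros((nt, nt))
        for pp in (pair_potentials or []):
            i = self._tindex[pp.type_i]
            j = self._tindex[pp.type_j]
            n = pp.n if pp.n is not None else math.lcm(
                self.types[i].symmetry, self.types[j].symmetry)
            if n < 1:
                raise ValueError("pair symmetry order n must be >= 1")
            for a, b in ((i, j), (j, i)):
                self.pp_a[a, b] = pp.a
                self.pp_b[a, b] = pp.b
                self.pp_c[a, b] = pp.c
                self.pp_n[a, b] = float(n)
                self.pp_th0[a, b] = pp.theta0
                self.pp_g0[a, b] = pp.gamma0
        self.host = np.empty(0, dtype=np.int32)        # inclusion -> vertex
        self.type_id = np.empty(0, dtype=np.int32)
        self.dir = np.empty((0, 3))
        self.host_inc = np.full(mesh.n_vertices, -1, dtype=np.int32)

    @property
    def n_inclusions(self) -> int:
        return len(self.host)

    def type_index(self, name: str) -> int:
        return self._tindex[name]

    def add(self, type_name: str, vertex: int,
            direction: np.ndarray | None = None,
            geom: SurfaceGeometry | None = None,
            angle: float | None = None) -> int:
        """Place one inclusion; direction defaults to T1 rotated by ``angle``
        (requires ``geom``) or to T1 itself."""
        if self.host_inc[vertex] >= 0:
            raise ValueError(f"vertex {vertex} already hosts an inclusion")
        if direction is None:
            if geom is None:
                raise ValueError("need geom or an explicit direction")
            ang = 0.0 if angle is None else float(angle)
            direction = (math.cos(ang) * geom.t1[vertex]
                         + math.sin(ang) * geom.t2[vertex])
        direction = np.asarray(direction, dtype=np.float64)
        nrm = float(np.linalg.norm(direction))
        if abs(nrm - 1.0) > 1e-12:  # keep already-unit vectors bit-stable
            direction = direction / nrm
        j = self.n_inclusions
        self.host = np.append(self.host, np.int32(vertex))
        self.type_id = np.append(self.type_id,
                                 np.int32(self.type_index(type_name)))
        self.dir = np.vstack([self.dir, direction[None, :]])
        self.host_inc[vertex] = j
        return j

    def place_random(self, type_name: str, coverage: float,
                     geom: SurfaceGeometry, rng: np.random.Generator) -> int:
        """Seeded uniform placement on unoccupied vertices at the requested
        coverage fraction (count = round(coverage * N_v), documented)."""
        if not 0.0 <= coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        count = int(round(coverage * self.mesh.n_vertices))
        free = np.flatnonzero(self.host_inc < 0)
        if count > len(free):
            raise ValueError("not enough unoccupied vertices")
        chosen = rng.choice(free, size=count, replace=False)
        for v in chosen:
            self.add(type_name, int(v), geom=geom,
                     angle=float(rng.uniform(0.0, 2.0 * math.pi)))
        return count

    def angles(self, geom: SurfaceGeometry) -> np.ndarray:
        """Orientation angle of every inclusion relative to T1 at its host."""
        out = np.empty(self.n_inclusions)
        for j in range(self.n_inclusions):
            v = self.host[j]
            out[j] = math.atan2(float(self.dir[j] @ geom.t2[v]),
                                float(self.dir[j] @ geom.t1[v]))
        return out


# -- energies ---------------------------------------------------------------


def type1_site_energy(geom_v: VertexGeometry, params: InclusionType,
                      kappa: float) -> float:
    """Isotropic membrane-inclusion energy at one vertex."""
    h = geom_v.mean_curvature
    k = geom_v.gaussian_curvature
    return (2.0 * params.dkappa * h * h
            - 2.0 * (params.dkappa + kappa) * params.c0 * h
            - params.dkappa_g * k) * geom_v.area


def type2_site_energy(geom_v: VertexGeometry, incl_dir: np.ndarray,
                      params: InclusionType) -> float:
    """Anisotropic membrane-inclusion energy at one vertex."""
    ct = float(incl_dir @ geom_v.t1)
    st = float(incl_dir @ geom_v.t2)
    cpar = geom_v.c1 * ct * ct + geom_v.c2 * st * st
    cperp = geom_v.c1 * st * st + geom_v.c2 * ct * ct
    return (0.5 * params.k1 * (cpar - params.c_par0) ** 2
            + 0.5 * params.k2 * (cperp - params.c_perp0) ** 2) * geom_v.area


def pair_energy(theta: float, gamma: float, a: float = 0.0, b: float = 0.0,
                c: float = 0.0, n: int = 1, theta0: float = 0.0,
                gamma0: float = 0.0) -> float:
    """Lowest-order Fourier pair interaction between adjacent inclusions."""
    return (-a - b * math.cos(n * (theta - theta0))
            - c * math.cos(gamma - gamma0))


def inclusion_field_energy(mesh: Mesh, geom: SurfaceGeometry,
                           field: InclusionField, kappa: float) -> float:
    """Sum of site energies plus each unique adjacent pair counted once."""
    e = 0.0
    for j in range(field.n_inclusions):
        v = int(field.host[j])
        t = field.types[field.type_id[j]]
        gv = geom.vertex(v)
        if t.kind == 1:
            e += type1_site_energy(gv, t, kappa)
        else:
            e += type2_site_energy(gv, field.dir[j], t)
    for j in range(field.n_inclusions):
        u = int(field.host[j])
        for ii in range(int(mesh.deg[u])):
            w = int(mesh.neigh[u, ii])
            jj = field.host_inc[w]
            if jj >= 0 and w > u:
                th, g = pair_angles(mesh, geom, u, field.dir[j],
                                    w, field.dir[jj])
                ti = field.type_id[j]
                tj = field.type_id[jj]
                e += pair_energy(th, g, field.pp_a[ti, tj],
                                 field.pp_b[ti, tj], field.pp_c[ti, tj],
                                 int(field.pp_n[ti, tj]),
                                 field.pp_th0[ti, tj], field.pp_g0[ti, tj])
    return e
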