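"""Membrane-level energy terms and system-level couplings (k_BT units).

All terms are written as full (vectorized) recomputations over the current
geometry; the Monte Carlo kernels carry their own incremental counterparts,
and the two must agree — that agreement is asserted in the test suite.

Terms
-----
bending (Helfrich)         E_b  = sum_v [ kappa/2 (2H_v - Cbar)^2 - kappa_G K_v ] A_v
area coupling              E_A  = N_T K_A/2 (A/A_0 - 1)^2
volume coupling            E_v  = -dP V + K/2 (V/V_0 - v_t)^2,  V_0 = A^(3/2) / (6 sqrt(pi))
osmotic (van 't Hoff)      dE   = -RT [ c_in V_ini ln(V/V_ini) - c_out (V - V_ini) ]
global curvature           E_s  = k_r/(2A) (M - m_0 A)^2,  M = sum_v 2 H_v A_v
frame tension              E_t  = -tau A_p = -tau Lx Ly

The Gaussian-curvature term is written with a minus sign so that a positive
Gaussian modulus lowers the energy of a sphere by 4 pi kappa_G; by
Gauss-Bonnet it is an invariant of the (fixed) topology up to discretization
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceGeometry
from .mesh import Box, Mesh


@dataclass
class MembraneParams:
    """Bending rigidity kappa (k_BT), Gaussian modulus kappa_G (k_BT) and
    spontaneous membrane curvature Cbar (1/l_dts)."""

    kappa: float = 20.0
    kappa_g: float = 0.0
    cbar: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class EnsembleCouplings:
    """System-level couplings; each term is enabled independently.

    tension:   frame tension tau (k_BT/l_dts^2), sampled by the box move.
    area:      (K_A, A_0) harmonic constraint on the total surface area.
    volume:    (dP, K, v_t) first/second-order coupling of enclosed volume.
    osmotic:   (RT, c_in, c_out, V_ini) van 't Hoff osmotic pressure; RT is
               the energy scale in k_BT and the reduced concentrations carry
               inverse-volume units so the products are energies.
    global_curvature: (k_r, m_0) harmonic coupling of the integrated mean
               curvature M (equivalently monolayer area difference).
    """

    tension_on: bool = False
    tau: float = 0.0
    area_on: bool = False
    k_a: float = 0.0
    a0: float = 1.0
    volume_on: bool = False
    dp: float = 0.0
    k_v: float = 0.0
    v_t: float = 1.0
    osmotic_on: bool = False
    rt: float = 0.0
    c_in: float = 0.0
    c_out: float = 0.0
    v_ini: float = 1.0
    global_curv_on: bool = False
    k_r: float = 0.0
    m0: float = 0.0

    def __post_init__(self) -> None:
        if self.area_on and self.a0 <= 0:
            raise ValueError("A_0 must be positive")
        if self.volume_on and not (0.0 < self.v_t <= 1.0):
            raise ValueError("v_t must lie in (0, 1]")
        if self.osmotic_on and self.v_ini <= 0:
            raise ValueError("V_ini must be positive")

    def pack(self) -> np.ndarray:
        """Flat float64 vector consumed by the MC kernels."""
        from . import _kernels as K

        e = np.zeros(K.ENS_LEN)
        e[K.ENS_TAU_ON] = 1.0 if self.tension_on else 0.0
        e[K.ENS_TAU] = self.tau
        e[K.ENS_KA_ON] = 1.0 if self.area_on else 0.0
        e[K.ENS_KA] = self.k_a
        e[K.ENS_A0] = self.a0
        e[K.ENS_V_ON] = 1.0 if self.volume_on else 0.0
        e[K.ENS_DP] = self.dp
        e[K.ENS_K] = self.k_v
        e[K.ENS_VT] = self.v_t
        e[K.ENS_OSM_ON] = 1.0 if self.osmotic_on else 0.0
        e[K.ENS_RT] = self.rt
        e[K.ENS_CIN] = self.c_in
        e[K.ENS_COUT] = self.c_out
        e[K.ENS_VINI] = self.v_ini
        e[K.ENS_GC_ON] = 1.0 if self.global_curv_on else 0.0
        e[K.ENS_KR] = self.k_r
        e[K.ENS_M0] = self.m0
        return e


def bending_energy(mesh: Mesh, geom: SurfaceGeometry, params: MembraneParams,
                   per_vertex: bool = False):
    """Discretized Helfrich bending energy."""
    h2 = geom.c1 + geom.c2
    kg = geom.c1 * geom.c2
    e = (0.5 * params.kappa * (h2 - params.cbar) ** 2
         - params.kappa_g * kg) * geom.area
    return e if per_vertex else float(e.sum())


def area_coupling_energy(mesh: Mesh, geom: SurfaceGeometry,
                         k_a: float, a0: float) -> float:
    if k_a < 0:
        raise ValueError("K_A must be non-negative")
    if a0 <= 0:
        raise ValueError("A_0 must be positive")
    a = geom.total_area
    return mesh.n_triangles * 0.5 * k_a * (a / a0 - 1.0) ** 2


def enclosed_volume(mesh: Mesh, geom: SurfaceGeometry | None = None) -> float:
    """Signed enclosed volume by the divergence theorem; positive for
    outward-oriented closed surfaces.  Rejects meshes that are only closed
    through the periodic box (no well-defined 3D interior)."""
    if not mesh.closed_in_3d:
        raise ValueError("enclosed volume requires a 3D-closed mesh")
    if geom is None:
        geom = SurfaceGeometry(mesh)
    return float(geom.tri_vol.sum())


def volume_coupling_energy(v: float, a: float, dp: float, k: float,
                           v_t: float) -> float:
    """-dP V + K/2 (V/V_0 - v_t)^2 with V_0 the volume of the sphere with
    the same area A."""
    e = -dp * v
    if k != 0.0:
        if a <= 0:
            raise ValueError("area must be positive when K != 0")
        v0 = a ** 1.5 / (6.0 * math.sqrt(math.pi))
        e += 0.5 * k * (v / v0 - v_t) ** 2
    return e


def osmotic_energy(v: float, rt: float, c_in: float, c_out: float,
                   v_ini: float) -> float:
    """van 't Hoff osmotic free energy relative to the initial volume."""
    if v <= 0 or v_ini <= 0:
        raise ValueError("volumes must be positive")
    return -rt * (c_in * v_ini * math.log(v / v_ini) - c_out * (v - v_ini))


def global_curvature_energy(mesh: Mesh, geom: SurfaceGeometry,
                            k_r: float, m0: float) -> float:
    a = geom.total_area
    if a <= 0:
        raise ValueError("total area must be positive")
    m = geom.total_mean_curvature
    return 0.5 * k_r / a * (m - m0 * a) ** 2


def frame_tension_energy(box: Box, tau: float) -> float:
    """E_tau = -tau A_p; requires a frame periodic in x and y."""
    if not (box.periodic[0] and box.periodic[1]):
        raise ValueError("frame tension requires x,y-periodic box")
    return -tau * box.projected_area


def coupling_energy(mesh: Mesh, geom: SurfaceGeometry,
                    coup: EnsembleCouplings) -> float:
    """Sum of the enabled system-level couplings."""
    e = 0.0
    if coup.tension_on:
        e += frame_tension_energy(mesh.box, coup.tau)
    if coup.area_on:
        e += area_coupling_energy(mesh, geom, coup.k_a, coup.a0)
    if coup.volume_on:
        e += volume_coupling_energy(enclosed_volume(mesh, geom),
                                    geom.total_area, coup.dp, coup.k_v,
                                    coup.v_t)
    if coup.osmotic_on:
        e += osmotic_energy(enclosed_volume(mesh, geom), coup.rt,
                            coup.c_in, coup.c_out, coup.v_ini)
    if coup.global_curv_on:
        e += global_curvature_energy(mesh, geom, coup.k_r, coup.m0)
    return e


def total_energy(state) -> float:
    """Full recomputation of the total energy of a simulation state
    (bending + inclusion terms + couplings + external force)."""
    from .inclusions import inclusion_field_energy

    geom = SurfaceGeometry(state.mesh)
    e = bending_energy(state.mesh, geom, state.membrane)
    e += inclusion_field_energy(state.mesh, geom, state.inclusions,
                                state.membrane.kappa)
    e += coupling_energy(state.mesh, geom, state.couplings)
    if state.force is not None and state.force.vertex >= 0:
        d = state.mesh.pos[state.force.vertex] - state.force.anchor
        e += 0.5 * state.force.k_spring * float(d @ d)
    return e
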