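"""Metropolis Monte Carlo engine for the triangulated membrane.

One sweep performs, on uniformly random targets, N_T Alexander link-flip
trials, N_v vertex-displacement trials and N_i inclusion trials (rotation or
hop with probability 1/2 each), plus at most one box-resize trial when the
constant-tension ensemble is active.  In frozen-shape mode only the
inclusion trials run, so a fixed (e.g. experimentally derived) mesh can be
decorated with equilibrated protein occupancy.

Hard constraints are enforced by outright rejection before any energy is
evaluated: edge lengths inside [l_min, l_max], a global minimum
vertex-vertex distance (the unit length l_dts, checked through a linked
cell list), a lower bound on the dihedral cosine between adjacent face
normals, and the optional spatial confinement.

Reproducibility: a single master seed; every sweep re-seeds the kernel RNG
with a value derived from (master seed, sweep index), so restarting from a
saved frame continues the exact uninterrupted trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels as K
from .energy import EnsembleCouplings, MembraneParams, total_energy
from .geometry import SurfaceGeometry
from .inclusions import InclusionField
from .mesh import Mesh

SQRT3 = math.sqrt(3.0)


@dataclass
class Constraints:
    """Hard-constraint system guaranteeing self-avoidance.

    l_min = l_dts and l_max = sqrt(3) l_dts together with a mild dihedral
    bound are sufficient for a self-avoiding surface; the minimum distance
    between *any* two vertices equals l_dts as well.
    """

    l_min: float = 1.0
    l_max: float = SQRT3
    d_min: float = 1.0
    min_dihedral_cos: float = 0.0

    def __post_init__(self) -> None:
        if self.l_min > self.l_max:
            raise ValueError("l_min must not exceed l_max")

    def pack(self) -> np.ndarray:
        c = np.zeros(4)
        c[K.CONS_LMIN] = self.l_min
        c[K.CONS_LMAX] = self.l_max
        c[K.CONS_DMIN] = self.d_min
        c[K.CONS_MINCOS] = self.min_dihedral_cos
        return c


@dataclass
class MoveParams:
    """Trial-move amplitudes (all > 0) and the box-trial probability."""

    delta: float = 0.1           # vertex displacement half-width (l_dts)
    rot_amp: float = math.pi / 4  # inclusion rotation half-width (rad)
    box_amp: float = 0.01        # relative in-plane rescale half-width
    p_box: float = 1.0           # box-trial probability per sweep

    def __post_init__(self) -> None:
        if min(self.delta, self.rot_amp, self.box_amp) <= 0:
            raise ValueError("move amplitudes must be positive")

    def pack(self) -> np.ndarray:
        m = np.zeros(4)
        m[K.MV_DELTA] = self.delta
        m[K.MV_ROT] = self.rot_amp
        m[K.MV_BOX] = self.box_amp
        m[K.MV_PBOX] = self.p_box
        return m


@dataclass
class Confinement:
    """Spatial confinement: none, slab (two sandwiching walls a distance H
    apart), ellipsoid, ellipsoidal shell or block."""

    kind: str = "none"
    center: tuple = (0.0, 0.0, 0.0)
    #: slab: (z0, H) wall midplane and spacing; ellipsoid/shell/block:
    #: semi-axes / half-extents; shell adds inner_fraction in (0, 1).
    z0: float = 0.0
    h: float = 0.0
    semi_axes: tuple = (1.0, 1.0, 1.0)
    inner_fraction: float = 0.0

    _KINDS = {"none": K.CONF_NONE, "slab": K.CONF_SLAB,
              "ellipsoid": K.CONF_ELLIPSOID, "shell": K.CONF_SHELL,
              "block": K.CONF_BLOCK}

    def pack(self) -> tuple[int, np.ndarray]:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown confinement kind {self.kind!r}")
        par = np.zeros(8)
        if self.kind == "slab":
            par[0] = self.z0
            par[1] = self.h
        elif self.kind != "none":
            par[0:3] = self.center
            par[3:6] = self.semi_axes
            par[6] = self.inner_fraction
        return self._KINDS[self.kind], par


@dataclass
class ExternalForce:
    """Harmonic anchor pulling one vertex (tether-pulling setup)."""

    vertex: int = -1
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))
    k_spring: float = 0.0

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=np.float64)
        if self.k_spring < 0:
            raise ValueError("spring constant must be non-negative")


@dataclass
class SweepStats:
    """Per-move-kind counters of one or more sweeps."""

    attempted: np.ndarray
    hard_rejected: np.ndarray
    accepted: np.ndarray

    @property
    def acceptance(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.accepted / np.maximum(self.attempted, 1)


def derive_sweep_seed(master_seed: int, sweep_index: int) -> int:
    """Deterministic per-sweep seed below 2^31 (splitmix-style hash)."""
    x = (master_seed * 0x9E3779B9 + sweep_index * 0xBF58476D + 0x94D049BB) \
        % (1 << 62)
    x ^= x >> 17
    x = (x * 0x85EBCA6B) % (1 << 62)
    x ^= x >> 13
    return int(x % (1 << 31))


class SimulationState:
    """A complete, runnable membrane Monte Carlo system."""

    def __init__(self, mesh: Mesh,
                 membrane: MembraneParams | None = None,
                 couplings: EnsembleCouplings | None = None,
                 inclusions: InclusionField | None = None,
                 constraints: Constraints | None = None,
                 moves: MoveParams | None = None,
                 confinement: Confinement | None = None,
                 force: ExternalForce | None = None,
                 frozen: bool = False,
                 seed: int = 1):
        self.mesh = mesh
        self.membrane = membrane or MembraneParams()
        self.couplings = couplings or EnsembleCouplings()
        self.inclusions = inclusions or InclusionField(mesh)
        self.constraints = constraints or Constraints()
        self.moves = moves or MoveParams()
        self.confinement = confinement or Confinement()
        self.force = force or ExternalForce()
        self.frozen = bool(frozen)
        self.seed = int(seed)
        self.sweep_index = 0
        self.resync_every = 1000

        if (self.couplings.volume_on or self.couplings.osmotic_on) \
                and not mesh.closed_in_3d:
            raise ValueError("volume couplings require a 3D-closed mesh")
        if self.couplings.tension_on and not (mesh.box.periodic[0]
                                              and mesh.box.periodic[1]):
            raise ValueError("frame tension requires an x,y-periodic box")

        self.geometry = SurfaceGeometry(mesh)
        self._evert = np.empty(mesh.n_vertices)
        self._tot = np.zeros(4)
        self._mark = np.zeros(mesh.n_vertices, dtype=np.int64)
        self._stamp = np.zeros(1, dtype=np.int64)
        self._pos_bak = np.empty_like(mesh.pos)

        self._ens = self.couplings.pack()
        self._mem = np.array([self.membrane.kappa, self.membrane.kappa_g,
                              self.membrane.cbar])
        self._cons = self.constraints.pack()
        self._mv = self.moves.pack()
        self._conf_kind, self._conf_par = self.confinement.pack()

        self._build_cells()
        self._resync()
        self._audit_initial()

    # -- infrastructure ----------------------------------------------------

    def _build_cells(self) -> None:
        L = self.mesh.box.lengths
        nc = np.maximum(1, (L / self.constraints.d_min).astype(np.int32))
        nc = np.minimum(nc, 64)  # cap the grid; correctness is size-independent
        self._nc = nc.astype(np.int32)
        ncell = int(nc[0]) * int(nc[1]) * int(nc[2])
        self._head = np.full(ncell, -1, dtype=np.int32)
        self._nxt = np.full(self.mesh.n_vertices, -1, dtype=np.int32)
        self._prv = np.full(self.mesh.n_vertices, -1, dtype=np.int32)
        self._cell_of = np.zeros(self.mesh.n_vertices, dtype=np.int32)
        K.cells_build(self.mesh.pos, L, self.mesh.box.periodic, self._nc,
                      self._head, self._nxt, self._prv, self._cell_of)

    def _resync(self) -> None:
        """Full recomputation of caches and running totals."""
        m, g = self.mesh, self.geometry
        inc = self.inclusions
        K.recompute_state(
            m.pos, m.neigh, m.deg, m.vtris, m.tris, m.box.lengths,
            m.box.periodic, g.tri_area, g.tri_norm, g.tri_vol, g.amix,
            g.area, g.normal, g.c1, g.c2, g.t1, g.t2, self._evert,
            self._mem, self._ens, inc.host, inc.type_id, inc.dir,
            inc.host_inc, inc.tp_kind, inc.tp_par, inc.pp_a, inc.pp_b,
            inc.pp_c, inc.pp_n, inc.pp_th0, inc.pp_g0,
            self.force.vertex, self.force.k_spring, self.force.anchor,
            self._tot, False)

    def _audit_initial(self) -> None:
        bad = self.audit()
        if bad:
            raise ValueError(f"initial configuration violates {bad} "
                             "hard constraints")

    def audit(self) -> int:
        """Number of hard-constraint violations in the current state."""
        m, g = self.mesh, self.geometry
        return int(K.audit_constraints(
            m.pos, m.neigh, m.deg, m.edges, m.etris, g.tri_norm,
            m.box.lengths, m.box.periodic, self._cons, self._nc,
            self._head, self._nxt, self._conf_kind, self._conf_par))

    def _sweep_args(self):
        m, g, inc = self.mesh, self.geometry, self.inclusions
        return (m.pos, m.tris, m.neigh, m.deg, m.vtris, m.vedge, m.edges,
                m.etris, m.box.lengths, m.box.periodic,
                g.tri_area, g.tri_norm, g.tri_vol, g.amix, g.area, g.normal,
                g.c1, g.c2, g.t1, g.t2, self._evert,
                inc.host, inc.type_id, inc.dir, inc.host_inc,
                inc.tp_kind, inc.tp_par, inc.pp_a, inc.pp_b, inc.pp_c,
                inc.pp_n, inc.pp_th0, inc.pp_g0,
                self._mem, self._ens, self._cons,
                self._conf_kind, self._conf_par,
                self.force.vertex, self.force.k_spring, self.force.anchor,
                self._mv, self._nc, self._head, self._nxt, self._prv,
                self._cell_of, self._tot, self._mark, self._stamp,
                self._pos_bak, np.empty_like(inc.dir))

    # -- public API --------------------------------------------------------

    @property
    def energy_running(self) -> float:
        """Total energy tracked incrementally by the kernels."""
        return float(self._tot[3])

    @property
    def total_area(self) -> float:
        return float(self._tot[0])

    @property
    def enclosed_volume(self) -> float:
        return float(self._tot[1])

    def total_energy(self) -> float:
        """Independent full recomputation (reference path)."""
        return total_energy(self)

    def mc_sweep(self, n_sweeps: int = 1) -> SweepStats:
        """Run ``n_sweeps`` Monte Carlo sweeps; returns move statistics."""
        stats = np.zeros((4, 3), dtype=np.int64)
        args = self._sweep_args()
        for _ in range(n_sweeps):
            seed = derive_sweep_seed(self.seed, self.sweep_index)
            K.mc_sweep(seed, self.frozen, *args, stats)
            self.sweep_index += 1
            if self.resync_every and self.sweep_index % self.resync_every == 0:
                self._resync()
        return SweepStats(stats[:, K.ST_TRY].copy(),
                          stats[:, K.ST_HARD].copy(),
                          stats[:, K.ST_ACC].copy())

    def attempt_vertex_move(self, v: int) -> bool:
        """Single vertex trial (mainly for tests); frozen mode forbids it."""
        if self.frozen:
            raise RuntimeError("shape moves disabled in frozen mode")
        m, g, inc = self.mesh, self.geometry, self.inclusions
        r = K.try_vertex_move(
            int(v), m.pos, m.tris, m.neigh, m.deg, m.vtris, m.vedge,
            m.edges, m.etris, m.box.lengths, m.box.periodic,
            g.tri_area, g.tri_norm, g.tri_vol, g.amix, g.area, g.normal,
            g.c1, g.c2, g.t1, g.t2, self._evert,
            inc.host, inc.type_id, inc.dir, inc.host_inc,
            inc.tp_kind, inc.tp_par, inc.pp_a, inc.pp_b, inc.pp_c,
            inc.pp_n, inc.pp_th0, inc.pp_g0,
            self._mem, self._ens, self._cons,
            self._conf_kind, self._conf_par,
            self.force.vertex, self.force.k_spring, self.force.anchor,
            self.moves.delta, self._nc, self._head, self._nxt, self._prv,
            self._cell_of, self._tot, self._mark, self._stamp)
        return r == 0

    def attempt_alexander_flip(self, edge_id: int) -> bool:
        if self.frozen:
            raise RuntimeError("shape moves disabled in frozen mode")
        m, g, inc = self.mesh, self.geometry, self.inclusions
        r = K.try_flip(
            int(edge_id), m.pos, m.tris, m.neigh, m.deg, m.vtris, m.vedge,
            m.edges, m.etris, m.box.lengths, m.box.periodic,
            g.tri_area, g.tri_norm, g.tri_vol, g.amix, g.area, g.normal,
            g.c1, g.c2, g.t1, g.t2, self._evert,
            inc.host, inc.type_id, inc.dir, inc.host_inc,
            inc.tp_kind, inc.tp_par, inc.pp_a, inc.pp_b, inc.pp_c,
            inc.pp_n, inc.pp_th0, inc.pp_g0,
            self._mem, self._ens, self._cons, self._tot,
            self._mark, self._stamp)
        return r == 0

    def attempt_inclusion_move(self, j: int) -> bool:
        m, g, inc = self.mesh, self.geometry, self.inclusions
        r = K.try_incl_move(
            int(j), self.moves.rot_amp, m.pos, m.neigh, m.deg,
            m.box.lengths, m.box.periodic, g.area, g.normal,
            g.c1, g.c2, g.t1, g.t2, self._evert,
            inc.host, inc.type_id, inc.dir, inc.host_inc,
            inc.tp_kind, inc.tp_par, inc.pp_a, inc.pp_b, inc.pp_c,
            inc.pp_n, inc.pp_th0, inc.pp_g0,
            self._mem, self._mark, self._stamp, self._tot)
        return r == 0

    def attempt_box_resize(self) -> bool:
        if not self.couplings.tension_on:
            raise RuntimeError("box move requires the tension ensemble")
        m, g, inc = self.mesh, self.geometry, self.inclusions
        dir_bak = inc.dir.copy() if inc.n_inclusions else np.empty((0, 3))
        r = K.try_box_move(
            self.moves.box_amp, m.pos, m.tris, m.neigh, m.deg, m.vtris,
            m.vedge, m.edges, m.etris, m.box.lengths, m.box.periodic,
            g.tri_area, g.tri_norm, g.tri_vol, g.amix, g.area, g.normal,
            g.c1, g.c2, g.t1, g.t2, self._evert,
            inc.host, inc.type_id, inc.dir, inc.host_inc,
            inc.tp_kind, inc.tp_par, inc.pp_a, inc.pp_b, inc.pp_c,
            inc.pp_n, inc.pp_th0, inc.pp_g0,
            self._mem, self._ens, self._cons,
            self._conf_kind, self._conf_par,
            self.force.vertex, self.force.k_spring, self.force.anchor,
            self._nc, self._head, self._nxt, self._prv, self._cell_of,
            self._tot, self._pos_bak, dir_bak)
        return r == 0

    def checkpoint(self, path) -> None:
        """Write a restart frame.  Canonicalizes the connectivity labeling
        first, so a run resumed from this file (same master seed, sweep
        counter set to this frame's) continues the exact trajectory."""
        from .io import write_frame

        self.mesh.canonicalize()
        self.geometry = SurfaceGeometry(self.mesh)
        self._build_cells()
        self._resync()
        write_frame(self, path)

    def harmonic_force_energy(self) -> float:
        """Current energy of the external harmonic anchor."""
        if self.force.vertex < 0:
            return 0.0
        d = self.mesh.pos[self.force.vertex] - self.force.anchor
        return 0.5 * self.force.k_spring * float(d @ d)

    def observables(self) -> dict:
        """Instantaneous scalar observables (full recompute where cheap)."""
        from .energy import bending_energy, coupling_energy
        from .inclusions import inclusion_field_energy

        g = self.geometry
        out = {
            "sweep": self.sweep_index,
            "energy": self.energy_running,
            "area": self.total_area,
            "projected_area": self.mesh.box.projected_area,
            "bending": bending_energy(self.mesh, g, self.membrane),
            "inclusion": inclusion_field_energy(self.mesh, g,
                                                self.inclusions,
                                                self.membrane.kappa),
            "coupling": coupling_energy(self.mesh, g, self.couplings),
            "force": self.harmonic_force_energy(),
        }
        if self.mesh.closed_in_3d:
            v = float(g.tri_vol.sum())
            a = float(g.tri_area.sum())
            out["volume"] = v
            out["reduced_volume"] = v / (a ** 1.5 / (6.0 * math.sqrt(math.pi)))
        return out

    def run(self, n_sweeps: int, frame_every: int = 0,
            out_dir: str | Path | None = None,
            collect_positions: bool = False,
            audit_frames: bool = False) -> "Trajectory":
        """Run sweeps, recording frames/observables at the given cadence.

        ``frame_every = 0`` records only the initial and final frames.
        """
        from .io import write_frame

        traj = Trajectory()
        out_path = Path(out_dir) if out_dir is not None else None
        if out_path is not None:
            out_path.mkdir(parents=True, exist_ok=True)

        def record() -> None:
            traj.sweeps.append(self.sweep_index)
            traj.observables.append(self.observables())
            traj.stats.append(None)
            if collect_positions:
                traj.positions.append(self.mesh.pos.copy())
                traj.boxes.append(self.mesh.box.lengths.copy())
            if audit_frames and self.audit():
                raise RuntimeError(
                    f"hard-constraint violation at sweep {self.sweep_index}")
            if out_path is not None:
                write_frame(self, out_path / f"frame{self.sweep_index:08d}.dts")

        record()
        done = 0
        chunk = frame_every if frame_every > 0 else n_sweeps
        while done < n_sweeps:
            todo = min(chunk, n_sweeps - done)
            stats = self.mc_sweep(todo)
            done += todo
            record()
            traj.stats[-1] = stats
        if out_path is not None:
            traj.write_observables(out_path / "observables.tsv")
        return traj


class Trajectory:
    """In-memory record of a run: observables and (optionally) frames."""

    def __init__(self) -> None:
        self.sweeps: list[int] = []
        self.observables: list[dict] = []
        self.stats: list[SweepStats | None] = []
        self.positions: list[np.ndarray] = []
        self.boxes: list[np.ndarray] = []

    def series(self, key: str) -> np.ndarray:
        return np.array([o[key] for o in self.observables])

    def write_observables(self, path: str | Path) -> None:
        keys = list(self.observables[0].keys())
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for o in self.observables:
                fh.write("\t".join(repr(o.get(k, "")) for k in keys) + "\n")


def zero_temperature_quench(state: SimulationState, n_sweeps: int,
                            beta: float = 1e8) -> None:
    """Greedy descent: scales every energy *magnitude* by ``beta`` so that
    any measurably uphill move is rejected (the acceptance of a move with
    unscaled dE > 1e-6 is below exp(-100)), then restores the parameters.
    Targets and curvatures (Cbar, A_0, v_t, m_0, ...) are left untouched.
    Inclusion energies are not scaled; use on inclusion-free states."""
    scale_ens = [K.ENS_TAU, K.ENS_KA, K.ENS_DP, K.ENS_K, K.ENS_RT, K.ENS_KR]
    mem0 = state._mem.copy()
    ens0 = state._ens.copy()
    fk0 = state.force.k_spring
    state._mem[0] *= beta
    state._mem[1] *= beta
    for i in scale_ens:
        state._ens[i] *= beta
    state.force.k_spring = fk0 * beta
    state._resync()
    try:
        state.mc_sweep(n_sweeps)
    finally:
        state._mem[:] = mem0
        state._ens[:] = ens0
        state.force.k_spring = fk0
        state._resync()
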