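"""File formats: the native text frame (mesh + inclusions) and PLY/OFF.

The native format is a versioned, line-oriented ASCII file:

    # dtsmem frame 1
    box <Lx> <Ly> <Lz> <px> <py> <pz>
    vertices <N>
    <id> <x> <y> <z> <domain>
    ...
    triangles <T>
    <id> <v1> <v2> <v3>
    ...
    inclusions <K>
    <id> <type-name> <host-vertex> <dx> <dy> <dz>
    ...

Indices are 0-based, triangle winding is preserved, floats are written with
17 significant digits so write -> read -> write round-trips bit-exactly
(orientations are stored as the in-plane unit vector itself for this
reason).  Bare meshes can also be exchanged as ASCII PLY or OFF (via
trimesh); inclusions then come from the run configuration.

Edge and ring numbering is rebuilt from the triangle list on read; a live
simulation that should continue a trajectory bit-exactly across a save
must be written through ``SimulationState.checkpoint``, which first
canonicalizes that numbering.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .inclusions import InclusionField
from .mesh import Box, Mesh

FORMAT_VERSION = 1


def write_frame(state_or_mesh, path: str | Path) -> None:
    """Write a native frame; accepts a SimulationState or a bare Mesh."""
    from .sampler import SimulationState

    if isinstance(state_or_mesh, SimulationState):
        mesh = state_or_mesh.mesh
        field = state_or_mesh.inclusions
    else:
        mesh = state_or_mesh
        field = None
    lines = [f"# dtsmem frame {FORMAT_VERSION}"]
    bl = mesh.box.lengths
    bp = mesh.box.periodic.astype(int)
    lines.append("box %.17g %.17g %.17g %d %d %d"
                 % (bl[0], bl[1], bl[2], bp[0], bp[1], bp[2]))
    lines.append(f"vertices {mesh.n_vertices}")
    for i, p in enumerate(mesh.pos):
        lines.append("%d %.17g %.17g %.17g %d"
                     % (i, p[0], p[1], p[2], mesh.domain[i]))
    lines.append(f"triangles {mesh.n_triangles}")
    for i, t in enumerate(mesh.tris):
        lines.append("%d %d %d %d" % (i, t[0], t[1], t[2]))
    n_inc = 0 if field is None else field.n_inclusions
    lines.append(f"inclusions {n_inc}")
    for j in range(n_inc):
        dv = field.dir[j]
        lines.append("%d %s %d %.17g %.17g %.17g"
                     % (j, field.types[field.type_id[j]].name,
                        field.host[j], dv[0], dv[1], dv[2]))
    Path(path).write_text("\n".join(lines) + "\n")


class FrameData:
    """Parsed native frame: mesh plus inclusion records (name, host, dir)."""

    def __init__(self, mesh: Mesh, inclusion_records: list):
        self.mesh = mesh
        self.inclusion_records = inclusion_records

    def build_inclusions(self, types, pair_potentials=None) -> InclusionField:
        field = InclusionField(self.mesh, types, pair_potentials)
        for name, host, dvec in self.inclusion_records:
            field.add(name, host, direction=np.asarray(dvec))
        return field


def read_frame(path: str | Path) -> FrameData:
    """Read a native frame; raises ValueError with a line number on parse
    errors and propagates mesh-validity failures."""
    lines = Path(path).read_text().splitlines()
    ln = 0

    def expect(prefix: str) -> list[str]:
        nonlocal ln
        while ln < len(lines) and (not lines[ln].strip()
                                   or lines[ln].startswith("#")):
            ln += 1
        if ln >= len(lines):
            raise ValueError(f"{path}: unexpected end of file, "
                             f"expected '{prefix}'")
        parts = lines[ln].split()
        if parts[0] != prefix:
            raise ValueError(f"{path}:{ln + 1}: expected '{prefix}', "
                             f"got {parts[0]!r}")
        ln += 1
        return parts

    b = expect("box")
    box = Box(np.array([float(b[1]), float(b[2]), float(b[3])]),
              np.array([bool(int(b[4])), bool(int(b[5])), bool(int(b[6]))]))
    nv = int(expect("vertices")[1])
    pos = np.empty((nv, 3))
    dom = np.zeros(nv, dtype=np.int32)
    for i in range(nv):
        parts = lines[ln].split()
        ln += 1
        if int(parts[0]) != i:
            raise ValueError(f"{path}:{ln}: vertex ids must be 0..N-1 in order")
        pos[i] = (float(parts[1]), float(parts[2]), float(parts[3]))
        if len(parts) > 4:
            dom[i] = int(parts[4])
    nt = int(expect("triangles")[1])
    tris = np.empty((nt, 3), dtype=np.int32)
    for i in range(nt):
        parts = lines[ln].split()
        ln += 1
        tris[i] = (int(parts[1]), int(parts[2]), int(parts[3]))
    records = []
    ni = int(expect("inclusions")[1])
    for _ in range(ni):
        parts = lines[ln].split()
        ln += 1
        records.append((parts[1], int(parts[2]),
                        (float(parts[3]), float(parts[4]), float(parts[5]))))
    mesh = Mesh(pos, tris, box, domain=dom)
    return FrameData(mesh, records)


# -- PLY / OFF (bare meshes) -----------------------------------------------


def write_ply(mesh: Mesh, path: str | Path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.pos, faces=mesh.tris, process=False)
    Path(path).write_bytes(trimesh.exchange.ply.export_ply(
        tm, encoding="ascii"))


def write_off(mesh: Mesh, path: str | Path) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.pos, faces=mesh.tris, process=False)
    Path(path).write_text(trimesh.exchange.export.export_off(tm))


def read_mesh_file(path: str | Path, box: Box | None = None) -> Mesh:
    """Load a bare mesh from PLY/OFF (or a native frame) into a Mesh.

    Without an explicit box, a non-periodic envelope with a 4 l_dts margin
    is fitted around the geometry.
    """
    path = Path(path)
    if path.suffix in (".dts", ".frame", ".txt"):
        return read_frame(path).mesh
    import trimesh

    tm = trimesh.load(str(path), process=False)
    pos = np.asarray(tm.vertices, dtype=np.float64)
    tris = np.asarray(tm.faces, dtype=np.int32)
    if box is None:
        lo = pos.min(axis=0) - 4.0
        hi = pos.max(axis=0) + 4.0
        pos = pos - lo
        box = Box(hi - lo, np.array([False, False, False]))
    return Mesh(pos, tris, box)
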