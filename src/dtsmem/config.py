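"""YAML run configuration -> a ready SimulationState.

Example
-------
::

    seed: 7
    mesh:
      generator: flat        # flat | icosphere | tube | torus | file
      nx: 16
      ny: 16
      spacing: 1.2
    membrane: {kappa: 20.0, kappa_g: 0.0, cbar: 0.0}
    couplings:
      tension: {tau: 0.0}
    inclusion_types:
      - {name: toxin, kind: 1, c0: 0.4, coverage: 0.2}
    pair_potentials:
      - {i: toxin, j: toxin, a: 0.5}
    constraints: {l_min: 1.0, l_max: 1.7320508075688772, min_dihedral_cos: 0.0}
    moves: {delta: 0.1, rot_amp: 0.7853981633974483, box_amp: 0.01, p_box: 1.0}
    confinement: {kind: none}
    force: {vertex: -1, k_spring: 0.0, anchor: [0, 0, 0]}
    frozen: false

Unknown keys raise; inclusion placement is a seeded uniform sample of
unoccupied vertices at the requested coverage (count = round(coverage N)).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .energy import EnsembleCouplings, MembraneParams
from .geometry import SurfaceGeometry
from .inclusions import InclusionField, InclusionType, PairPotential
from .mesh import build_flat_grid, build_icosphere, build_torus, build_tube
from .sampler import (Confinement, Constraints, ExternalForce, MoveParams,
                      SimulationState)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    extra = set(block) - allowed
    if extra:
        raise ValueError(f"unknown keys {sorted(extra)} in '{where}'")


def _build_mesh(cfg: dict, cons: Constraints):
    kind = cfg.get("generator", "flat")
    if kind == "flat":
        _check_keys(cfg, {"generator", "nx", "ny", "spacing", "lz"}, "mesh")
        return build_flat_grid(cfg.get("nx", 16), cfg.get("ny", 16),
                               cfg.get("spacing", 1.2), cfg.get("lz"),
                               l_min=cons.l_min, l_max=cons.l_max)
    if kind == "icosphere":
        _check_keys(cfg, {"generator", "subdivisions", "radius"}, "mesh")
        return build_icosphere(cfg.get("subdivisions", 3), cfg.get("radius"),
                               l_min=cons.l_min, l_max=cons.l_max)
    if kind == "tube":
        _check_keys(cfg, {"generator", "n_axial", "n_circ", "radius",
                          "length"}, "mesh")
        return build_tube(cfg.get("n_axial", 16), cfg.get("n_circ", 16),
                          cfg.get("radius"), cfg.get("length"),
                          l_min=cons.l_min, l_max=cons.l_max)
    if kind == "torus":
        _check_keys(cfg, {"generator", "n_major", "n_minor", "r_major",
                          "r_minor"}, "mesh")
        return build_torus(cfg["n_major"], cfg["n_minor"],
                           cfg["r_major"], cfg["r_minor"])
    if kind == "file":
        _check_keys(cfg, {"generator", "path"}, "mesh")
        from .io import read_mesh_file

        return read_mesh_file(cfg["path"])
    raise ValueError(f"unknown mesh generator {kind!r}")


def _build_couplings(cfg: dict) -> EnsembleCouplings:
    _check_keys(cfg, {"tension", "area", "volume", "osmotic",
                      "global_curvature"}, "couplings")
    c = EnsembleCouplings()
    if "tension" in cfg:
        _check_keys(cfg["tension"], {"tau"}, "couplings.tension")
        c.tension_on = True
        c.tau = float(cfg["tension"].get("tau", 0.0))
    if "area" in cfg:
        _check_keys(cfg["area"], {"k_a", "a0"}, "couplings.area")
        c.area_on = True
        c.k_a = float(cfg["area"]["k_a"])
        c.a0 = float(cfg["area"]["a0"])
    if "volume" in cfg:
        _check_keys(cfg["volume"], {"dp", "k", "v_t"}, "couplings.volume")
        c.volume_on = True
        c.dp = float(cfg["volume"].get("dp", 0.0))
        c.k_v = float(cfg["volume"].get("k", 0.0))
        c.v_t = float(cfg["volume"].get("v_t", 1.0))
    if "osmotic" in cfg:
        _check_keys(cfg["osmotic"], {"rt", "c_in", "c_out", "v_ini"},
                    "couplings.osmotic")
        c.osmotic_on = True
        c.rt = float(cfg["osmotic"].get("rt", 1.0))
        c.c_in = float(cfg["osmotic"].get("c_in", 0.0))
        c.c_out = float(cfg["osmotic"].get("c_out", 0.0))
        c.v_ini = float(cfg["osmotic"]["v_ini"])
    if "global_curvature" in cfg:
        _check_keys(cfg["global_curvature"], {"k_r", "m0"},
                    "couplings.global_curvature")
        c.global_curv_on = True
        c.k_r = float(cfg["global_curvature"]["k_r"])
        c.m0 = float(cfg["global_curvature"].get("m0", 0.0))
    return EnsembleCouplings(**{f: getattr(c, f) for f in
                                c.__dataclass_fields__})


def load_config(path_or_dict) -> SimulationState:
    """Build a complete SimulationState from a YAML file (or parsed dict)."""
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        cfg = yaml.safe_load(Path(path_or_dict).read_text())
    _check_keys(cfg, {"seed", "mesh", "membrane", "couplings",
                      "inclusion_types", "pair_potentials", "constraints",
                      "moves", "confinement", "force", "frozen"}, "top level")
    seed = int(cfg.get("seed", 1))

    cons_cfg = cfg.get("constraints", {})
    _check_keys(cons_cfg, {"l_min", "l_max", "d_min", "min_dihedral_cos"},
                "constraints")
    cons = Constraints(**cons_cfg)

    mesh = _build_mesh(cfg.get("mesh", {}), cons)

    mem_cfg = cfg.get("membrane", {})
    _check_keys(mem_cfg, {"kappa", "kappa_g", "cbar"}, "membrane")
    membrane = MembraneParams(**mem_cfg)

    couplings = _build_couplings(cfg.get("couplings", {}))

    types = []
    coverages = []
    for tcfg in cfg.get("inclusion_types", []):
        tcfg = dict(tcfg)
        coverages.append(float(tcfg.pop("coverage", 0.0)))
        count = tcfg.pop("count", None)
        _check_keys(tcfg, {"name", "kind", "dkappa", "dkappa_g", "c0", "k1",
                           "k2", "c_par0", "c_perp0", "symmetry"},
                    "inclusion_types")
        types.append(InclusionType(**tcfg))
        if count is not None:
            coverages[-1] = count / mesh.n_vertices
    pps = []
    for pcfg in cfg.get("pair_potentials", []):
        pcfg = dict(pcfg)
        pcfg["type_i"] = pcfg.pop("i", pcfg.pop("type_i", None))
        pcfg["type_j"] = pcfg.pop("j", pcfg.pop("type_j", None))
        _check_keys(pcfg, {"type_i", "type_j", "a", "b", "c", "n", "theta0",
                           "gamma0"}, "pair_potentials")
        pps.append(PairPotential(**pcfg))

    geom = SurfaceGeometry(mesh)
    field = InclusionField(mesh, types, pps)
    rng = np.random.default_rng(seed)
    for t, cov in zip(types, coverages):
        if cov:
            field.place_random(t.name, cov, geom, rng)

    mv_cfg = cfg.get("moves", {})
    _check_keys(mv_cfg, {"delta", "rot_amp", "box_amp", "p_box"}, "moves")
    conf_cfg = dict(cfg.get("confinement", {}))
    _check_keys(conf_cfg, {"kind", "center", "z0", "h", "semi_axes",
                           "inner_fraction"}, "confinement")
    for key in ("center", "semi_axes"):
        if key in conf_cfg:
            conf_cfg[key] = tuple(conf_cfg[key])
    frc_cfg = dict(cfg.get("force", {}))
    _check_keys(frc_cfg, {"vertex", "k_spring", "anchor"}, "force")
    if "anchor" in frc_cfg:
        frc_cfg["anchor"] = np.asarray(frc_cfg["anchor"], dtype=np.float64)

    return SimulationState(
        mesh, membrane=membrane, couplings=couplings, inclusions=field,
        constraints=cons, moves=MoveParams(**mv_cfg),
        confinement=Confinement(**conf_cfg),
        force=ExternalForce(**frc_cfg) if frc_cfg else None,
        frozen=bool(cfg.get("frozen", False)), seed=seed)
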