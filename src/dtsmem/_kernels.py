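"""Numba kernels: discrete geometry, incremental energies and the MC moves.

Everything here operates on the flat arrays owned by ``Mesh`` /
``SimulationState``.  The layout conventions are documented in
:mod:`dtsmem.mesh`; additional per-state arrays:

* geometry caches: ``tri_area``, ``tri_norm``, ``tri_vol``, ``amix`` (mixed
  Voronoi vertex area used to normalize the shape operator), ``varea``
  (barycentric 1/3 vertex area used in energy integrals), ``vnorm``, ``c1``,
  ``c2`` (principal curvatures, c1 >= c2), ``t1v``/``t2v`` (principal
  directions), ``evert`` (per-vertex bending + inclusion-site energy).
* running totals ``tot``: [surface area A, enclosed volume V,
  integrated mean curvature M = sum 2H A_v, total energy E].
* parameter packs (float64 vectors) ``mem``, ``ens``, ``cons``, ``mv``
  assembled by the sampler; see the index constants below.

Energy differences for Metropolis are evaluated over the exact dependency
region of a move (the moved vertices plus their one-rings for positional
moves; the four quad vertices for a link flip) with snapshot/restore on
rejection, so the running total energy tracks a full recomputation to
floating-point accumulation error.
"""

import math

import numpy as np
from numba import njit

MAXD = 20          # ring capacity (keep in sync with mesh.MAXD)
MAXS = MAXD + 2    # refresh-set capacity of a single-vertex move

# ens[] layout: flag/value pairs for the system-level couplings
ENS_TAU_ON, ENS_TAU = 0, 1
ENS_KA_ON, ENS_KA, ENS_A0 = 2, 3, 4
ENS_V_ON, ENS_DP, ENS_K, ENS_VT = 5, 6, 7, 8
ENS_OSM_ON, ENS_RT, ENS_CIN, ENS_COUT, ENS_VINI = 9, 10, 11, 12, 13
ENS_GC_ON, ENS_KR, ENS_M0 = 14, 15, 16
ENS_LEN = 17

# cons[] layout
CONS_LMIN, CONS_LMAX, CONS_DMIN, CONS_MINCOS = 0, 1, 2, 3

# mv[] layout
MV_DELTA, MV_ROT, MV_BOX, MV_PBOX = 0, 1, 2, 3

# confinement kinds
CONF_NONE, CONF_SLAB, CONF_ELLIPSOID, CONF_SHELL, CONF_BLOCK = 0, 1, 2, 3, 4

# stats rows / columns
ST_FLIP, ST_VERT, ST_INCL, ST_BOX = 0, 1, 2, 3
ST_TRY, ST_HARD, ST_ACC = 0, 1, 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _mi1(d, l, p):
    if p:
        d -= l * round(d / l)
    return d


@njit(cache=True, inline="always")
def mi3(px, py, pz, qx, qy, qz, L, per):
    return (_mi1(px - qx, L[0], per[0]),
            _mi1(py - qy, L[1], per[1]),
            _mi1(pz - qz, L[2], per[2]))


# ---------------------------------------------------------------------------
# triangle caches
# ---------------------------------------------------------------------------

@njit(cache=True)
def tri_update(t, pos, tris, L, per, tri_area, tri_norm, tri_vol):
    i0, i1, i2 = tris[t, 0], tris[t, 1], tris[t, 2]
    ax, ay, az = pos[i0, 0], pos[i0, 1], pos[i0, 2]
    e1x, e1y, e1z = mi3(pos[i1, 0], pos[i1, 1], pos[i1, 2], ax, ay, az, L, per)
    e2x, e2y, e2z = mi3(pos[i2, 0], pos[i2, 1], pos[i2, 2], ax, ay, az, L, per)
    nx = e1y * e2z - e1z * e2y
    ny = e1z * e2x - e1x * e2z
    nz = e1x * e2y - e1y * e2x
    a2 = math.sqrt(nx * nx + ny * ny + nz * nz)
    tri_area[t] = 0.5 * a2
    tri_norm[t, 0] = nx / a2
    tri_norm[t, 1] = ny / a2
    tri_norm[t, 2] = nz / a2
    # signed volume of the cone to the origin (divergence theorem); only
    # meaningful summed over a 3D-closed mesh, where min-image is a no-op.
    bx, by, bz = ax + e1x, ay + e1y, az + e1z
    cx, cy, cz = ax + e2x, ay + e2y, az + e2z
    tri_vol[t] = (ax * (by * cz - bz * cy)
                  - ay * (bx * cz - bz * cx)
                  + az * (bx * cy - by * cx)) / 6.0


@njit(cache=True)
def all_tris_update(pos, tris, L, per, tri_area, tri_norm, tri_vol):
    for t in range(tris.shape[0]):
        tri_update(t, pos, tris, L, per, tri_area, tri_norm, tri_vol)


# ---------------------------------------------------------------------------
# per-vertex geometry: mixed area + edge-dihedral shape operator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mixed_area_v(v, pos, vtris, deg, tris, L, per):
    """Meyer mixed (Voronoi-clamped) area of vertex v; always positive."""
    am = 0.0
    for ii in range(deg[v]):
        t = vtris[v, ii]
        ia, ib, ic = tris[t, 0], tris[t, 1], tris[t, 2]
        # rotate so corner 0 is v
        if ib == v:
            ia, ib, ic = ib, ic, ia
        elif ic == v:
            ia, ib, ic = ic, ia, ib
        ax, ay, az = pos[ia, 0], pos[ia, 1], pos[ia, 2]
        bx, by, bz = mi3(pos[ib, 0], pos[ib, 1], pos[ib, 2], ax, ay, az, L, per)
        cx, cy, cz = mi3(pos[ic, 0], pos[ic, 1], pos[ic, 2], ax, ay, az, L, per)
        # d_a, d_b, d_c: dot products at the three corners
        da = bx * cx + by * cy + bz * cz
        db = (cx - bx) * (-bx) + (cy - by) * (-by) + (cz - bz) * (-bz)
        dc = (-cx) * (bx - cx) + (-cy) * (by - cy) + (-cz) * (bz - cz)
        crx = by * cz - bz * cy
        cry = bz * cx - bx * cz
        crz = bx * cy - by * cx
        a2 = math.sqrt(crx * crx + cry * cry + crz * crz)
        area = 0.5 * a2
        if da < 0.0:
            am += 0.5 * area
        elif db < 0.0 or dc < 0.0:
            am += 0.25 * area
        else:
            cot_b = db / a2
            cot_c = dc / a2
            l_ab2 = bx * bx + by * by + bz * bz
            l_ac2 = cx * cx + cy * cy + cz * cz
            am += (l_ab2 * cot_c + l_ac2 * cot_b) / 8.0
    return am


@njit(cache=True)
def vertex_geometry(v, pos, neigh, deg, vtris, tris, L, per,
                    tri_area, tri_norm,
                    varea, amix, vnorm, c1a, c2a, t1a, t2a):
    """Area, outward normal and principal curvatures/directions of vertex v.

    The shape operator is assembled from the one-ring edges: each edge
    contributes (1/2) * h_e * (b_e (x) b_e) with h_e = 2 |e| sin(alpha_e / 2),
    alpha_e the dihedral angle between the two face normals signed positive
    for convex (ridge) folds, and b_e the unit edge binormal.  Normalization
    by the mixed Voronoi area gives pointwise-accurate curvatures even at
    irregular (non-6-valent) vertices.
    """
    dv = deg[v]
    a3 = 0.0
    nx = ny = nz = 0.0
    for ii in range(dv):
        t = vtris[v, ii]
        a = tri_area[t]
        a3 += a
        nx += a * tri_norm[t, 0]
        ny += a * tri_norm[t, 1]
        nz += a * tri_norm[t, 2]
    varea[v] = a3 / 3.0
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx /= nn
    ny /= nn
    nz /= nn
    vnorm[v, 0] = nx
    vnorm[v, 1] = ny
    vnorm[v, 2] = nz
    am = _mixed_area_v(v, pos, vtris, deg, tris, L, per)
    amix[v] = am

    vx, vy, vz = pos[v, 0], pos[v, 1], pos[v, 2]
    sxx = sxy = sxz = syy = syz = szz = 0.0
    for ii in range(dv):
        u = neigh[v, ii]
        tb = vtris[v, ii]
        ta = vtris[v, ii - 1] if ii > 0 else vtris[v, dv - 1]
        n1x, n1y, n1z = tri_norm[ta, 0], tri_norm[ta, 1], tri_norm[ta, 2]
        n2x, n2y, n2z = tri_norm[tb, 0], tri_norm[tb, 1], tri_norm[tb, 2]
        ex, ey, ez = mi3(pos[u, 0], pos[u, 1], pos[u, 2], vx, vy, vz, L, per)
        le = math.sqrt(ex * ex + ey * ey + ez * ez)
        dotn = n1x * n2x + n1y * n2y + n1z * n2z
        if dotn > 1.0:
            dotn = 1.0
        elif dotn < -1.0:
            dotn = -1.0
        # convexity sign: put the two unit face normals at the face
        # centroids; a ridge (convex) spreads the tips apart.
        cax = cay = caz = 0.0
        cbx = cby = cbz = 0.0
        for kk in range(3):
            w = tris[ta, kk]
            wx, wy, wz = mi3(pos[w, 0], pos[w, 1], pos[w, 2], vx, vy, vz, L, per)
            cax += wx
            cay += wy
            caz += wz
            w = tris[tb, kk]
            wx, wy, wz = mi3(pos[w, 0], pos[w, 1], pos[w, 2], vx, vy, vz, L, per)
            cbx += wx
            cby += wy
            cbz += wz
        dbx = (cbx - cax) / 3.0
        dby = (cby - cay) / 3.0
        dbz = (cbz - caz) / 3.0
        tx = dbx + n2x - n1x
        ty = dby + n2y - n1y
        tz = dbz + n2z - n1z
        base2 = dbx * dbx + dby * dby + dbz * dbz
        tip2 = tx * tx + ty * ty + tz * tz
        s = 1.0 if tip2 >= base2 else -1.0
        he = s * le * math.sqrt(max(0.0, 2.0 * (1.0 - dotn)))
        # binormal: unit( e x unit(n1 + n2) )
        mx, my, mz = n1x + n2x, n1y + n2y, n1z + n2z
        bx = ey * mz - ez * my
        by = ez * mx - ex * mz
        bz = ex * my - ey * mx
        bn = math.sqrt(bx * bx + by * by + bz * bz)
        if bn < 1e-14:
            continue
        bx /= bn
        by /= bn
        bz /= bn
        w_ = 0.5 * he
        sxx += w_ * bx * bx
        sxy += w_ * bx * by
        sxz += w_ * bx * bz
        syy += w_ * by * by
        syz += w_ * by * bz
        szz += w_ * bz * bz
    sxx /= am
    sxy /= am
    sxz /= am
    syy /= am
    syz /= am
    szz /= am

    # tangent basis seeded from the first ring edge
    u0 = neigh[v, 0]
    ex, ey, ez = mi3(pos[u0, 0], pos[u0, 1], pos[u0, 2], vx, vy, vz, L, per)
    dd = ex * nx + ey * ny + ez * nz
    qx, qy, qz = ex - dd * nx, ey - dd * ny, ez - dd * nz
    qn = math.sqrt(qx * qx + qy * qy + qz * qz)
    if qn < 1e-12:
        qx, qy, qz = 1.0 - nx * nx, -nx * ny, -nx * nz
        qn = math.sqrt(qx * qx + qy * qy + qz * qz)
        if qn < 1e-12:
            qx, qy, qz = -ny * nx, 1.0 - ny * ny, -ny * nz
            qn = math.sqrt(qx * qx + qy * qy + qz * qz)
    qx /= qn
    qy /= qn
    qz /= qn
    rx = ny * qz - nz * qy
    ry = nz * qx - nx * qz
    rz = nx * qy - ny * qx

    aq = (qx * (sxx * qx + sxy * qy + sxz * qz)
          + qy * (sxy * qx + syy * qy + syz * qz)
          + qz * (sxz * qx + syz * qy + szz * qz))
    cq = (rx * (sxx * rx + sxy * ry + sxz * rz)
          + ry * (sxy * rx + syy * ry + syz * rz)
          + rz * (sxz * rx + syz * ry + szz * rz))
    bq = (qx * (sxx * rx + sxy * ry + sxz * rz)
          + qy * (sxy * rx + syy * ry + syz * rz)
          + qz * (sxz * rx + syz * ry + szz * rz))
    tr2 = 0.5 * (aq + cq)
    disc = math.sqrt(0.25 * (aq - cq) * (aq - cq) + bq * bq)
    cc1 = tr2 + disc
    cc2 = tr2 - disc
    c1a[v] = cc1
    c2a[v] = cc2

    if disc < 1e-9:
        # umbilic: principal directions degenerate; use the tangent
        # projection of a fixed reference axis (x, falling back to y).
        px, py, pz = 1.0 - nx * nx, -nx * ny, -nx * nz
        pn = math.sqrt(px * px + py * py + pz * pz)
        if pn < 1e-6:
            px, py, pz = -ny * nx, 1.0 - ny * ny, -ny * nz
            pn = math.sqrt(px * px + py * py + pz * pz)
        t1x, t1y, t1z = px / pn, py / pn, pz / pn
    else:
        w1 = abs(bq) + abs(cc1 - aq)
        w2 = abs(cc1 - cq) + abs(bq)
        if w1 >= w2:
            e1, e2 = bq, cc1 - aq
        else:
            e1, e2 = cc1 - cq, bq
        en = math.sqrt(e1 * e1 + e2 * e2)
        e1 /= en
        e2 /= en
        t1x = e1 * qx + e2 * rx
        t1y = e1 * qy + e2 * ry
        t1z = e1 * qz + e2 * rz
    t1a[v, 0] = t1x
    t1a[v, 1] = t1y
    t1a[v, 2] = t1z
    t2a[v, 0] = ny * t1z - nz * t1y
    t2a[v, 1] = nz * t1x - nx * t1z
    t2a[v, 2] = nx * t1y - ny * t1x


@njit(cache=True)
def all_geometry(pos, neigh, deg, vtris, tris, L, per, tri_area, tri_norm,
                 varea, amix, vnorm, c1a, c2a, t1a, t2a):
    for v in range(pos.shape[0]):
        vertex_geometry(v, pos, neigh, deg, vtris, tris, L, per,
                        tri_area, tri_norm, varea, amix, vnorm,
                        c1a, c2a, t1a, t2a)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

@njit(cache=True)
def vertex_energy(v, mem, varea, c1a, c2a, t1a, t2a,
                  host_inc, inc_type, inc_dir, tp_kind, tp_par):
    """Bending + inclusion-site energy of vertex v (k_BT)."""
    cc1 = c1a[v]
    cc2 = c2a[v]
    a = varea[v]
    h2 = cc1 + cc2               # 2H
    kg = cc1 * cc2               # Gaussian curvature
    e = (0.5 * mem[0] * (h2 - mem[2]) ** 2 - mem[1] * kg) * a
    j = host_inc[v]
    if j >= 0:
        ty = inc_type[j]
        if tp_kind[ty] == 1:
            dk = tp_par[ty, 0]
            dkg = tp_par[ty, 1]
            c0 = tp_par[ty, 2]
            h = 0.5 * h2
            e += (2.0 * dk * h * h - 2.0 * (dk + mem[0]) * c0 * h - dkg * kg) * a
        else:
            k1 = tp_par[ty, 0]
            k2 = tp_par[ty, 1]
            cp0 = tp_par[ty, 2]
            cq0 = tp_par[ty, 3]
            dx, dy, dz = inc_dir[j, 0], inc_dir[j, 1], inc_dir[j, 2]
            ct = dx * t1a[v, 0] + dy * t1a[v, 1] + dz * t1a[v, 2]
            st = dx * t2a[v, 0] + dy * t2a[v, 1] + dz * t2a[v, 2]
            cpar = cc1 * ct * ct + cc2 * st * st
            cperp = cc1 * st * st + cc2 * ct * ct
            e += (0.5 * k1 * (cpar - cp0) ** 2
                  + 0.5 * k2 * (cperp - cq0) ** 2) * a
    return e


@njit(cache=True)
def pair_geometry(u, w, pos, vnorm, L, per):
    """Return (ok, pu, pw) in-plane unit projections of the u->w connector."""
    rx, ry, rz = mi3(pos[w, 0], pos[w, 1], pos[w, 2],
                     pos[u, 0], pos[u, 1], pos[u, 2], L, per)
    nux, nuy, nuz = vnorm[u, 0], vnorm[u, 1], vnorm[u, 2]
    nwx, nwy, nwz = vnorm[w, 0], vnorm[w, 1], vnorm[w, 2]
    du = rx * nux + ry * nuy + rz * nuz
    pux, puy, puz = rx - du * nux, ry - du * nuy, rz - du * nuz
    npu = math.sqrt(pux * pux + puy * puy + puz * puz)
    dw = rx * nwx + ry * nwy + rz * nwz
    pwx, pwy, pwz = rx - dw * nwx, ry - dw * nwy, rz - dw * nwz
    npw = math.sqrt(pwx * pwx + pwy * pwy + pwz * pwz)
    if npu < 1e-12 or npw < 1e-12:
        return False, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, rx, ry, rz
    return (True, pux / npu, puy / npu, puz / npu,
            pwx / npw, pwy / npw, pwz / npw, rx, ry, rz)


@njit(cache=True)
def pair_energy_uw(u, w, pos, vnorm, L, per, host_inc, inc_type, inc_dir,
                   ppA, ppB, ppC, ppn, ppth0, ppg0):
    """Nearest-neighbor inclusion-inclusion energy between hosts u and w.

    Theta_k is the signed angle (about the vertex normal) from the in-plane
    projection of the connecting line to the inclusion direction; the pair
    angle is Theta_2 - Theta_1.  gamma is the angle between the two vertex
    normals, positive when the normal tips spread farther apart than the
    edge length (ridge), negative otherwise (valley).
    """
    i = host_inc[u]
    j = host_inc[w]
    ok, pux, puy, puz, pwx, pwy, pwz, rx, ry, rz = pair_geometry(
        u, w, pos, vnorm, L, per)
    if not ok:
        return 0.0
    nux, nuy, nuz = vnorm[u, 0], vnorm[u, 1], vnorm[u, 2]
    nwx, nwy, nwz = vnorm[w, 0], vnorm[w, 1], vnorm[w, 2]
    dx, dy, dz = inc_dir[i, 0], inc_dir[i, 1], inc_dir[i, 2]
    cos1 = dx * pux + dy * puy + dz * puz
    # n_u x p_u
    bx = nuy * puz - nuz * puy
    by = nuz * pux - nux * puz
    bz = nux * puy - nuy * pux
    sin1 = dx * bx + dy * by + dz * bz
    th1 = math.atan2(sin1, cos1)
    ex, ey, ez = inc_dir[j, 0], inc_dir[j, 1], inc_dir[j, 2]
    cos2 = ex * pwx + ey * pwy + ez * pwz
    bx = nwy * pwz - nwz * pwy
    by = nwz * pwx - nwx * pwz
    bz = nwx * pwy - nwy * pwx
    sin2 = ex * bx + ey * by + ez * bz
    th2 = math.atan2(sin2, cos2)
    theta = th2 - th1
    cg = nux * nwx + nuy * nwy + nuz * nwz
    if cg > 1.0:
        cg = 1.0
    elif cg < -1.0:
        cg = -1.0
    tx, ty, tz = rx + nwx - nux, ry + nwy - nuy, rz + nwz - nuz
    s = 1.0 if (tx * tx + ty * ty + tz * tz) >= (rx * rx + ry * ry + rz * rz) \
        else -1.0
    g = s * math.acos(cg)
    ti = inc_type[i]
    tj = inc_type[j]
    return (-ppA[ti, tj]
            - ppB[ti, tj] * math.cos(ppn[ti, tj] * (theta - ppth0[ti, tj]))
            - ppC[ti, tj] * math.cos(g - ppg0[ti, tj]))


@njit(cache=True)
def local_pair_sum(slist, ns, mark, stamp, pos, vnorm, L, per,
                   neigh, deg, host_inc, inc_type, inc_dir,
                   ppA, ppB, ppC, ppn, ppth0, ppg0):
    """Sum of pair energies with at least one endpoint in slist[:ns]."""
    for k in range(ns):
        mark[slist[k]] = stamp
    e = 0.0
    for k in range(ns):
        u = slist[k]
        if host_inc[u] < 0:
            continue
        for ii in range(deg[u]):
            w = neigh[u, ii]
            if host_inc[w] < 0:
                continue
            if mark[w] == stamp and w <= u:
                continue
            e += pair_energy_uw(u, w, pos, vnorm, L, per, host_inc,
                                inc_type, inc_dir, ppA, ppB, ppC,
                                ppn, ppth0, ppg0)
    return e


@njit(cache=True)
def full_pair_sum(pos, vnorm, L, per, neigh, deg, inc_host, host_inc,
                  inc_type, inc_dir, ppA, ppB, ppC, ppn, ppth0, ppg0):
    e = 0.0
    for j in range(inc_host.shape[0]):
        u = inc_host[j]
        for ii in range(deg[u]):
            w = neigh[u, ii]
            if host_inc[w] >= 0 and w > u:
                e += pair_energy_uw(u, w, pos, vnorm, L, per, host_inc,
                                    inc_type, inc_dir, ppA, ppB, ppC,
                                    ppn, ppth0, ppg0)
    return e


@njit(cache=True)
def global_energy(a, v, m, lx, ly, nt, ens):
    """System-level couplings evaluated from the running totals."""
    e = 0.0
    if ens[ENS_TAU_ON] > 0.0:
        e -= ens[ENS_TAU] * lx * ly
    if ens[ENS_KA_ON] > 0.0:
        e += nt * 0.5 * ens[ENS_KA] * (a / ens[ENS_A0] - 1.0) ** 2
    if ens[ENS_V_ON] > 0.0:
        v0 = a ** 1.5 / (6.0 * math.sqrt(math.pi))
        e += -ens[ENS_DP] * v + 0.5 * ens[ENS_K] * (v / v0 - ens[ENS_VT]) ** 2
    if ens[ENS_OSM_ON] > 0.0:
        e -= ens[ENS_RT] * (ens[ENS_CIN] * ens[ENS_VINI]
                            * math.log(v / ens[ENS_VINI])
                            - ens[ENS_COUT] * (v - ens[ENS_VINI]))
    if ens[ENS_GC_ON] > 0.0:
        e += 0.5 * ens[ENS_KR] / a * (m - ens[ENS_M0] * a) ** 2
    return e


@njit(cache=True)
def force_energy(fv, fk, anchor, pos):
    if fv < 0:
        return 0.0
    dx = pos[fv, 0] - anchor[0]
    dy = pos[fv, 1] - anchor[1]
    dz = pos[fv, 2] - anchor[2]
    return 0.5 * fk * (dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def conf_ok(x, y, z, kind, par):
    if kind == CONF_NONE:
        return True
    if kind == CONF_SLAB:
        return abs(z - par[0]) <= 0.5 * par[1]
    fx = (x - par[0]) / par[3]
    fy = (y - par[1]) / par[4]
    fz = (z - par[2]) / par[5]
    if kind == CONF_BLOCK:
        return abs(fx) <= 1.0 and abs(fy) <= 1.0 and abs(fz) <= 1.0
    rho = math.sqrt(fx * fx + fy * fy + fz * fz)
    if kind == CONF_ELLIPSOID:
        return rho <= 1.0
    return par[6] <= rho <= 1.0  # shell


# ---------------------------------------------------------------------------
# cell list (global hard-core checks)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cell_axis(x, l, p, nc):
    if p:
        u = x / l
        u -= math.floor(u)
        c = int(u * nc)
        if c >= nc:
            c = nc - 1
        return c
    c = int(math.floor(x / (l / nc)))
    if c < 0:
        c = 0
    elif c >= nc:
        c = nc - 1
    return c


@njit(cache=True)
def cell_index(x, y, z, L, per, nc):
    cx = _cell_axis(x, L[0], per[0], nc[0])
    cy = _cell_axis(y, L[1], per[1], nc[1])
    cz = _cell_axis(z, L[2], per[2], nc[2])
    return (cz * nc[1] + cy) * nc[0] + cx


@njit(cache=True)
def cells_build(pos, L, per, nc, head, nxt, prv, cell_of):
    head[:] = -1
    for v in range(pos.shape[0]):
        c = cell_index(pos[v, 0], pos[v, 1], pos[v, 2], L, per, nc)
        cell_of[v] = c
        nxt[v] = head[c]
        prv[v] = -1
        if head[c] >= 0:
            prv[head[c]] = v
        head[c] = v


@njit(cache=True)
def cell_move(v, x, y, z, L, per, nc, head, nxt, prv, cell_of):
    c = cell_index(x, y, z, L, per, nc)
    old = cell_of[v]
    if c == old:
        return
    # unlink
    if prv[v] >= 0:
        nxt[prv[v]] = nxt[v]
    else:
        head[old] = nxt[v]
    if nxt[v] >= 0:
        prv[nxt[v]] = prv[v]
    # insert
    cell_of[v] = c
    nxt[v] = head[c]
    prv[v] = -1
    if head[c] >= 0:
        prv[head[c]] = v
    head[c] = v


@njit(cache=True)
def too_close(v, x, y, z, dmin2, pos, L, per, nc, head, nxt):
    cx = _cell_axis(x, L[0], per[0], nc[0])
    cy = _cell_axis(y, L[1], per[1], nc[1])
    cz = _cell_axis(z, L[2], per[2], nc[2])
    for oz in range(-1, 2):
        zz = cz + oz
        if per[2]:
            zz %= nc[2]
        elif zz < 0 or zz >= nc[2]:
            continue
        for oy in range(-1, 2):
            yy = cy + oy
            if per[1]:
                yy %= nc[1]
            elif yy < 0 or yy >= nc[1]:
                continue
            for ox in range(-1, 2):
                xx = cx + ox
                if per[0]:
                    xx %= nc[0]
                elif xx < 0 or xx >= nc[0]:
                    continue
                w = head[(zz * nc[1] + yy) * nc[0] + xx]
                while w >= 0:
                    if w != v:
                        dx, dy, dz = mi3(pos[w, 0], pos[w, 1], pos[w, 2],
                                         x, y, z, L, per)
                        if dx * dx + dy * dy + dz * dz < dmin2:
                            return True
                    w = nxt[w]
    return False


# ---------------------------------------------------------------------------
# topological link flip (shared with Mesh.flip_edge)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _find_edge(v, w, neigh, deg, vedge):
    for ii in range(deg[v]):
        if neigh[v, ii] == w:
            return vedge[v, ii]
    return -1


@njit(cache=True)
def _rebuild_ring(v, tlist, ntl, tris, neigh, deg, vtris, old_neigh,
                  old_vedge, old_deg, vedge, flip_eid, fa, fb):
    """Rebuild the ordered ring of v from an unordered incident-triangle
    list; returns False when the triangles do not chain into one cycle."""
    ps = np.empty(MAXD, dtype=np.int32)
    qs = np.empty(MAXD, dtype=np.int32)
    for m in range(ntl):
        t = tlist[m]
        if tris[t, 0] == v:
            ps[m] = tris[t, 1]
            qs[m] = tris[t, 2]
        elif tris[t, 1] == v:
            ps[m] = tris[t, 2]
            qs[m] = tris[t, 0]
        else:
            ps[m] = tris[t, 0]
            qs[m] = tris[t, 1]
    cur = 0
    for step in range(ntl):
        p = ps[cur]
        neigh[v, step] = p
        vtris[v, step] = tlist[cur]
        # edge id to p
        if (v == fa and p == fb) or (v == fb and p == fa):
            vedge[v, step] = flip_eid
        else:
            eid = -1
            for ii in range(old_deg):
                if old_neigh[ii] == p:
                    eid = old_vedge[ii]
                    break
            vedge[v, step] = eid
        # advance: find triangle whose p == qs[cur]
        nxt_ = -1
        for m in range(ntl):
            if ps[m] == qs[cur]:
                nxt_ = m
                break
        if nxt_ < 0:
            return False
        cur = nxt_
    deg[v] = ntl
    return cur == 0


@njit(cache=True)
def topo_flip(k, tris, neigh, deg, vtris, vedge, edges, etris):
    """Flip edge k.  Returns 0 on success, -1 degree violation, -2 duplicate
    edge, -3 malformed ring (should not happen on a valid mesh)."""
    a = edges[k, 0]
    b = edges[k, 1]
    t_ab = etris[k, 0]
    t_ba = etris[k, 1]
    # ensure t_ab traverses a -> b
    trav = False
    for i in range(3):
        if tris[t_ab, i] == a and tris[t_ab, (i + 1) % 3] == b:
            trav = True
            break
    if not trav:
        t_ab, t_ba = t_ba, t_ab
    c = -1
    d = -1
    for i in range(3):
        w = tris[t_ab, i]
        if w != a and w != b:
            c = w
        w = tris[t_ba, i]
        if w != a and w != b:
            d = w
    if deg[a] <= 3 or deg[b] <= 3:
        return -1
    if deg[c] >= MAXD or deg[d] >= MAXD:
        return -1
    for ii in range(deg[c]):
        if neigh[c, ii] == d:
            return -2

    # locate the four quad-boundary edges before rewiring
    e_bc = _find_edge(b, c, neigh, deg, vedge)
    e_ca = _find_edge(c, a, neigh, deg, vedge)
    e_ad = _find_edge(a, d, neigh, deg, vedge)
    e_db = _find_edge(d, b, neigh, deg, vedge)

    tris[t_ab, 0] = d
    tris[t_ab, 1] = b
    tris[t_ab, 2] = c
    tris[t_ba, 0] = c
    tris[t_ba, 1] = a
    tris[t_ba, 2] = d
    if c < d:
        edges[k, 0] = c
        edges[k, 1] = d
    else:
        edges[k, 0] = d
        edges[k, 1] = c
    etris[k, 0] = t_ab
    etris[k, 1] = t_ba
    # (c,a) moves from t_ab to t_ba; (d,b) moves from t_ba to t_ab
    for col in range(2):
        if etris[e_ca, col] == t_ab:
            etris[e_ca, col] = t_ba
        if etris[e_db, col] == t_ba:
            etris[e_db, col] = t_ab

    quad = np.empty(4, dtype=np.int32)
    quad[0] = a
    quad[1] = b
    quad[2] = c
    quad[3] = d
    tbuf = np.empty(MAXD, dtype=np.int32)
    onei = np.empty(MAXD, dtype=np.int32)
    oved = np.empty(MAXD, dtype=np.int32)
    for m in range(4):
        v = quad[m]
        odeg = deg[v]
        for ii in range(odeg):
            onei[ii] = neigh[v, ii]
            oved[ii] = vedge[v, ii]
        ntl = 0
        for ii in range(odeg):
            t = vtris[v, ii]
            if (tris[t, 0] == v) or (tris[t, 1] == v) or (tris[t, 2] == v):
                tbuf[ntl] = t
                ntl += 1
        if v == c:
            tbuf[ntl] = t_ba
            ntl += 1
        elif v == d:
            tbuf[ntl] = t_ab
            ntl += 1
        if not _rebuild_ring(v, tbuf, ntl, tris, neigh, deg, vtris,
                             onei, oved, odeg, vedge, k, c, d):
            return -3
    return 0


# ---------------------------------------------------------------------------
# snapshot / restore helpers for the incremental moves
# ---------------------------------------------------------------------------

@njit(cache=True)
def _save_geom(slist, ns, varea, amix, vnorm, c1a, c2a, t1a, t2a, evert,
               host_inc, inc_dir, gbuf, dbuf):
    for k in range(ns):
        v = slist[k]
        gbuf[k, 0] = varea[v]
        gbuf[k, 1] = amix[v]
        gbuf[k, 2] = vnorm[v, 0]
        gbuf[k, 3] = vnorm[v, 1]
        gbuf[k, 4] = vnorm[v, 2]
        gbuf[k, 5] = c1a[v]
        gbuf[k, 6] = c2a[v]
        gbuf[k, 7] = t1a[v, 0]
        gbuf[k, 8] = t1a[v, 1]
        gbuf[k, 9] = t1a[v, 2]
        gbuf[k, 10] = t2a[v, 0]
        gbuf[k, 11] = t2a[v, 1]
        gbuf[k, 12] = t2a[v, 2]
        gbuf[k, 13] = evert[v]
        j = host_inc[v]
        if j >= 0:
            dbuf[k, 0] = inc_dir[j, 0]
            dbuf[k, 1] = inc_dir[j, 1]
            dbuf[k, 2] = inc_dir[j, 2]


@njit(cache=True)
def _restore_geom(slist, ns, varea, amix, vnorm, c1a, c2a, t1a, t2a, evert,
                  host_inc, inc_dir, gbuf, dbuf):
    for k in range(ns):
        v = slist[k]
        varea[v] = gbuf[k, 0]
        amix[v] = gbuf[k, 1]
        vnorm[v, 0] = gbuf[k, 2]
        vnorm[v, 1] = gbuf[k, 3]
        vnorm[v, 2] = gbuf[k, 4]
        c1a[v] = gbuf[k, 5]
        c2a[v] = gbuf[k, 6]
        t1a[v, 0] = gbuf[k, 7]
        t1a[v, 1] = gbuf[k, 8]
        t1a[v, 2] = gbuf[k, 9]
        t2a[v, 0] = gbuf[k, 10]
        t2a[v, 1] = gbuf[k, 11]
        t2a[v, 2] = gbuf[k, 12]
        evert[v] = gbuf[k, 13]
        j = host_inc[v]
        if j >= 0:
            inc_dir[j, 0] = dbuf[k, 0]
            inc_dir[j, 1] = dbuf[k, 1]
            inc_dir[j, 2] = dbuf[k, 2]


@njit(cache=True)
def _reproject_dir(v, host_inc, inc_dir, vnorm, t1a):
    """Keep an inclusion's orientation tangent after its host normal moved."""
    j = host_inc[v]
    if j < 0:
        return
    dx, dy, dz = inc_dir[j, 0], inc_dir[j, 1], inc_dir[j, 2]
    nx, ny, nz = vnorm[v, 0], vnorm[v, 1], vnorm[v, 2]
    dd = dx * nx + dy * ny + dz * nz
    dx -= dd * nx
    dy -= dd * ny
    dz -= dd * nz
    nn = math.sqrt(dx * dx + dy * dy + dz * dz)
    if nn < 1e-12:
        inc_dir[j, 0] = t1a[v, 0]
        inc_dir[j, 1] = t1a[v, 1]
        inc_dir[j, 2] = t1a[v, 2]
    else:
        inc_dir[j, 0] = dx / nn
        inc_dir[j, 1] = dy / nn
        inc_dir[j, 2] = dz / nn


@njit(cache=True)
def _refresh_set(slist, ns, pos, neigh, deg, vtris, tris, L, per,
                 tri_area, tri_norm, varea, amix, vnorm, c1a, c2a,
                 t1a, t2a, evert, mem, host_inc, inc_type, inc_dir,
                 tp_kind, tp_par):
    for k in range(ns):
        v = slist[k]
        vertex_geometry(v, pos, neigh, deg, vtris, tris, L, per,
                        tri_area, tri_norm, varea, amix, vnorm,
                        c1a, c2a, t1a, t2a)
        _reproject_dir(v, host_inc, inc_dir, vnorm, t1a)
    for k in range(ns):
        v = slist[k]
        evert[v] = vertex_energy(v, mem, varea, c1a, c2a, t1a, t2a,
                                 host_inc, inc_type, inc_dir, tp_kind, tp_par)


# ---------------------------------------------------------------------------
# trial moves
# ---------------------------------------------------------------------------

@njit(cache=True)
def try_vertex_move(v, pos, tris, neigh, deg, vtris, vedge, edges, etris,
                    L, per, tri_area, tri_norm, tri_vol, amix, varea, vnorm,
                    c1a, c2a, t1a, t2a, evert,
                    inc_host, inc_type, inc_dir, host_inc,
                    tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
                    mem, ens, cons, conf_kind, conf_par,
                    force_v, force_k, anchor, delta,
                    nc, head, nxt, prv, cell_of,
                    tot, mark, stampbox):
    """One Metropolis trial displacement of vertex v.

    Returns 0 accepted, 1 hard-constraint rejection, 2 Metropolis rejection.
    """
    n_t = tris.shape[0]
    ox, oy, oz = pos[v, 0], pos[v, 1], pos[v, 2]
    nx_ = ox + (2.0 * np.random.random() - 1.0) * delta
    ny_ = oy + (2.0 * np.random.random() - 1.0) * delta
    nz_ = oz + (2.0 * np.random.random() - 1.0) * delta
    if not conf_ok(nx_, ny_, nz_, conf_kind, conf_par):
        return 1
    lmin2 = cons[CONS_LMIN] * cons[CONS_LMIN]
    lmax2 = cons[CONS_LMAX] * cons[CONS_LMAX]
    dv = deg[v]
    for ii in range(dv):
        u = neigh[v, ii]
        dx, dy, dz = mi3(pos[u, 0], pos[u, 1], pos[u, 2], nx_, ny_, nz_, L, per)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < lmin2 or d2 > lmax2:
            return 1
    dmin2 = cons[CONS_DMIN] * cons[CONS_DMIN]
    if too_close(v, nx_, ny_, nz_, dmin2, pos, L, per, nc, head, nxt):
        return 1

    # refresh set: v plus its one-ring
    slist = np.empty(MAXS, dtype=np.int32)
    slist[0] = v
    for ii in range(dv):
        slist[1 + ii] = neigh[v, ii]
    ns = 1 + dv

    stampbox[0] += 1
    stamp = stampbox[0]
    e_before = 0.0
    for k in range(ns):
        e_before += evert[slist[k]]
    e_before += local_pair_sum(slist, ns, mark, stamp, pos, vnorm, L, per,
                               neigh, deg, host_inc, inc_type, inc_dir,
                               ppA, ppB, ppC, ppn, ppth0, ppg0)
    e_before += global_energy(tot[0], tot[1], tot[2], L[0], L[1], n_t, ens)
    if force_v == v:
        e_before += force_energy(force_v, force_k, anchor, pos)

    gbuf = np.empty((MAXS, 14))
    dbuf = np.empty((MAXS, 3))
    _save_geom(slist, ns, varea, amix, vnorm, c1a, c2a, t1a, t2a, evert,
               host_inc, inc_dir, gbuf, dbuf)
    tbuf = np.empty((MAXD, 5))
    for ii in range(dv):
        t = vtris[v, ii]
        tbuf[ii, 0] = tri_area[t]
        tbuf[ii, 1] = tri_vol[t]
        tbuf[ii, 2] = tri_norm[t, 0]
        tbuf[ii, 3] = tri_norm[t, 1]
        tbuf[ii, 4] = tri_norm[t, 2]
    a_old, v_old, m_old = tot[0], tot[1], tot[2]
    m_before = 0.0
    for k in range(ns):
        u = slist[k]
        m_before += (c1a[u] + c2a[u]) * varea[u]

    pos[v, 0] = nx_
    pos[v, 1] = ny_
    pos[v, 2] = nz_
    d_a = 0.0
    d_v = 0.0
    for ii in range(dv):
        t = vtris[v, ii]
        d_a -= tri_area[t]
        d_v -= tri_vol[t]
        tri_update(t, pos, tris, L, per, tri_area, tri_norm, tri_vol)
        d_a += tri_area[t]
        d_v += tri_vol[t]

    # dihedral bound on every edge whose faces moved: edges incident to v
    # and the opposite (ring-perimeter) edges of v's triangles
    mincos = cons[CONS_MINCOS]
    ok = True
    for ii in range(dv):
        e1 = vedge[v, ii]
        ca = (tri_norm[etris[e1, 0], 0] * tri_norm[etris[e1, 1], 0]
              + tri_norm[etris[e1, 0], 1] * tri_norm[etris[e1, 1], 1]
              + tri_norm[etris[e1, 0], 2] * tri_norm[etris[e1, 1], 2])
        if ca < mincos:
            ok = False
            break
        u1 = neigh[v, ii]
        u2 = neigh[v, ii + 1] if ii + 1 < dv else neigh[v, 0]
        e2 = _find_edge(u1, u2, neigh, deg, vedge)
        ca = (tri_norm[etris[e2, 0], 0] * tri_norm[etris[e2, 1], 0]
              + tri_norm[etris[e2, 0], 1] * tri_norm[etris[e2, 1], 1]
              + tri_norm[etris[e2, 0], 2] * tri_norm[etris[e2, 1], 2])
        if ca < mincos:
            ok = False
            break
    if not ok:
        pos[v, 0] = ox
        pos[v, 1] = oy
        pos[v, 2] = oz
        for ii in range(dv):
            t = vtris[v, ii]
            tri_area[t] = tbuf[ii, 0]
            tri_vol[t] = tbuf[ii, 1]
            tri_norm[t, 0] = tbuf[ii, 2]
            tri_norm[t, 1] = tbuf[ii, 3]
            tri_norm[t, 2] = tbuf[ii, 4]
        return 1

    _refresh_set(slist, ns, pos, neigh, deg, vtris, tris, L, per,
                 tri_area, tri_norm, varea, amix, vnorm, c1a, c2a,
                 t1a, t2a, evert, mem, host_inc, inc_type, inc_dir,
                 tp_kind, tp_par)
    m_after = 0.0
    for k in range(ns):
        u = slist[k]
        m_after += (c1a[u] + c2a[u]) * varea[u]
    tot[0] = a_old + d_a
    tot[1] = v_old + d_v
    tot[2] = m_old + (m_after - m_before)

    stampbox[0] += 1
    stamp = stampbox[0]
    e_after = 0.0
    for k in range(ns):
        e_after += evert[slist[k]]
    e_after += local_pair_sum(slist, ns, mark, stamp, pos, vnorm, L, per,
                              neigh, deg, host_inc, inc_type, inc_dir,
                              ppA, ppB, ppC, ppn, ppth0, ppg0)
    e_after += global_energy(tot[0], tot[1], tot[2], L[0], L[1], n_t, ens)
    if force_v == v:
        e_after += force_energy(force_v, force_k, anchor, pos)

    de = e_after - e_before
    if de <= 0.0 or np.random.random() < math.exp(-de):
        tot[3] += de
        cell_move(v, nx_, ny_, nz_, L, per, nc, head, nxt, prv, cell_of)
        return 0

    pos[v, 0] = ox
    pos[v, 1] = oy
    pos[v, 2] = oz
    for ii in range(dv):
        t = vtris[v, ii]
        tri_area[t] = tbuf[ii, 0]
        tri_vol[t] = tbuf[ii, 1]
        tri_norm[t, 0] = tbuf[ii, 2]
        tri_norm[t, 1] = tbuf[ii, 3]
        tri_norm[t, 2] = tbuf[ii, 4]
    _restore_geom(slist, ns, varea, amix, vnorm, c1a, c2a, t1a, t2a, evert,
                  host_inc, inc_dir, gbuf, dbuf)
    tot[0] = a_old
    tot[1] = v_old
    tot[2] = m_old
    return 2


@njit(cache=True)
def try_flip(k, pos, tris, neigh, deg, vtris, vedge, edges, etris,
             L, per, tri_area, tri_norm, tri_vol, amix, varea, vnorm,
             c1a, c2a, t1a, t2a, evert,
             inc_host, inc_type, inc_dir, host_inc,
             tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
             mem, ens, cons, tot, mark, stampbox):
    """One Metropolis trial of the Alexander link flip of edge k."""
    n_t = tris.shape[0]
    a = edges[k, 0]
    b = edges[k, 1]
    t_ab = etris[k, 0]
    t_ba = etris[k, 1]
    trav = False
    for i in range(3):
        if tris[t_ab, i] == a and tris[t_ab, (i + 1) % 3] == b:
            trav = True
            break
    if not trav:
        t_ab, t_ba = t_ba, t_ab
    c = -1
    d = -1
    for i in range(3):
        w = tris[t_ab, i]
        if w != a and w != b:
            c = w
        w = tris[t_ba, i]
        if w != a and w != b:
            d = w
    if deg[a] <= 3 or deg[b] <= 3 or deg[c] >= MAXD or deg[d] >= MAXD:
        return 1
    for ii in range(deg[c]):
        if neigh[c, ii] == d:
            return 1
    dx, dy, dz = mi3(pos[d, 0], pos[d, 1], pos[d, 2],
                     pos[c, 0], pos[c, 1], pos[c, 2], L, per)
    d2 = dx * dx + dy * dy + dz * dz
    if d2 < cons[CONS_LMIN] ** 2 or d2 > cons[CONS_LMAX] ** 2:
        return 1

    quad = np.empty(4, dtype=np.int32)
    quad[0] = a
    quad[1] = b
    quad[2] = c
    quad[3] = d

    stampbox[0] += 1
    e_before = evert[a] + evert[b] + evert[c] + evert[d]
    e_before += local_pair_sum(quad, 4, mark, stampbox[0], pos, vnorm, L, per,
                               neigh, deg, host_inc, inc_type, inc_dir,
                               ppA, ppB, ppC, ppn, ppth0, ppg0)
    e_before += global_energy(tot[0], tot[1], tot[2], L[0], L[1], n_t, ens)

    # snapshots
    sn_nei = np.empty((4, MAXD), dtype=np.int32)
    sn_vtr = np.empty((4, MAXD), dtype=np.int32)
    sn_ved = np.empty((4, MAXD), dtype=np.int32)
    sn_deg = np.empty(4, dtype=np.int32)
    for m in range(4):
        v = quad[m]
        sn_deg[m] = deg[v]
        for ii in range(MAXD):
            sn_nei[m, ii] = neigh[v, ii]
            sn_vtr[m, ii] = vtris[v, ii]
            sn_ved[m, ii] = vedge[v, ii]
    sn_tris = np.empty((2, 3), dtype=np.int32)
    for i in range(3):
        sn_tris[0, i] = tris[t_ab, i]
        sn_tris[1, i] = tris[t_ba, i]
    sn_edge = np.empty(2, dtype=np.int32)
    sn_edge[0] = edges[k, 0]
    sn_edge[1] = edges[k, 1]
    e_bc = _find_edge(b, c, neigh, deg, vedge)
    e_ca = _find_edge(c, a, neigh, deg, vedge)
    e_ad = _find_edge(a, d, neigh, deg, vedge)
    e_db = _find_edge(d, b, neigh, deg, vedge)
    eids = np.empty(5, dtype=np.int32)
    eids[0] = k
    eids[1] = e_bc
    eids[2] = e_ca
    eids[3] = e_ad
    eids[4] = e_db
    sn_etr = np.empty((5, 2), dtype=np.int32)
    for m in range(5):
        sn_etr[m, 0] = etris[eids[m], 0]
        sn_etr[m, 1] = etris[eids[m], 1]
    sn_tc = np.empty((2, 5))
    tt = t_ab
    for m in range(2):
        sn_tc[m, 0] = tri_area[tt]
        sn_tc[m, 1] = tri_vol[tt]
        sn_tc[m, 2] = tri_norm[tt, 0]
        sn_tc[m, 3] = tri_norm[tt, 1]
        sn_tc[m, 4] = tri_norm[tt, 2]
        tt = t_ba
    gbuf = np.empty((4, 14))
    dbuf = np.empty((4, 3))
    _save_geom(quad, 4, varea, amix, vnorm, c1a, c2a, t1a, t2a, evert,
               host_inc, inc_dir, gbuf, dbuf)
    a_old, v_old, m_old = tot[0], tot[1], tot[2]
    m_before = 0.0
    for m in range(4):
        u = quad[m]
        m_before += (c1a[u] + c2a[u]) * varea[u]

    st = topo_flip(k, tris, neigh, deg, vtris, vedge, edges, etris)
    if st != 0:
        return 1

    d_a = -sn_tc[0, 0] - sn_tc[1, 0]
    d_v = -sn_tc[0, 1] - sn_tc[1, 1]
    tri_update(t_ab, pos, tris, L, per, tri_area, tri_norm, tri_vol)
    tri_update(t_ba, pos, tris, L, per, tri_area, tri_norm, tri_vol)
    d_a += tri_area[t_ab] + tri_area[t_ba]
    d_v += tri_vol[t_ab] + tri_vol[t_ba]

    mincos = cons[CONS_MINCOS]
    ok = True
    for m in range(5):
        e1 = eids[m]
        ca = (tri_norm[etris[e1, 0], 0] * tri_norm[etris[e1, 1], 0]
              + tri_norm[etris[e1, 0], 1] * tri_norm[etris[e1, 1], 1]
              + tri_norm[etris[e1, 0], 2] * tri_norm[etris[e1, 1], 2])
        if ca < mincos:
            ok = False
            break

    if ok:
        _refresh_set(quad, 4, pos, neigh, deg, vtris, tris, L, per,
                     tri_area, tri_norm, varea, amix, vnorm, c1a, c2a,
                     t1a, t2a, evert, mem, host_inc, inc_type, inc_dir,
                     tp_kind, tp_par)
        m_after = 0.0
        for m in range(4):
            u = quad[m]
            m_after += (c1a[u] + c2a[u]) * varea[u]
        tot[0] = a_old + d_a
        tot[1] = v_old + d_v
        tot[2] = m_old + (m_after - m_before)
        stampbox[0] += 1
        e_after = evert[a] + evert[b] + evert[c] + evert[d]
        e_after += local_pair_sum(quad, 4, mark, stampbox[0], pos, vnorm,
                                  L, per, neigh, deg, host_inc, inc_type,
                                  inc_dir, ppA, ppB, ppC, ppn, ppth0, ppg0)
        e_after += global_energy(tot[0], tot[1], tot[2], L[0], L[1], n_t, ens)
        de = e_after - e_before
        if de <= 0.0 or np.random.random() < math.exp(-de):
            tot[3] += de
            return 0

    # restore
    for m in range(4):
        v = quad[m]
        deg[v] = sn_deg[m]
        for ii in range(MAXD):
            neigh[v, ii] = sn_nei[m, ii]
            vtris[v, ii] = sn_vtr[m, ii]
            vedge[v, ii] = sn_ved[m, ii]
    for i in range(3):
        tris[t_ab, i] = sn_tris[0, i]
        tris[t_ba, i] = sn_tris[1, i]
    edges[k, 0] = sn_edge[0]
    edges[k, 1] = sn_edge[1]
    for m in range(5):
        etris[eids[m], 0] = sn_etr[m, 0]
        etris[eids[m], 1] = sn_etr[m, 1]
    tt = t_ab
    for m in range(2):
        tri_area[tt] = sn_tc[m, 0]
        tri_vol[tt] = sn_tc[m, 1]
        tri_norm[tt, 0] = sn_tc[m, 2]
        tri_norm[tt, 1] = sn_tc[m, 3]
        tri_norm[tt, 2] = sn_tc[m, 4]
        tt = t_ba
    _restore_geom(quad, 4, varea, amix, vnorm, c1a, c2a, t1a, t2a, evert,
                  host_inc, inc_dir, gbuf, dbuf)
    tot[0] = a_old
    tot[1] = v_old
    tot[2] = m_old
    return 1 if not ok else 2


@njit(cache=True)
def try_incl_move(j, rot_amp, pos, neigh, deg, L, per, varea, vnorm,
                  c1a, c2a, t1a, t2a, evert,
                  inc_host, inc_type, inc_dir, host_inc,
                  tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
                  mem, mark, stampbox, tot):
    """Rotate inclusion j in its tangent plane, or hop it to an adjacent
    unoccupied vertex with parallel transport of its orientation."""
    v = inc_host[j]
    if np.random.random() < 0.5:
        # in-plane rotation
        phi = (2.0 * np.random.random() - 1.0) * rot_amp
        cph = math.cos(phi)
        sph = math.sin(phi)
        nx, ny, nz = vnorm[v, 0], vnorm[v, 1], vnorm[v, 2]
        dx, dy, dz = inc_dir[j, 0], inc_dir[j, 1], inc_dir[j, 2]
        cx = ny * dz - nz * dy
        cy = nz * dx - nx * dz
        cz = nx * dy - ny * dx
        ndx = dx * cph + cx * sph
        ndy = dy * cph + cy * sph
        ndz = dz * cph + cz * sph
        slist = np.empty(1, dtype=np.int32)
        slist[0] = v
        stampbox[0] += 1
        e_before = evert[v] + local_pair_sum(
            slist, 1, mark, stampbox[0], pos, vnorm, L, per, neigh, deg,
            host_inc, inc_type, inc_dir, ppA, ppB, ppC, ppn, ppth0, ppg0)
        odx, ody, odz = dx, dy, dz
        oe = evert[v]
        inc_dir[j, 0] = ndx
        inc_dir[j, 1] = ndy
        inc_dir[j, 2] = ndz
        evert[v] = vertex_energy(v, mem, varea, c1a, c2a, t1a, t2a,
                                 host_inc, inc_type, inc_dir, tp_kind, tp_par)
        stampbox[0] += 1
        e_after = evert[v] + local_pair_sum(
            slist, 1, mark, stampbox[0], pos, vnorm, L, per, neigh, deg,
            host_inc, inc_type, inc_dir, ppA, ppB, ppC, ppn, ppth0, ppg0)
        de = e_after - e_before
        if de <= 0.0 or np.random.random() < math.exp(-de):
            tot[3] += de
            return 0
        inc_dir[j, 0] = odx
        inc_dir[j, 1] = ody
        inc_dir[j, 2] = odz
        evert[v] = oe
        return 2

    # hop to a random adjacent vertex
    ii = int(np.random.randint(0, deg[v]))
    u = neigh[v, ii]
    if host_inc[u] >= 0:
        return 1
    ok, pvx, pvy, pvz, pux, puy, puz, rx, ry, rz = pair_geometry(
        v, u, pos, vnorm, L, per)
    if not ok:
        return 1
    dx, dy, dz = inc_dir[j, 0], inc_dir[j, 1], inc_dir[j, 2]
    nvx, nvy, nvz = vnorm[v, 0], vnorm[v, 1], vnorm[v, 2]
    nux, nuy, nuz = vnorm[u, 0], vnorm[u, 1], vnorm[u, 2]
    # components of D in the (p, n x p) frame at v
    bx = nvy * pvz - nvz * pvy
    by = nvz * pvx - nvx * pvz
    bz = nvx * pvy - nvy * pvx
    ca_ = dx * pvx + dy * pvy + dz * pvz
    sa_ = dx * bx + dy * by + dz * bz
    bx = nuy * puz - nuz * puy
    by = nuz * pux - nux * puz
    bz = nux * puy - nuy * pux
    ndx = ca_ * pux + sa_ * bx
    ndy = ca_ * puy + sa_ * by
    ndz = ca_ * puz + sa_ * bz
    nn = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    ndx /= nn
    ndy /= nn
    ndz /= nn

    slist = np.empty(2, dtype=np.int32)
    slist[0] = v
    slist[1] = u
    stampbox[0] += 1
    e_before = evert[v] + evert[u] + local_pair_sum(
        slist, 2, mark, stampbox[0], pos, vnorm, L, per, neigh, deg,
        host_inc, inc_type, inc_dir, ppA, ppB, ppC, ppn, ppth0, ppg0)
    oev, oeu = evert[v], evert[u]
    odx, ody, odz = dx, dy, dz
    host_inc[v] = -1
    host_inc[u] = j
    inc_host[j] = u
    inc_dir[j, 0] = ndx
    inc_dir[j, 1] = ndy
    inc_dir[j, 2] = ndz
    evert[v] = vertex_energy(v, mem, varea, c1a, c2a, t1a, t2a,
                             host_inc, inc_type, inc_dir, tp_kind, tp_par)
    evert[u] = vertex_energy(u, mem, varea, c1a, c2a, t1a, t2a,
                             host_inc, inc_type, inc_dir, tp_kind, tp_par)
    stampbox[0] += 1
    e_after = evert[v] + evert[u] + local_pair_sum(
        slist, 2, mark, stampbox[0], pos, vnorm, L, per, neigh, deg,
        host_inc, inc_type, inc_dir, ppA, ppB, ppC, ppn, ppth0, ppg0)
    de = e_after - e_before
    if de <= 0.0 or np.random.random() < math.exp(-de):
        tot[3] += de
        return 0
    host_inc[u] = -1
    host_inc[v] = j
    inc_host[j] = v
    inc_dir[j, 0] = odx
    inc_dir[j, 1] = ody
    inc_dir[j, 2] = odz
    evert[v] = oev
    evert[u] = oeu
    return 2


@njit(cache=True)
def audit_constraints(pos, neigh, deg, edges, etris, tri_norm, L, per, cons,
                      nc, head, nxt, conf_kind, conf_par):
    """Count hard-constraint violations over the whole configuration."""
    bad = 0
    lmin2 = cons[CONS_LMIN] ** 2
    lmax2 = cons[CONS_LMAX] ** 2
    for k in range(edges.shape[0]):
        a = edges[k, 0]
        b = edges[k, 1]
        dx, dy, dz = mi3(pos[b, 0], pos[b, 1], pos[b, 2],
                         pos[a, 0], pos[a, 1], pos[a, 2], L, per)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < lmin2 - 1e-12 or d2 > lmax2 + 1e-12:
            bad += 1
        ca = (tri_norm[etris[k, 0], 0] * tri_norm[etris[k, 1], 0]
              + tri_norm[etris[k, 0], 1] * tri_norm[etris[k, 1], 1]
              + tri_norm[etris[k, 0], 2] * tri_norm[etris[k, 1], 2])
        if ca < cons[CONS_MINCOS] - 1e-12:
            bad += 1
    dmin2 = cons[CONS_DMIN] ** 2
    for v in range(pos.shape[0]):
        if too_close(v, pos[v, 0], pos[v, 1], pos[v, 2], dmin2 - 1e-12,
                     pos, L, per, nc, head, nxt):
            bad += 1
        if not conf_ok(pos[v, 0], pos[v, 1], pos[v, 2], conf_kind, conf_par):
            bad += 1
    return bad


@njit(cache=True)
def recompute_state(pos, neigh, deg, vtris, tris, L, per,
                    tri_area, tri_norm, tri_vol, amix, varea, vnorm,
                    c1a, c2a, t1a, t2a, evert, mem, ens,
                    inc_host, inc_type, inc_dir, host_inc, tp_kind, tp_par,
                    ppA, ppB, ppC, ppn, ppth0, ppg0,
                    force_v, force_k, anchor, tot, reproject):
    """Full recomputation of caches and totals (init / resync / box move)."""
    all_tris_update(pos, tris, L, per, tri_area, tri_norm, tri_vol)
    all_geometry(pos, neigh, deg, vtris, tris, L, per, tri_area, tri_norm,
                 varea, amix, vnorm, c1a, c2a, t1a, t2a)
    if reproject:
        for v in range(pos.shape[0]):
            _reproject_dir(v, host_inc, inc_dir, vnorm, t1a)
    a = 0.0
    vol = 0.0
    for t in range(tris.shape[0]):
        a += tri_area[t]
        vol += tri_vol[t]
    m = 0.0
    esum = 0.0
    for v in range(pos.shape[0]):
        evert[v] = vertex_energy(v, mem, varea, c1a, c2a, t1a, t2a,
                                 host_inc, inc_type, inc_dir, tp_kind, tp_par)
        esum += evert[v]
        m += (c1a[v] + c2a[v]) * varea[v]
    esum += full_pair_sum(pos, vnorm, L, per, neigh, deg, inc_host, host_inc,
                          inc_type, inc_dir, ppA, ppB, ppC, ppn, ppth0, ppg0)
    esum += global_energy(a, vol, m, L[0], L[1], tris.shape[0], ens)
    esum += force_energy(force_v, force_k, anchor, pos)
    tot[0] = a
    tot[1] = vol
    tot[2] = m
    tot[3] = esum


@njit(cache=True)
def try_box_move(box_amp, pos, tris, neigh, deg, vtris, vedge, edges, etris,
                 L, per, tri_area, tri_norm, tri_vol, amix, varea, vnorm,
                 c1a, c2a, t1a, t2a, evert,
                 inc_host, inc_type, inc_dir, host_inc,
                 tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
                 mem, ens, cons, conf_kind, conf_par,
                 force_v, force_k, anchor,
                 nc, head, nxt, prv, cell_of, tot,
                 pos_bak, dir_bak):
    """Isotropic in-plane rescaling of the frame (constant-tension move).

    Accepts with min(1, lambda^(2 N_v) exp(-dE)); the lambda term is the
    Jacobian of affinely rescaling the x, y coordinates of all vertices.
    """
    n = pos.shape[0]
    lam = 1.0 + (2.0 * np.random.random() - 1.0) * box_amp
    e_before = tot[3]
    for v in range(n):
        pos_bak[v, 0] = pos[v, 0]
        pos_bak[v, 1] = pos[v, 1]
        pos_bak[v, 2] = pos[v, 2]
    for j in range(inc_host.shape[0]):
        dir_bak[j, 0] = inc_dir[j, 0]
        dir_bak[j, 1] = inc_dir[j, 1]
        dir_bak[j, 2] = inc_dir[j, 2]
    a_old, v_old, m_old = tot[0], tot[1], tot[2]
    lx0, ly0 = L[0], L[1]
    for v in range(n):
        pos[v, 0] *= lam
        pos[v, 1] *= lam
    L[0] = lx0 * lam
    L[1] = ly0 * lam
    all_tris_update(pos, tris, L, per, tri_area, tri_norm, tri_vol)
    cells_build(pos, L, per, nc, head, nxt, prv, cell_of)
    bad = audit_constraints(pos, neigh, deg, edges, etris, tri_norm, L, per,
                            cons, nc, head, nxt, conf_kind, conf_par)
    if bad == 0:
        recompute_state(pos, neigh, deg, vtris, tris, L, per,
                        tri_area, tri_norm, tri_vol, amix, varea, vnorm,
                        c1a, c2a, t1a, t2a, evert, mem, ens,
                        inc_host, inc_type, inc_dir, host_inc, tp_kind, tp_par,
                        ppA, ppB, ppC, ppn, ppth0, ppg0,
                        force_v, force_k, anchor, tot, True)
        de = tot[3] - e_before
        logacc = -de + 2.0 * n * math.log(lam)
        if logacc >= 0.0 or np.random.random() < math.exp(logacc):
            return 0
    # restore
    for v in range(n):
        pos[v, 0] = pos_bak[v, 0]
        pos[v, 1] = pos_bak[v, 1]
        pos[v, 2] = pos_bak[v, 2]
    for j in range(inc_host.shape[0]):
        inc_dir[j, 0] = dir_bak[j, 0]
        inc_dir[j, 1] = dir_bak[j, 1]
        inc_dir[j, 2] = dir_bak[j, 2]
    L[0] = lx0
    L[1] = ly0
    all_tris_update(pos, tris, L, per, tri_area, tri_norm, tri_vol)
    all_geometry(pos, neigh, deg, vtris, tris, L, per, tri_area, tri_norm,
                 varea, amix, vnorm, c1a, c2a, t1a, t2a)
    for v in range(n):
        evert[v] = vertex_energy(v, mem, varea, c1a, c2a, t1a, t2a,
                                 host_inc, inc_type, inc_dir, tp_kind, tp_par)
    cells_build(pos, L, per, nc, head, nxt, prv, cell_of)
    tot[0] = a_old
    tot[1] = v_old
    tot[2] = m_old
    tot[3] = e_before
    return 1 if bad > 0 else 2


@njit(cache=True)
def mc_sweep(seed, frozen, pos, tris, neigh, deg, vtris, vedge, edges, etris,
             L, per, tri_area, tri_norm, tri_vol, amix, varea, vnorm,
             c1a, c2a, t1a, t2a, evert,
             inc_host, inc_type, inc_dir, host_inc,
             tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
             mem, ens, cons, conf_kind, conf_par,
             force_v, force_k, anchor, mv,
             nc, head, nxt, prv, cell_of,
             tot, mark, stampbox, pos_bak, dir_bak, stats):
    """One Monte Carlo sweep: N_T link-flip trials, N_v vertex trials and
    N_i inclusion trials on uniformly random targets, plus (at most) one
    box-resize trial when the tension ensemble is active.  In frozen-shape
    mode only the inclusion trials run."""
    np.random.seed(seed)
    n_v = pos.shape[0]
    n_t = tris.shape[0]
    n_e = edges.shape[0]
    n_i = inc_host.shape[0]
    if not frozen:
        for _ in range(n_t):
            k = int(np.random.randint(0, n_e))
            r = try_flip(k, pos, tris, neigh, deg, vtris, vedge, edges, etris,
                         L, per, tri_area, tri_norm, tri_vol, amix, varea,
                         vnorm, c1a, c2a, t1a, t2a, evert,
                         inc_host, inc_type, inc_dir, host_inc,
                         tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
                         mem, ens, cons, tot, mark, stampbox)
            stats[ST_FLIP, ST_TRY] += 1
            if r == 0:
                stats[ST_FLIP, ST_ACC] += 1
            elif r == 1:
                stats[ST_FLIP, ST_HARD] += 1
        for _ in range(n_v):
            v = int(np.random.randint(0, n_v))
            r = try_vertex_move(v, pos, tris, neigh, deg, vtris, vedge, edges,
                                etris, L, per, tri_area, tri_norm, tri_vol,
                                amix, varea, vnorm, c1a, c2a, t1a, t2a, evert,
                                inc_host, inc_type, inc_dir, host_inc,
                                tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0,
                                ppg0, mem, ens, cons, conf_kind, conf_par,
                                force_v, force_k, anchor, mv[MV_DELTA],
                                nc, head, nxt, prv, cell_of,
                                tot, mark, stampbox)
            stats[ST_VERT, ST_TRY] += 1
            if r == 0:
                stats[ST_VERT, ST_ACC] += 1
            elif r == 1:
                stats[ST_VERT, ST_HARD] += 1
    for _ in range(n_i):
        j = int(np.random.randint(0, n_i))
        r = try_incl_move(j, mv[MV_ROT], pos, neigh, deg, L, per, varea,
                          vnorm, c1a, c2a, t1a, t2a, evert,
                          inc_host, inc_type, inc_dir, host_inc,
                          tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
                          mem, mark, stampbox, tot)
        stats[ST_INCL, ST_TRY] += 1
        if r == 0:
            stats[ST_INCL, ST_ACC] += 1
        elif r == 1:
            stats[ST_INCL, ST_HARD] += 1
    if (not frozen) and ens[ENS_TAU_ON] > 0.0 \
            and np.random.random() < mv[MV_PBOX]:
        r = try_box_move(mv[MV_BOX], pos, tris, neigh, deg, vtris, vedge,
                         edges, etris, L, per, tri_area, tri_norm, tri_vol,
                         amix, varea, vnorm, c1a, c2a, t1a, t2a, evert,
                         inc_host, inc_type, inc_dir, host_inc,
                         tp_kind, tp_par, ppA, ppB, ppC, ppn, ppth0, ppg0,
                         mem, ens, cons, conf_kind, conf_par,
                         force_v, force_k, anchor,
                         nc, head, nxt, prv, cell_of, tot, pos_bak, dir_bak)
        stats[ST_BOX, ST_TRY] += 1
        if r == 0:
            stats[ST_BOX, ST_ACC] += 1
        elif r == 1:
            stats[ST_BOX, ST_HARD] += 1
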