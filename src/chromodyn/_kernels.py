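"""Compiled kernels: neighbour search, force accumulation, Langevin stepping.

Layout contract shared with the engine:

* particles are chromatin beads 0..M-1 followed by TF spheres;
* ``cls`` holds per-particle class codes (0 TU, 1 euchromatin,
  2 heterochromatin, 3 active TF, 4 inactive TF);
* ``eps4``/``rc2`` are dense 5x5 lookup tables (eps4 = 4*eps);
* bonds are (i, j, kind) arrays with kind 0 = FENE, 1 = harmonic backbone,
  2 = harmonic loop; angle triplets are implicit: (i, i+1, i+2) for every
  i < M-2;
* ``ffp`` packs scalar force-field constants, ``conf`` the confinement.

Neighbour search keeps two Verlet half-lists built in one cell-list pass:
bead-bead pairs (always WCA, cutoff 2^(1/6) sigma) with a tight list radius,
and pairs involving a TF (class-dependent truncated-shifted LJ, cutoff up to
1.8 sigma) with a wider one.  Both share the same skin, so a single
maximum-displacement trigger keeps both valid.

The integrator is BAOAB velocity-Verlet splitting of the underdamped
Langevin equation: friction and Gaussian noise enter through the exact
Ornstein-Uhlenbeck O-step between the two half-drifts, which keeps both the
kinetic temperature and configurational averages accurate at dt = 0.01.
Gaussian noise (one vector per particle per step) is pre-generated per chunk
by the caller.

Error codes returned in ``err``: 0 ok, 1 FENE overstretch (err[1], err[2]
are the bead indices), 2 neighbour-list overflow.
"""

import math

import numpy as np
from numba import njit

# ffp packing indices
KF, R0SQ, KH, RBAR_BB, RBAR_LOOP, KANG, KBT, RC_REP = range(8)

MAX_CELLS_PER_DIM = 96


def pack_ffp(params) -> np.ndarray:
    out = np.empty(8, dtype=np.float64)
    out[KF] = params.Kf
    out[R0SQ] = params.R0 * params.R0
    out[KH] = params.Kh
    out[RBAR_BB] = params.Rbar_backbone
    out[RBAR_LOOP] = params.Rbar_loop
    out[KANG] = params.kBT * params.lp / params.sigma
    out[KBT] = params.kBT
    out[RC_REP] = params.rc_rep
    return out


def pack_confinement(confinement) -> np.ndarray:
    out = np.zeros(4, dtype=np.float64)
    if confinement is not None and confinement.kind == "ellipsoid":
        out[0] = 1.0
        out[1:4] = confinement.semi_axes
    return out


def fibre_bond_arrays(fibre):
    kind_codes = {"fene": 0, "harmonic_backbone": 1, "harmonic_loop": 2}
    nb = len(fibre.bonds)
    bi = np.empty(nb, dtype=np.int64)
    bj = np.empty(nb, dtype=np.int64)
    bk = np.empty(nb, dtype=np.int8)
    for q, b in enumerate(fibre.bonds):
        bi[q], bj[q], bk[q] = b.i, b.j, kind_codes[b.kind]
    return bi, bj, bk


@njit(cache=True, fastmath=True)
def _build_pairs(pos, m_beads, rlist_bb, rlist_tf,
                 bb_i, bb_j, tf_i, tf_j, counts, head, nxt, cells):
    """One cell-list pass filling both half lists.

    counts[0] = bead-bead pairs within rlist_bb, counts[1] = TF-involving
    pairs within rlist_tf; counts[0] = -1 flags capacity overflow.
    ``head``/``nxt``/``cells`` are caller-owned scratch buffers (hoisted out
    of the hot path; rebuilds happen every ~20 steps).
    """
    n = pos.shape[0]
    r2bb = rlist_bb * rlist_bb
    r2tf = rlist_tf * rlist_tf
    xmin = pos[0, 0]; xmax = pos[0, 0]
    ymin = pos[0, 1]; ymax = pos[0, 1]
    zmin = pos[0, 2]; zmax = pos[0, 2]
    for i in range(n):
        if pos[i, 0] < xmin: xmin = pos[i, 0]
        if pos[i, 0] > xmax: xmax = pos[i, 0]
        if pos[i, 1] < ymin: ymin = pos[i, 1]
        if pos[i, 1] > ymax: ymax = pos[i, 1]
        if pos[i, 2] < zmin: zmin = pos[i, 2]
        if pos[i, 2] > zmax: zmax = pos[i, 2]
    rcell = rlist_bb if rlist_bb > rlist_tf else rlist_tf
    ncx = int((xmax - xmin) / rcell)
    ncy = int((ymax - ymin) / rcell)
    ncz = int((zmax - zmin) / rcell)
    if ncx < 1: ncx = 1
    if ncy < 1: ncy = 1
    if ncz < 1: ncz = 1
    if ncx > MAX_CELLS_PER_DIM: ncx = MAX_CELLS_PER_DIM
    if ncy > MAX_CELLS_PER_DIM: ncy = MAX_CELLS_PER_DIM
    if ncz > MAX_CELLS_PER_DIM: ncz = MAX_CELLS_PER_DIM
    lx = (xmax - xmin) / ncx + 1e-12
    ly = (ymax - ymin) / ncy + 1e-12
    lz = (zmax - zmin) / ncz + 1e-12
    ncells = ncx * ncy * ncz
    for c in range(ncells):
        head[c] = -1
    for i in range(n):
        cx = int((pos[i, 0] - xmin) / lx)
        cy = int((pos[i, 1] - ymin) / ly)
        cz = int((pos[i, 2] - zmin) / lz)
        if cx >= ncx: cx = ncx - 1
        if cy >= ncy: cy = ncy - 1
        if cz >= ncz: cz = ncz - 1
        cells[i, 0] = cx
        cells[i, 1] = cy
        cells[i, 2] = cz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = np.int32(i)
    cap_bb = bb_i.shape[0]
    cap_tf = tf_i.shape[0]
    n_bb = 0
    n_tf = 0
    for i in range(n):
        cx = cells[i, 0]
        cy = cells[i, 1]
        cz = cells[i, 2]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        i_is_bead = i < m_beads
        for ox in range(-1, 2):
            nx = cx + ox
            if nx < 0 or nx >= ncx:
                continue
            for oy in range(-1, 2):
                ny = cy + oy
                if ny < 0 or ny >= ncy:
                    continue
                for oz in range(-1, 2):
                    nz = cz + oz
                    if nz < 0 or nz >= ncz:
                        continue
                    j = head[(nx * ncy + ny) * ncz + nz]
                    while j >= 0:
                        if j > i:
                            dx = xi - pos[j, 0]
                            dy = yi - pos[j, 1]
                            dz = zi - pos[j, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if i_is_bead and j < m_beads:
                                if r2 < r2bb:
                                    if n_bb >= cap_bb:
                                        counts[0] = -1
                                        return
                                    bb_i[n_bb] = i
                                    bb_j[n_bb] = j
                                    n_bb += 1
                            else:
                                if r2 < r2tf:
                                    if n_tf >= cap_tf:
                                        counts[0] = -1
                                        return
                                    tf_i[n_tf] = i
                                    tf_j[n_tf] = j
                                    n_tf += 1
                        j = nxt[j]
    counts[0] = n_bb
    counts[1] = n_tf


@njit(cache=True, fastmath=True)
def _accumulate_forces(pos, frc, cls, eps4, rc2,
                       bb_i, bb_j, tf_i, tf_j, counts,
                       bond_i, bond_j, bond_kind, m_beads, ffp, conf,
                       fcap, tang, err):
    n = pos.shape[0]
    for i in range(n):
        frc[i, 0] = 0.0
        frc[i, 1] = 0.0
        frc[i, 2] = 0.0
    kbt4 = 4.0 * ffp[KBT]
    rcw = ffp[RC_REP]
    rc_rep2 = rcw * rcw
    if fcap > 0.0:
        # push-off mode: bounded soft-cosine repulsion for every pair
        # U = A(1 + cos(pi r / rc)); no attraction, finite force at r -> 0
        pref = fcap * math.pi / rcw
        for q in range(2):
            pi_arr = bb_i if q == 0 else tf_i
            pj_arr = bb_j if q == 0 else tf_j
            for p in range(counts[q]):
                i = pi_arr[p]
                j = pj_arr[p]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc_rep2 and r2 > 0.0:
                    r = math.sqrt(r2)
                    fr = pref * math.sin(math.pi * r / rcw) / r
                    frc[j, 0] += fr * dx
                    frc[j, 1] += fr * dy
                    frc[j, 2] += fr * dz
                    frc[i, 0] -= fr * dx
                    frc[i, 1] -= fr * dy
                    frc[i, 2] -= fr * dz
    else:
        # bead-bead: pure WCA with constant parameters
        for p in range(counts[0]):
            i = bb_i[p]
            j = bb_j[p]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc_rep2 and r2 > 0.0:
                inv2 = 1.0 / r2
                s6 = inv2 * inv2 * inv2
                fr = kbt4 * (12.0 * s6 * s6 - 6.0 * s6) * inv2
                frc[j, 0] += fr * dx
                frc[j, 1] += fr * dy
                frc[j, 2] += fr * dz
                frc[i, 0] -= fr * dx
                frc[i, 1] -= fr * dy
                frc[i, 2] -= fr * dz
        # TF-involving pairs: class-dependent truncated-shifted LJ
        for p in range(counts[1]):
            i = tf_i[p]
            j = tf_j[p]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            ci = cls[i]
            cj = cls[j]
            if r2 < rc2[ci, cj] and r2 > 0.0:
                inv2 = 1.0 / r2
                s6 = inv2 * inv2 * inv2
                fr = eps4[ci, cj] * (12.0 * s6 * s6 - 6.0 * s6) * inv2
                frc[j, 0] += fr * dx
                frc[j, 1] += fr * dy
                frc[j, 2] += fr * dz
                frc[i, 0] -= fr * dx
                frc[i, 1] -= fr * dy
                frc[i, 2] -= fr * dz
    # ellipsoidal wall (WCA-like along the scaled-radius normal)
    if conf[0] > 0.5:
        a = conf[1]
        b = conf[2]
        c = conf[3]
        # interior early-out: d >= (1-s)*c, so s < 1 - rcw/c implies no force
        s_in = 1.0 - rcw / c
        s_in2 = s_in * s_in if s_in > 0.0 else 0.0
        inva2 = 1.0 / (a * a)
        invb2 = 1.0 / (b * b)
        invc2 = 1.0 / (c * c)
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            s2 = x * x * inva2 + y * y * invb2 + z * z * invc2
            if s2 <= s_in2 or s2 <= 0.0:
                continue
            s = math.sqrt(s2)
            gx = x * inva2 / s
            gy = y * invb2 / s
            gz = z * invc2 / s
            gn = math.sqrt(gx * gx + gy * gy + gz * gz)
            d = (1.0 - s) / gn
            if d < 0.2:
                d = 0.2
            if d < rcw:
                inv2 = 1.0 / (d * d)
                s6 = inv2 * inv2 * inv2
                fmag = 4.0 * ffp[KBT] * (12.0 * s6 * s6 - 6.0 * s6) / d
                frc[i, 0] -= fmag * gx / gn
                frc[i, 1] -= fmag * gy / gn
                frc[i, 2] -= fmag * gz / gn
    # bonds.  In push-off mode FENE bonds are temporarily replaced by stout
    # harmonic springs (same Kh, rest length sigma): they cannot diverge, so
    # a transiently stretched bond recovers instead of aborting the run; the
    # engine verifies all bonds are < 0.95 R0 before enabling the FENE form.
    soft = fcap > 0.0
    for q in range(bond_i.shape[0]):
        i = bond_i[q]
        j = bond_j[q]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        k = bond_kind[q]
        if k == 0:
            if soft:
                r = math.sqrt(r2)
                fr = -2.0 * ffp[KH] * (r - 1.0) / r
            else:
                if r2 >= ffp[R0SQ]:
                    err[0] = 1
                    err[1] = i
                    err[2] = j
                    return
                fr = -ffp[KF] / (1.0 - r2 / ffp[R0SQ])
        else:
            r = math.sqrt(r2)
            rbar = ffp[RBAR_BB] if k == 1 else ffp[RBAR_LOOP]
            fr = -2.0 * ffp[KH] * (r - rbar) / r
        frc[j, 0] += fr * dx
        frc[j, 1] += fr * dy
        frc[j, 2] += fr * dz
        frc[i, 0] -= fr * dx
        frc[i, 1] -= fr * dy
        frc[i, 2] -= fr * dz
    # Kratky-Porod bending on consecutive triplets; tangent vectors and
    # inverse norms are shared between adjacent triplets via scratch arrays
    kang = ffp[KANG]
    nt = m_beads - 1
    tx = tang[0]
    ty = tang[1]
    tz = tang[2]
    tinv2 = tang[3]  # 1 / |t|^2
    tinv = tang[4]   # 1 / |t|
    for i in range(nt):
        ax = pos[i + 1, 0] - pos[i, 0]
        ay = pos[i + 1, 1] - pos[i, 1]
        az = pos[i + 1, 2] - pos[i, 2]
        tx[i] = ax
        ty[i] = ay
        tz[i] = az
        n2v = ax * ax + ay * ay + az * az
        tinv2[i] = 1.0 / n2v
        tinv[i] = 1.0 / math.sqrt(n2v)
    for i in range(m_beads - 2):
        t1x = tx[i]
        t1y = ty[i]
        t1z = tz[i]
        t2x = tx[i + 1]
        t2y = ty[i + 1]
        t2z = tz[i + 1]
        inv12 = tinv[i] * tinv[i + 1]
        dot = t1x * t2x + t1y * t2y + t1z * t2z
        cosv = dot * inv12
        # F_i = -kang * dcos/dt1 ; F_k = kang * dcos/dt2 ; F_j = -(F_i + F_k)
        c1v = cosv * tinv2[i]
        c2v = cosv * tinv2[i + 1]
        g1x = t2x * inv12 - c1v * t1x
        g1y = t2y * inv12 - c1v * t1y
        g1z = t2z * inv12 - c1v * t1z
        g2x = t1x * inv12 - c2v * t2x
        g2y = t1y * inv12 - c2v * t2y
        g2z = t1z * inv12 - c2v * t2z
        fix = -kang * g1x
        fiy = -kang * g1y
        fiz = -kang * g1z
        fkx = kang * g2x
        fky = kang * g2y
        fkz = kang * g2z
        frc[i, 0] += fix
        frc[i, 1] += fiy
        frc[i, 2] += fiz
        frc[i + 2, 0] += fkx
        frc[i + 2, 1] += fky
        frc[i + 2, 2] += fkz
        frc[i + 1, 0] -= fix + fkx
        frc[i + 1, 1] -= fiy + fky
        frc[i + 1, 2] -= fiz + fkz
    err[0] = 0


@njit(cache=True, fastmath=True)
def _run_chunk(pos, vel, frc, cls, eps4, rc2,
               bb_i, bb_j, tf_i, tf_j, counts,
               pos_ref, m_beads, rlist_bb, rlist_tf, skin_half2,
               bond_i, bond_j, bond_kind, ffp, conf,
               dt, c1, c2, fcap, noise, head, nxt, cells, tang, err):
    """Advance nsteps = noise.shape[0] BAOAB steps in place.

    Returns the number of completed steps (== nsteps unless err[0] != 0).
    """
    n = pos.shape[0]
    half = 0.5 * dt
    for step in range(noise.shape[0]):
        # BAOA sweep; max displacement since the last neighbour build is
        # tracked in the same pass
        maxd2 = 0.0
        for i in range(n):
            vx = vel[i, 0] + half * frc[i, 0]
            vy = vel[i, 1] + half * frc[i, 1]
            vz = vel[i, 2] + half * frc[i, 2]
            px = pos[i, 0] + half * vx
            py = pos[i, 1] + half * vy
            pz = pos[i, 2] + half * vz
            vx = c1 * vx + c2 * noise[step, i, 0]
            vy = c1 * vy + c2 * noise[step, i, 1]
            vz = c1 * vz + c2 * noise[step, i, 2]
            px += half * vx
            py += half * vy
            pz += half * vz
            pos[i, 0] = px
            pos[i, 1] = py
            pos[i, 2] = pz
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
            dx = px - pos_ref[i, 0]
            dy = py - pos_ref[i, 1]
            dz = pz - pos_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > skin_half2:
            _build_pairs(pos, m_beads, rlist_bb, rlist_tf,
                         bb_i, bb_j, tf_i, tf_j, counts, head, nxt, cells)
            if counts[0] < 0:
                err[0] = 2
                return step
            for i in range(n):
                pos_ref[i, 0] = pos[i, 0]
                pos_ref[i, 1] = pos[i, 1]
                pos_ref[i, 2] = pos[i, 2]
        _accumulate_forces(pos, frc, cls, eps4, rc2,
                           bb_i, bb_j, tf_i, tf_j, counts,
                           bond_i, bond_j, bond_kind, m_beads, ffp, conf,
                           fcap, tang, err)
        if err[0] != 0:
            return step
        for i in range(n):
            vel[i, 0] += half * frc[i, 0]
            vel[i, 1] += half * frc[i, 1]
            vel[i, 2] += half * frc[i, 2]
    return noise.shape[0]


@njit(cache=True)
def _detect_bound(pos, tu_idx, tf_idx, rc2, out):
    """out[k] = 1 iff any listed TF centre is within sqrt(rc2) of TU k."""
    for k in range(tu_idx.shape[0]):
        i = tu_idx[k]
        hit = 0
        for q in range(tf_idx.shape[0]):
            j = tf_idx[q]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz <= rc2:
                hit = 1
                break
        out[k] = hit


@njit(cache=True)
def _pairs_within(pos, cutoff, pair_i, pair_j):
    """All pairs with separation <= cutoff (cell list); -1 on overflow.

    Used for contact-map accumulation over trajectory frames.
    """
    counts = np.zeros(2, dtype=np.int64)
    dummy_i = np.empty(0, dtype=np.int32)
    dummy_j = np.empty(0, dtype=np.int32)
    n = pos.shape[0]
    head = np.empty(MAX_CELLS_PER_DIM ** 3, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    cells = np.empty((n, 3), dtype=np.int32)
    _build_pairs(pos, n, cutoff + 1e-9, 1e-9,
                 pair_i, pair_j, dummy_i, dummy_j, counts, head, nxt, cells)
    return counts[0]


def alloc_pair_arrays(n: int, per_particle: int = 128):
    cap = max(n * per_particle, 4096)
    return (np.empty(cap, dtype=np.int32), np.empty(cap, dtype=np.int32))


def alloc_cell_scratch(n: int):
    head = np.empty(MAX_CELLS_PER_DIM ** 3, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    cells = np.empty((n, 3), dtype=np.int32)
    return head, nxt, cells


def alloc_tangent_scratch(m_beads: int):
    return np.empty((5, max(m_beads - 1, 1)), dtype=np.float64)


def forces_via_cells(pos, class_ids, fibre, params, eps_tab, rc_tab, conf):
    """One-shot cell-list force evaluation (used by total_forces)."""
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    n = pos.shape[0]
    m = fibre.n_beads
    bb_i, bb_j = alloc_pair_arrays(n)
    tf_i, tf_j = alloc_pair_arrays(n)
    counts = np.zeros(2, dtype=np.int64)
    head, nxt, cells = alloc_cell_scratch(n)
    _build_pairs(pos, m, float(params.rc_rep), float(rc_tab.max()),
                 bb_i, bb_j, tf_i, tf_j, counts, head, nxt, cells)
    if counts[0] < 0:
        raise MemoryError("neighbour list capacity exceeded")
    frc = np.zeros_like(pos)
    bi, bj, bk = fibre_bond_arrays(fibre)
    err = np.zeros(3, dtype=np.int64)
    _accumulate_forces(pos, frc, class_ids.astype(np.int8),
                       4.0 * eps_tab, rc_tab ** 2,
                       bb_i, bb_j, tf_i, tf_j, counts,
                       bi, bj, bk, m, pack_ffp(params),
                       pack_confinement(conf), -1.0,
                       alloc_tangent_scratch(m), err)
    if err[0] == 1:
        from .params import OverstretchError

        raise OverstretchError(
            f"FENE bond overstretched between beads {err[1]} and {err[2]}")
    return frc
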