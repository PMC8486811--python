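"""Pair, bonded, and angular potentials with analytic forces.

The model combines five interaction terms:

* WCA repulsion between every pair of particles (excluded volume),
* FENE springs along the unlooped backbone (Kremer-Grest combination:
  the bonded pair also feels WCA),
* harmonic springs for backbone and loop bonds on looped chains,
* a Kratky-Porod bending term on consecutive bead triplets,
* a truncated-and-shifted Lennard-Jones attraction between active TFs and
  binding chromatin beads.

Scalar functions here return ``(energy, radial_force)`` with the radial force
``f = -dU/dr`` (positive = repulsive).  They are the readable reference; the
simulation engine uses the compiled kernels in :mod:`chromodyn._kernels`,
which are cross-checked against :func:`total_forces` in brute-force mode.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    BeadClass,
    Confinement,
    ConfigurationError,
    GeometryError,
    InteractionParams,
    OverstretchError,
    RC_REP_FACTOR,
    TF_ACTIVE_CODE,
    TF_INACTIVE_CODE,
    TFState,
)

N_CLASS_CODES = 5  # TU, eu, het, TF-active, TF-inactive


def wca_energy_force(r: float, params: InteractionParams) -> tuple[float, float]:
    """Weeks-Chandler-Andersen repulsion: LJ cut at its minimum and shifted up.

    Zero at and beyond r = 2^(1/6) sigma; equals kBT at r = sigma.
    """
    if r <= 0:
        raise GeometryError(f"WCA needs r > 0, got {r}")
    rc = params.rc_rep
    if r >= rc:
        return 0.0, 0.0
    s6 = (params.sigma / r) ** 6
    energy = 4.0 * params.kBT * (s6 * s6 - s6 + 0.25)
    force = 4.0 * params.kBT * (12.0 * s6 * s6 - 6.0 * s6) / r
    return energy, force


def fene_energy_force(r: float, params: InteractionParams) -> tuple[float, float]:
    """Finite-extensible nonlinear elastic spring; diverges at R0 = 1.6 sigma."""
    if r <= 0:
        raise GeometryError(f"FENE needs r > 0, got {r}")
    if r >= params.R0:
        raise OverstretchError(
            f"FENE bond overstretched: r = {r:.4f} >= R0 = {params.R0}")
    x2 = (r / params.R0) ** 2
    energy = -0.5 * params.Kf * params.R0 ** 2 * math.log1p(-x2)
    force = -params.Kf * r / (1.0 - x2)
    return energy, force


def harmonic_energy_force(r: float, Rbar: float, Kh: float) -> tuple[float, float]:
    """Harmonic spring U = Kh (r - Rbar)^2 (note: no 1/2 prefactor)."""
    if r <= 0:
        raise GeometryError(f"harmonic bond needs r > 0, got {r}")
    dr = r - Rbar
    return Kh * dr * dr, -2.0 * Kh * dr


def lj_trunc_shifted_energy_force(
    d: float, eps: float, rc: float, params: InteractionParams
) -> tuple[float, float]:
    """Truncated-shifted Lennard-Jones for TF-chromatin pairs.

    Shifted so the energy is exactly zero at the cutoff; with rc = 2^(1/6)
    sigma it reduces to WCA.
    """
    if d <= 0:
        raise GeometryError(f"LJ needs d > 0, got {d}")
    if d >= rc:
        return 0.0, 0.0
    s6 = (params.sigma / d) ** 6
    c6 = (params.sigma / rc) ** 6
    energy = 4.0 * eps * (s6 * s6 - s6 - c6 * c6 + c6)
    force = 4.0 * eps * (12.0 * s6 * s6 - 6.0 * s6) / d
    return energy, force


def kratky_porod_energy_forces(
    r_i: np.ndarray, r_j: np.ndarray, r_k: np.ndarray, lp: float,
    kBT: float = 1.0, sigma: float = 1.0,
) -> tuple[float, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Bending energy (kBT lp / sigma)(1 - cos theta) on a consecutive triplet.

    Returns the energy and the three force vectors; their sum is zero and so
    is the net torque about any point.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    r_k = np.asarray(r_k, dtype=float)
    t1 = r_j - r_i
    t2 = r_k - r_j
    n1 = float(np.linalg.norm(t1))
    n2 = float(np.linalg.norm(t2))
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("coincident beads in angle triplet")
    k = kBT * lp / sigma
    cos = float(np.dot(t1, t2)) / (n1 * n2)
    energy = k * (1.0 - cos)
    # dU/dt1 = -k d(cos)/dt1 etc.; F_i = -dU/dr_i with dt1/dr_i = -1
    dcos_dt1 = t2 / (n1 * n2) - cos * t1 / (n1 * n1)
    dcos_dt2 = t1 / (n1 * n2) - cos * t2 / (n2 * n2)
    f_i = -k * dcos_dt1
    f_k = k * dcos_dt2
    f_j = -(f_i + f_k)
    return energy, (f_i, f_j, f_k)


def pair_rule(
    bead_class: BeadClass | int, tf_state: TFState | str, params: InteractionParams
) -> tuple[float, float]:
    """(eps, rc) for a TF-chromatin pair.

    Active TF + TU -> (8 kBT, 1.8 sigma); active TF + euchromatin ->
    (3 kBT, 1.8 sigma); everything else (heterochromatin, or an inactive TF)
    is purely repulsive: (kBT, 2^(1/6) sigma).
    """
    if isinstance(tf_state, str):
        try:
            tf_state = TFState[tf_state.upper()]
        except KeyError:
            raise ConfigurationError(f"unknown TF state {tf_state!r}") from None
    try:
        bead_class = BeadClass(bead_class)
    except ValueError:
        raise ConfigurationError(f"unknown bead class {bead_class!r}") from None
    if tf_state == TFState.ACTIVE:
        if bead_class == BeadClass.TU:
            return params.eps_strong * params.kBT, params.rc_attr * params.sigma
        if bead_class == BeadClass.EUCHROMATIN:
            return params.eps_weak * params.kBT, params.rc_attr * params.sigma
    return params.kBT, params.rc_rep


def pair_tables(params: InteractionParams) -> tuple[np.ndarray, np.ndarray]:
    """Dense (eps, rc) lookup tables over the 5 particle-class codes.

    Codes 0-2 are chromatin BeadClass values, 3/4 are active/inactive TFs.
    Chromatin-chromatin and TF-TF pairs are WCA; TF-chromatin pairs follow
    :func:`pair_rule`.
    """
    eps = np.full((N_CLASS_CODES, N_CLASS_CODES), params.kBT, dtype=np.float64)
    rc = np.full((N_CLASS_CODES, N_CLASS_CODES), params.rc_rep, dtype=np.float64)
    for cls in BeadClass:
        for code, state in ((TF_ACTIVE_CODE, TFState.ACTIVE),
                            (TF_INACTIVE_CODE, TFState.INACTIVE)):
            e, r = pair_rule(cls, state, params)
            eps[cls, code] = eps[code, cls] = e
            rc[cls, code] = rc[code, cls] = r
    return eps, rc


def confinement_force(
    position: np.ndarray, confinement: Confinement, params: InteractionParams
) -> np.ndarray:
    """Inward WCA-like wall force of the ellipsoidal territory.

    Zero strictly inside the shrunken ellipsoid (semi-axes minus 2^(1/6)
    sigma); rises as the particle approaches the wall along the scaled-radius
    normal.  The wall gap is the linearised normal distance
    d = (1 - s)/|grad s| with s the scaled radius.
    """
    position = np.asarray(position, dtype=float)
    if confinement.kind == "none":
        return np.zeros(3)
    a, b, c = confinement.semi_axes
    x, y, z = position
    s = math.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    if s == 0.0:
        return np.zeros(3)
    grad = np.array([x / a ** 2, y / b ** 2, z / c ** 2]) / s
    gn = float(np.linalg.norm(grad))
    d = (1.0 - s) / gn
    d = max(d, 0.2 * params.sigma)  # clamp: warm-up may start marginally close
    if d >= params.rc_rep:
        return np.zeros(3)
    s6 = (params.sigma / d) ** 6
    fmag = 4.0 * params.kBT * (12.0 * s6 * s6 - 6.0 * s6) / d
    return -fmag * grad / gn


def total_forces(state, fibre, params: InteractionParams,
                 confinement: Confinement | None = None,
                 method: str = "cell") -> np.ndarray:
    """Force vectors on every particle (chromatin beads then TFs).

    ``method='brute'`` is the O(N^2) reference sum of all pair, bond and
    angle terms; ``method='cell'`` runs the compiled cell-list kernel and
    must agree with it to float tolerance.
    """
    from .dynamics import SystemState  # local import to avoid a cycle

    if not isinstance(state, SystemState):
        raise ConfigurationError("total_forces expects a SystemState")
    pos = np.asarray(state.positions, dtype=np.float64)
    class_ids = particle_class_ids(fibre, state.tf_states)
    eps_tab, rc_tab = pair_tables(params)
    conf = confinement if confinement is not None else Confinement.none()
    if method == "brute":
        return _brute_forces(pos, class_ids, fibre, params, eps_tab, rc_tab, conf)
    if method == "cell":
        from . import _kernels

        return _kernels.forces_via_cells(pos, class_ids, fibre, params,
                                         eps_tab, rc_tab, conf)
    raise ConfigurationError(f"unknown method {method!r}")


def particle_class_ids(fibre, tf_states: np.ndarray) -> np.ndarray:
    """Per-particle class codes: bead classes followed by TF activity codes."""
    tf_states = np.asarray(tf_states)
    codes = np.where(tf_states == TFState.ACTIVE, TF_ACTIVE_CODE, TF_INACTIVE_CODE)
    return np.concatenate([fibre.bead_class.astype(np.int8),
                           codes.astype(np.int8)])


def _brute_forces(pos, class_ids, fibre, params, eps_tab, rc_tab, conf):
    n = pos.shape[0]
    f = np.zeros_like(pos)
    # all pairs, excluding nothing: bonded pairs also feel WCA (Kremer-Grest)
    for i in range(n - 1):
        dx = pos[i + 1:] - pos[i]
        r = np.sqrt(np.sum(dx * dx, axis=1))
        for joff, rij in enumerate(r):
            j = i + 1 + joff
            rc = rc_tab[class_ids[i], class_ids[j]]
            if rij >= rc or rij == 0.0:
                continue
            eps = eps_tab[class_ids[i], class_ids[j]]
            _, fmag = lj_trunc_shifted_energy_force(float(rij), float(eps),
                                                    float(rc), params)
            fv = fmag * dx[joff] / rij
            f[j] += fv
            f[i] -= fv
    for bond in fibre.bonds:
        dx = pos[bond.j] - pos[bond.i]
        r = float(np.linalg.norm(dx))
        if bond.kind == "fene":
            _, fmag = fene_energy_force(r, params)
        elif bond.kind == "harmonic_backbone":
            _, fmag = harmonic_energy_force(r, params.Rbar_backbone, params.Kh)
        elif bond.kind == "harmonic_loop":
            _, fmag = harmonic_energy_force(r, params.Rbar_loop, params.Kh)
        else:
            raise ConfigurationError(f"unknown bond kind {bond.kind!r}")
        fv = fmag * dx / r
        f[bond.j] += fv
        f[bond.i] -= fv
    for ang in fibre.angles:
        _, (fi, fj, fk) = kratky_porod_energy_forces(
            pos[ang.i], pos[ang.j], pos[ang.k], params.lp,
            params.kBT, params.sigma)
        f[ang.i] += fi
        f[ang.j] += fj
        f[ang.k] += fk
    if conf.kind != "none":
        for i in range(n):
            f[i] += confinement_force(pos[i], conf, params)
    return f
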