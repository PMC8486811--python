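"""Force-field unit tests: analytic values, gradients, and the cell-list oracle."""

import math

import numpy as np
import pytest

from chromodyn.dynamics import SystemState
from chromodyn.fibre import add_loops, build_toy_fibre
from chromodyn.forcefield import (
    confinement_force,
    fene_energy_force,
    harmonic_energy_force,
    kratky_porod_energy_forces,
    lj_trunc_shifted_energy_force,
    pair_rule,
    total_forces,
    wca_energy_force,
)
from chromodyn.params import (
    BeadClass,
    Confinement,
    ConfigurationError,
    GeometryError,
    InteractionParams,
    OverstretchError,
    TFState,
)

P = InteractionParams()
RC_REP = 2.0 ** (1.0 / 6.0)


class TestScalarPotentials:
    def test_wca_analytic_values(self):
        # zero at the cutoff by construction, kBT exactly at r = sigma
        assert wca_energy_force(RC_REP, P) == (0.0, 0.0)
        assert wca_energy_force(2.0, P) == (0.0, 0.0)
        e, _ = wca_energy_force(1.0, P)
        assert e == pytest.approx(1.0, abs=1e-12)

    def test_fene_analytic_values(self):
        e0, f0 = fene_energy_force(1e-9, P)
        assert e0 == pytest.approx(0.0, abs=1e-12)
        e1, _ = fene_energy_force(1.0, P)
        assert e1 == pytest.approx(19.020343189632978, rel=1e-12)
        e_div, _ = fene_energy_force(1.59, P)
        assert e_div > 100.0  # divergence approaching R0

    def test_fene_monotone_and_overstretch(self):
        rs = np.linspace(0.1, 1.55, 40)
        es = [fene_energy_force(r, P)[0] for r in rs]
        assert np.all(np.diff(es) > 0)
        with pytest.raises(OverstretchError):
            fene_energy_force(1.6, P)

    def test_harmonic_minimum_and_value(self):
        assert harmonic_energy_force(1.1, 1.1, 100.0)[0] == 0.0
        e, _ = harmonic_energy_force(1.2, 1.1, 100.0)
        assert e == pytest.approx(1.0, rel=1e-12)

    def test_lj_shifted_zero_at_cutoff_and_well_depth(self):
        e, f = lj_trunc_shifted_energy_force(1.8, 8.0, 1.8, P)
        assert e == 0.0 and f == 0.0
        # well at the LJ minimum, shifted: ~ -0.8858 eps (-7.087 kBT for TUs)
        e_min, _ = lj_trunc_shifted_energy_force(RC_REP, 8.0, 1.8, P)
        assert e_min == pytest.approx(-7.08682355530704, rel=1e-10)
        # rc = 2^(1/6) sigma reduces to WCA
        for r in (0.95, 1.05, 1.12):
            e_lj, f_lj = lj_trunc_shifted_energy_force(r, 1.0, RC_REP, P)
            e_wca, f_wca = wca_energy_force(r, P)
            assert e_lj == pytest.approx(e_wca, rel=1e-12)
            assert f_lj == pytest.approx(f_wca, rel=1e-12)

    def test_energy_continuity_at_cutoffs(self):
        for fn, rc in ((lambda r: wca_energy_force(r, P)[0], RC_REP),
                       (lambda r: lj_trunc_shifted_energy_force(r, 8.0, 1.8, P)[0], 1.8)):
            eps_seq = [1e-4, 1e-6, 1e-8]
            jumps = [abs(fn(rc - e) - fn(rc + e)) for e in eps_seq]
            assert jumps[0] < 1e-2 and jumps[-1] < 1e-7
            assert jumps == sorted(jumps, reverse=True)

    def test_invalid_geometry_errors(self):
        for fn in (lambda: wca_energy_force(0.0, P),
                   lambda: fene_energy_force(-1.0, P),
                   lambda: harmonic_energy_force(0.0, 1.1, 100.0),
                   lambda: lj_trunc_shifted_energy_force(0.0, 1.0, 1.8, P)):
            with pytest.raises(GeometryError):
                fn()

    def test_kratky_porod_limits(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.0, 0.0, 0.0])
        c = np.array([2.0, 0.0, 0.0])
        e, _ = kratky_porod_energy_forces(a, b, c, lp=3.0)
        assert e == pytest.approx(0.0, abs=1e-14)
        # reversal: (1 - (-1)) * lp = 6 kBT
        e_rev, _ = kratky_porod_energy_forces(a, b, a, lp=3.0)
        assert e_rev == pytest.approx(6.0, rel=1e-12)
        with pytest.raises(GeometryError):
            kratky_porod_energy_forces(a, a, c, lp=3.0)

    def test_kratky_porod_zero_net_force_and_torque(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.normal(size=(3, 3))
            _, (fi, fj, fk) = kratky_porod_energy_forces(*pts, lp=3.0)
            total = fi + fj + fk
            torque = (np.cross(pts[0], fi) + np.cross(pts[1], fj)
                      + np.cross(pts[2], fk))
            np.testing.assert_allclose(total, 0.0, atol=1e-12)
            np.testing.assert_allclose(torque, 0.0, atol=1e-12)


class TestFiniteDifferenceGradients:
    """Every analytic force equals -dU/dr from central differences."""

    @pytest.mark.parametrize("fn,r", [
        (lambda r: wca_energy_force(r, P), 1.05),
        (lambda r: wca_energy_force(r, P), 0.9),
        (lambda r: fene_energy_force(r, P), 0.8),
        (lambda r: fene_energy_force(r, P), 1.35),
        (lambda r: harmonic_energy_force(r, 1.1, 100.0), 1.23),
        (lambda r: lj_trunc_shifted_energy_force(r, 8.0, 1.8, P), 1.3),
        (lambda r: lj_trunc_shifted_energy_force(r, 3.0, 1.8, P), 1.02),
    ])
    def test_radial_potentials(self, fn, r):
        h = 1e-6
        force = fn(r)[1]
        fd = -(fn(r + h)[0] - fn(r - h)[0]) / (2 * h)
        assert force == pytest.approx(fd, rel=1e-5)

    def test_bending_forces_match_finite_differences(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(3, 3)) * 1.5
        _, forces = kratky_porod_energy_forces(*pts, lp=3.0)
        h = 1e-6
        for p in range(3):
            for d in range(3):
                plus = pts.copy()
                minus = pts.copy()
                plus[p, d] += h
                minus[p, d] -= h
                e_p, _ = kratky_porod_energy_forces(*plus, lp=3.0)
                e_m, _ = kratky_porod_energy_forces(*minus, lp=3.0)
                fd = -(e_p - e_m) / (2 * h)
                assert forces[p][d] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestPairRule:
    @pytest.mark.parametrize("cls,state,eps,rc", [
        (BeadClass.TU, TFState.ACTIVE, 8.0, 1.8),
        (BeadClass.EUCHROMATIN, TFState.ACTIVE, 3.0, 1.8),
        (BeadClass.HETEROCHROMATIN, TFState.ACTIVE, 1.0, RC_REP),
        (BeadClass.TU, TFState.INACTIVE, 1.0, RC_REP),
        (BeadClass.EUCHROMATIN, TFState.INACTIVE, 1.0, RC_REP),
    ])
    def test_eps_rc_assignment(self, cls, state, eps, rc):
        got = pair_rule(cls, state, P)
        assert got[0] == pytest.approx(eps)
        assert got[1] == pytest.approx(rc)

    def test_unknown_class_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            pair_rule(7, TFState.ACTIVE, P)


def _random_state(fibre, n_tf, seed, spread=3.0):
    rng = np.random.default_rng(seed)
    # random walk with fixed bond length 0.95 so FENE bonds stay < R0
    steps = rng.normal(size=(fibre.n_beads, 3))
    steps *= 0.95 / np.linalg.norm(steps, axis=1)[:, None]
    steps[0] = 0.0
    pos = np.cumsum(steps, axis=0)
    pos -= pos.mean(axis=0)
    tf_pos = rng.uniform(-spread, spread, size=(n_tf, 3))
    pos = np.vstack([pos, tf_pos])
    states = rng.integers(0, 2, n_tf).astype(np.int8)
    return SystemState(pos, np.zeros_like(pos), states)


class TestTotalForces:
    def test_isolated_beads_beyond_cutoffs_have_zero_force(self):
        fib = build_toy_fibre(2, 1, seed=1)
        fib = type(fib)(2, fib.bead_class, (), (), ())  # two unbonded beads
        pos = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
        st = SystemState(pos, np.zeros_like(pos), np.zeros(0, dtype=np.int8))
        f = total_forces(st, fib, P, method="brute")
        np.testing.assert_array_equal(f, 0.0)

    @pytest.mark.parametrize("n_beads,n_tf,seed", [(30, 8, 0), (50, 10, 3)])
    def test_cell_list_matches_brute_force(self, n_beads, n_tf, seed):
        fib = build_toy_fibre(n_beads, max(2, n_beads // 8), seed=seed)
        st = _random_state(fib, n_tf, seed)
        f_cell = total_forces(st, fib, P, method="cell")
        f_brute = total_forces(st, fib, P, method="brute")
        scale = np.abs(f_brute).max()
        assert np.abs(f_cell - f_brute).max() / scale < 1e-10

    def test_cell_list_matches_brute_on_looped_chain_with_confinement(self):
        fib = add_loops(build_toy_fibre(40, 5, seed=2), [(3, 20), (25, 38)])
        st = _random_state(fib, 6, 4)
        conf = Confinement.sphere(30.0)
        f_cell = total_forces(st, fib, P, conf, method="cell")
        f_brute = total_forces(st, fib, P, conf, method="brute")
        scale = np.abs(f_brute).max()
        assert np.abs(f_cell - f_brute).max() / scale < 1e-10

    def test_internal_forces_sum_to_zero(self):
        fib = build_toy_fibre(40, 6, seed=5)
        st = _random_state(fib, 8, 6)
        f = total_forces(st, fib, P, method="cell")  # no confinement wall
        scale = np.abs(f).max()
        assert np.abs(f.sum(axis=0)).max() / scale < 1e-10


class TestConfinementForce:
    def test_zero_at_centre_inward_at_wall(self):
        conf = Confinement.sphere(10.0)
        np.testing.assert_array_equal(
            confinement_force(np.zeros(3), conf, P), 0.0)
        f = confinement_force(np.array([9.9, 0.0, 0.0]), conf, P)
        assert f[0] < 0  # pushes back toward the centre
        deep_inside = confinement_force(np.array([5.0, 0.0, 0.0]), conf, P)
        np.testing.assert_array_equal(deep_inside, 0.0)

    def test_ellipsoid_force_normal_direction(self):
        conf = Confinement(kind="ellipsoid", semi_axes=(20.0, 10.0, 10.0))
        f = confinement_force(np.array([0.0, 9.8, 0.0]), conf, P)
        assert f[1] < 0 and abs(f[0]) < 1e-12 and abs(f[2]) < 1e-12
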