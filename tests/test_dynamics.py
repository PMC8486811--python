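"""Integrator physics: ballistic limit, equipartition, Boltzmann statistics,
persistence length, switching, confinement, determinism, aborts."""

import numpy as np
import pytest

from chromodyn.dynamics import (
    Simulation,
    SimulationConfig,
    SystemState,
    run_simulation,
    switch_tf_states,
)
from chromodyn.fibre import AngleSpec, BondSpec, ChromatinFibre, build_toy_fibre
from chromodyn.params import (
    BeadClass,
    Confinement,
    ConfigurationError,
    OverstretchError,
    SwitchingParams,
    ThermostatParams,
)


def phantom_config(**kw) -> SimulationConfig:
    base = dict(n_tf=0, confinement=Confinement.none(),
                pair_interactions=False, warmup_pushoff=0.0,
                warmup_equil=0.0, production=0.0)
    base.update(kw)
    return SimulationConfig(**base)


def harmonic_chain(m: int) -> ChromatinFibre:
    """Phantom chain: stiff harmonic bonds (Rbar = 1.1 sigma) + bending."""
    classes = np.full(m, BeadClass.EUCHROMATIN, dtype=np.int8)
    bonds = tuple(BondSpec(i, i + 1, "harmonic_backbone") for i in range(m - 1))
    angles = tuple(AngleSpec(i, i + 1, i + 2) for i in range(m - 2))
    return ChromatinFibre(m, classes, bonds, angles)


def single_bead_system(confinement=None, velocity=(0.0, 0.0, 0.0),
                       gamma=1.0, temperature=1.0, seed=0):
    fib = ChromatinFibre(1, np.array([1], dtype=np.int8), (), ())
    cfg = phantom_config(
        confinement=confinement or Confinement.none(),
        thermostat=ThermostatParams(gamma=gamma, temperature=temperature))
    pos = np.zeros((1, 3))
    vel = np.array([velocity], dtype=float)
    state = SystemState(pos, vel, np.zeros(0, dtype=np.int8))
    return Simulation(fib, cfg, seed=seed, state=state)


class TestIntegrator:
    def test_ballistic_motion_without_friction_or_noise(self):
        sim = single_bead_system(velocity=(1.0, -2.0, 0.5), gamma=0.0)
        sim.advance(3.0)
        np.testing.assert_allclose(sim.pos[0], [3.0, -6.0, 1.5], rtol=1e-12)
        np.testing.assert_allclose(sim.vel[0], [1.0, -2.0, 0.5], rtol=1e-12)

    def test_equipartition_free_particle(self):
        # a single particle has only 3 dof, so the time average carries
        # ~1.5% sampling noise; the tight 2% check is on the 300-dof chain
        sim = single_bead_system(seed=3)
        sim.advance(100.0)
        ke = []
        for _ in range(1500):
            sim.advance(2.0)
            ke.append(sim.mean_kinetic_energy())
        assert np.mean(ke) / 1.5 == pytest.approx(1.0, abs=0.05)

    def test_equipartition_phantom_chain(self):
        # <KE>/dof = kBT/2 within 2% (300 dof: sampling SE ~0.3%)
        sim = Simulation(harmonic_chain(100), phantom_config(), seed=4)
        sim.advance(100.0)
        ke = []
        for _ in range(400):
            sim.advance(2.0)
            ke.append(sim.mean_kinetic_energy())
        assert np.mean(ke) / 1.5 == pytest.approx(1.0, abs=0.02)

    def test_harmonic_dimer_bond_extension_variance(self):
        # Boltzmann: U = Kh (r - Rbar)^2 -> Var(r) = kBT / (2 Kh) = 0.005
        sim = Simulation(harmonic_chain(2), phantom_config(), seed=5)
        sim.advance(50.0)
        ext = []
        for _ in range(6000):
            sim.advance(0.5)
            ext.append(float(np.linalg.norm(sim.pos[1] - sim.pos[0])))
        var = np.var(ext)
        assert var == pytest.approx(0.005, rel=0.15)

    def test_phantom_chain_persistence_length(self):
        # tangent autocorrelation <t_i . t_{i+s}> ~ exp(-s sigma / lp);
        # fitted lp must land in [2.4, 3.6] sigma for the default lp = 3
        sim = Simulation(harmonic_chain(100), phantom_config(), seed=6)
        sim.advance(300.0)
        smax = 6
        acc = np.zeros(smax + 1)
        cnt = np.zeros(smax + 1)
        for _ in range(800):
            sim.advance(2.0)
            t = np.diff(sim.pos, axis=0)
            t /= np.linalg.norm(t, axis=1)[:, None]
            for s in range(smax + 1):
                dots = np.sum(t[:-s if s else None] * t[s:], axis=1) if s else \
                    np.ones(t.shape[0])
                acc[s] += dots.sum()
                cnt[s] += dots.size
        corr = acc / cnt
        slope = np.polyfit(np.arange(smax + 1), np.log(corr), 1)[0]
        lp_fit = -1.0 / slope
        assert 2.4 <= lp_fit <= 3.6

    def test_overstretched_fene_bond_aborts_with_diagnostic(self):
        classes = np.full(2, BeadClass.EUCHROMATIN, dtype=np.int8)
        fib = ChromatinFibre(2, classes, (BondSpec(0, 1, "fene"),), ())
        pos = np.array([[0.0, 0.0, 0.0], [1.7, 0.0, 0.0]])
        state = SystemState(pos, np.zeros_like(pos), np.zeros(0, dtype=np.int8))
        sim = Simulation(fib, phantom_config(), seed=0, state=state)
        with pytest.raises(OverstretchError, match="0 and 1"):
            sim.advance(0.01)  # full force field: diagnostic abort


class TestSwitching:
    @pytest.mark.parametrize("params,expected", [
        (SwitchingParams.toy(), 0.5),
        (SwitchingParams.chromosome(), 0.2),
    ])
    def test_stationary_active_fraction(self, params, expected):
        # two-state Markov chain relaxes to alpha_on/(alpha_on+alpha_off);
        # >= 1e4 TF-attempts, tolerance 3 binomial SE
        rng = np.random.default_rng(11)
        n = 20_000
        states = np.ones(n, dtype=np.int8)  # start all inactive
        for _ in range(3000):
            states = switch_tf_states(states, params, rng)
        frac = float((states == 0).mean())
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_zero_rates_freeze_states(self):
        params = SwitchingParams(alpha_off=0.0, alpha_on=0.0)
        rng = np.random.default_rng(0)
        states = np.array([0, 1, 0, 1], dtype=np.int8)
        out = switch_tf_states(states, params, rng)
        np.testing.assert_array_equal(out, states)

    def test_probability_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SwitchingParams(alpha_off=0.5, alpha_on=0.5, attempt_interval=100.0)


class TestConfinement:
    def test_confined_particle_stays_inside_and_samples_uniformly(self):
        conf = Confinement.sphere(6.0)
        sim = single_bead_system(confinement=conf, seed=8)
        sim.advance(100.0)
        radii = []
        for _ in range(3000):
            sim.advance(1.0)
            radii.append(float(np.linalg.norm(sim.pos[0])))
        radii = np.asarray(radii)
        assert radii.max() < 6.0  # never escapes
        # uniform measure in the zero-energy interior: E[(r/R_eff)^3] = 1/2
        r_eff = 6.0 - 2.0 ** (1.0 / 6.0)
        s3 = np.clip(radii / r_eff, 0, 1) ** 3
        assert np.mean(s3) == pytest.approx(0.5, abs=0.1)

    def test_particle_outside_confinement_rejected(self):
        conf = Confinement.sphere(5.0)
        fib = ChromatinFibre(1, np.array([1], dtype=np.int8), (), ())
        pos = np.array([[6.0, 0.0, 0.0]])
        state = SystemState(pos, np.zeros_like(pos), np.zeros(0, dtype=np.int8))
        with pytest.raises(ConfigurationError):
            Simulation(fib, phantom_config(confinement=conf), seed=0,
                       state=state)


class TestRunSimulation:
    def test_bitwise_determinism(self, tiny_fibre, tiny_config):
        a = run_simulation(tiny_fibre, tiny_config, seed=42)
        b = run_simulation(tiny_fibre, tiny_config, seed=42)
        np.testing.assert_array_equal(a.record.samples, b.record.samples)
        np.testing.assert_array_equal(a.final_state.positions,
                                      b.final_state.positions)

    def test_different_seeds_diverge(self, tiny_fibre, tiny_config):
        a = run_simulation(tiny_fibre, tiny_config, seed=1)
        b = run_simulation(tiny_fibre, tiny_config, seed=2)
        assert not np.array_equal(a.final_state.positions,
                                  b.final_state.positions)

    def test_zero_production_yields_empty_record(self, tiny_fibre, tiny_config):
        from dataclasses import replace

        cfg = replace(tiny_config, production=0.0)
        res = run_simulation(tiny_fibre, cfg, seed=3)
        assert res.record.samples.shape == (0, tiny_fibre.tu_indices.size)

    def test_smoke_binding_occurs(self, tiny_fibre, tiny_config):
        res = run_simulation(tiny_fibre, tiny_config, seed=4)
        assert res.record.samples.sum() > 0  # TFs find and bind TUs


def test_langevin_step_single_step_wrapper(tiny_fibre):
    import numpy as np
    from chromodyn.dynamics import SystemState, langevin_step
    from chromodyn.params import InteractionParams, ThermostatParams

    rng = np.random.default_rng(0)
    fib = tiny_fibre
    pos = np.zeros((fib.n_beads, 3))
    pos[:, 0] = np.arange(fib.n_beads) * 1.0
    vel = np.zeros_like(pos)
    state = SystemState(pos, vel, np.zeros(0, dtype=np.int8))
    out = langevin_step(state, fib, InteractionParams(),
                        ThermostatParams(), rng)
    assert out.time == 0.01
    assert np.isfinite(out.positions).all()
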