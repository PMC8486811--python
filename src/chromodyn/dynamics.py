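"""Langevin time evolution and run orchestration.

The underdamped Langevin equation (friction gamma, Gaussian thermal noise
with variance 2 kBT gamma per component per unit time) is integrated with a
BAOAB velocity-Verlet splitting at dt = 0.01 tau_B.  TFs switch between
active and inactive states at stochastic attempts every 100 tau_B.  A run is
fully reproducible from (fibre, config, seed): the seed is split into
independent streams for initialisation, thermal noise, and switching.

A production run is preceded by a warm-up that is never recorded: a
soft push-off phase with capped forces removes residual overlaps of the
random-walk initial conformation, followed by an equilibration phase with
the full force field.
"""

from __future__ import annotations

import hashlib
import math
import time as _time
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .fibre import ChromatinFibre, initial_conformation
from .forcefield import confinement_force, pair_tables, particle_class_ids  # noqa: F401  (re-export)
from .params import (
    Confinement,
    ConfigurationError,
    InteractionParams,
    OverstretchError,
    SwitchingParams,
    TFState,
    TF_ACTIVE_CODE,
    TF_INACTIVE_CODE,
    ThermostatParams,
)
from .transcription import ActivityRecord

_CHUNK_STEPS = 1000  # noise pre-generation granularity


@dataclass
class SystemState:
    """Positions/velocities for M beads + n TFs, TF activity flags, elapsed time."""

    positions: np.ndarray
    velocities: np.ndarray
    tf_states: np.ndarray  # int8; 0 = active, 1 = inactive
    time: float = 0.0

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        if self.positions.shape != self.velocities.shape:
            raise ConfigurationError("positions/velocities shape mismatch")
        if not np.isfinite(self.positions).all() or not np.isfinite(self.velocities).all():
            raise ConfigurationError("non-finite state")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulation (durations in tau_B).

    The default confinement is a sphere of radius 25 sigma: with the
    1000-bead toy chain this gives a chromatin volume fraction of ~0.8% and
    a TF concentration of ~20 nM in physical units (20 TFs), i.e. a dilute
    nucleoplasm-like environment well below the ~14% used for chromosome
    territories.
    """

    n_tf: int = 20
    params: InteractionParams = field(default_factory=InteractionParams)
    thermostat: ThermostatParams = field(default_factory=ThermostatParams)
    switching: SwitchingParams = field(default_factory=SwitchingParams.toy)
    confinement: Confinement = field(default_factory=lambda: Confinement.sphere(25.0))
    warmup_pushoff: float = 300.0
    warmup_equil: float = 1000.0
    production: float = 10_000.0
    sample_interval: float = 100.0
    traj_stride: float = 0.0  # 0 = keep no frames
    pushoff_strength: float = 50.0
    transcription_cutoff: float = 1.8
    record_all_beads: bool = False
    pair_interactions: bool = True
    verlet_skin: float = 1.3

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:12]


@dataclass
class SimResult:
    record: ActivityRecord
    final_state: SystemState
    frames: list  # (time, positions copy, tf_states copy)
    kinetic_samples: np.ndarray  # mean KE per particle at sample times
    log: list[str]
    config_hash: str
    seed: int


def switch_tf_states(tf_states: np.ndarray, switching: SwitchingParams,
                     rng: np.random.Generator) -> np.ndarray:
    """One switching attempt: a two-state Markov step per TF.

    Active TFs deactivate with probability alpha_off * attempt_interval,
    inactive ones activate with probability alpha_on * attempt_interval; the
    stationary active fraction is alpha_on / (alpha_on + alpha_off).
    """
    p_off = switching.alpha_off * switching.attempt_interval
    p_on = switching.alpha_on * switching.attempt_interval
    if p_off > 1.0 or p_on > 1.0:
        raise ConfigurationError("switching probability per attempt exceeds 1")
    u = rng.random(tf_states.shape[0])
    out = tf_states.copy()
    active = tf_states == TFState.ACTIVE
    out[active & (u < p_off)] = TFState.INACTIVE
    out[~active & (u < p_on)] = TFState.ACTIVE
    return out


def _check_inside(positions: np.ndarray, confinement: Confinement) -> None:
    if confinement.kind != "ellipsoid":
        return
    a, b, c = confinement.semi_axes
    s2 = (positions[:, 0] / a) ** 2 + (positions[:, 1] / b) ** 2 + (positions[:, 2] / c) ** 2
    if (s2 >= 1.0).any():
        raise ConfigurationError("particle initialised outside the confinement")


class Simulation:
    """Stateful engine: owns particle arrays and advances them in chunks."""

    def __init__(self, fibre: ChromatinFibre, config: SimulationConfig,
                 seed: int, state: SystemState | None = None):
        self.fibre = fibre
        self.config = config
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        s_init, s_noise, s_switch = ss.spawn(3)
        self._rng_noise = np.random.Generator(np.random.SFC64(s_noise))
        self._rng_switch = np.random.Generator(np.random.SFC64(s_switch))
        rng_init = np.random.Generator(np.random.SFC64(s_init))
        p = config.params
        if state is None:
            pos = initial_conformation(fibre, config.confinement,
                                       seed=int(rng_init.integers(2 ** 31)),
                                       n_tf=config.n_tf, params=p)
            # start cold (T/100): the thermostat re-thermalises within a few
            # tau_B, and gentle early dynamics protects the push-off
            vel = rng_init.normal(
                scale=0.1 * math.sqrt(config.thermostat.temperature),
                size=pos.shape)
            frac = config.switching.stationary_active_fraction
            if math.isnan(frac):
                frac = 0.5
            tf_states = np.where(rng_init.random(config.n_tf) < frac,
                                 TFState.ACTIVE, TFState.INACTIVE).astype(np.int8)
            state = SystemState(pos, vel, tf_states, 0.0)
        else:
            state.validate()
        _check_inside(state.positions, config.confinement)
        self.state = state
        self.pos = np.ascontiguousarray(state.positions, dtype=np.float64)
        self.vel = np.ascontiguousarray(state.velocities, dtype=np.float64)
        self.tf_states = np.asarray(state.tf_states, dtype=np.int8)
        state.positions = self.pos
        state.velocities = self.vel
        state.tf_states = self.tf_states
        n = self.pos.shape[0]
        if n != fibre.n_beads + config.n_tf:
            raise ConfigurationError("state size != n_beads + n_tf")
        self._cls = particle_class_ids(fibre, self.tf_states)
        eps_tab, rc_tab = pair_tables(p)
        self._eps4 = 4.0 * eps_tab
        if config.pair_interactions:
            self._rc2 = rc_tab ** 2
            self._rlist_bb = float(p.rc_rep + config.verlet_skin)
            self._rlist_tf = float(rc_tab.max() + config.verlet_skin)
            self._skin_half2 = (config.verlet_skin / 2.0) ** 2
        else:
            self._rc2 = np.zeros_like(rc_tab)
            self._rlist_bb = 1e-9
            self._rlist_tf = 1e-9
            self._skin_half2 = 1e30  # list never rebuilt; it is empty anyway
        self._bb_i, self._bb_j = _kernels.alloc_pair_arrays(n)
        self._tf_i, self._tf_j = _kernels.alloc_pair_arrays(n, 64)
        self._counts = np.zeros(2, dtype=np.int64)
        self._head, self._nxt, self._cells = _kernels.alloc_cell_scratch(n)
        self._tang = _kernels.alloc_tangent_scratch(fibre.n_beads)
        self._pos_ref = self.pos.copy()
        self._bi, self._bj, self._bk = _kernels.fibre_bond_arrays(fibre)
        self._ffp = _kernels.pack_ffp(p)
        self._conf = _kernels.pack_confinement(config.confinement)
        self._frc = np.zeros_like(self.pos)
        self.log: list[str] = []
        self._steps_done = 0
        self._refresh_neighbours_and_forces(fcap=config.pushoff_strength)

    # -- internals ---------------------------------------------------------

    def _refresh_neighbours_and_forces(self, fcap: float) -> None:
        if self.config.pair_interactions:
            _kernels._build_pairs(self.pos, self.fibre.n_beads,
                                  self._rlist_bb, self._rlist_tf,
                                  self._bb_i, self._bb_j,
                                  self._tf_i, self._tf_j, self._counts,
                                  self._head, self._nxt, self._cells)
            if self._counts[0] < 0:
                raise ConfigurationError("neighbour list capacity exceeded")
        else:
            self._counts[:] = 0
        self._pos_ref[:] = self.pos
        err = np.zeros(3, dtype=np.int64)
        _kernels._accumulate_forces(
            self.pos, self._frc, self._cls, self._eps4, self._rc2,
            self._bb_i, self._bb_j, self._tf_i, self._tf_j, self._counts,
            self._bi, self._bj, self._bk, self.fibre.n_beads,
            self._ffp, self._conf, fcap, self._tang, err)
        self._raise_on_error(err)

    def _raise_on_error(self, err: np.ndarray) -> None:
        if err[0] == 1:
            raise OverstretchError(
                f"FENE bond overstretched between beads {err[1]} and {err[2]} "
                f"at step {self._steps_done} (seed {self.seed})")
        if err[0] == 2:
            raise ConfigurationError("neighbour list capacity exceeded mid-run")

    def advance(self, n_tau: float, fcap: float = -1.0) -> None:
        """Integrate for n_tau Brownian times (must be a multiple of dt)."""
        th = self.config.thermostat
        nsteps = int(round(n_tau / th.dt))
        if abs(nsteps * th.dt - n_tau) > 1e-9:
            raise ConfigurationError("advance duration must be a multiple of dt")
        c1 = math.exp(-th.gamma * th.dt)
        c2 = math.sqrt(th.temperature * (1.0 - c1 * c1))
        err = np.zeros(3, dtype=np.int64)
        done = 0
        if not hasattr(self, "_noise_buf"):
            self._noise_buf = np.empty((_CHUNK_STEPS, self.pos.shape[0], 3))
        while done < nsteps:
            chunk = min(_CHUNK_STEPS, nsteps - done)
            noise = self._noise_buf[:chunk]
            self._rng_noise.standard_normal(out=noise)
            steps = _kernels._run_chunk(
                self.pos, self.vel, self._frc, self._cls, self._eps4, self._rc2,
                self._bb_i, self._bb_j, self._tf_i, self._tf_j, self._counts,
                self._pos_ref, self.fibre.n_beads,
                self._rlist_bb, self._rlist_tf, self._skin_half2,
                self._bi, self._bj, self._bk,
                self._ffp, self._conf, th.dt, c1, c2, fcap, noise,
                self._head, self._nxt, self._cells, self._tang, err)
            self._steps_done += steps
            self._raise_on_error(err)
            if not np.isfinite(self.pos[::7]).all():
                raise ConfigurationError(
                    f"non-finite coordinates at step {self._steps_done} "
                    f"(seed {self.seed})")
            done += chunk
        self.state.time += n_tau

    def pushoff(self, duration: float) -> None:
        """Soft push-off: ramped soft-cosine pair repulsion with harmonic
        bonds, then a bond-length check before enabling the full force field.

        The amplitude ramp (4% -> 100% of ``pushoff_strength`` over five
        equal sub-phases) lets severe initial overlaps relax gently; the
        final check extends the push-off if any backbone bond is still near
        the FENE maximum.
        """
        strength = self.config.pushoff_strength
        if duration > 0:
            dt = self.config.thermostat.dt
            seg = max(round(duration / 5.0 / dt) * dt, dt)
            for frac in (0.04, 0.1, 0.2, 0.4, 1.0):
                self.advance(seg, fcap=strength * frac)
        r0_safe = 0.95 * self.config.params.R0
        for _ in range(20):
            chain = self.pos[:self.fibre.n_beads]
            if np.linalg.norm(np.diff(chain, axis=0), axis=1).max() < r0_safe:
                break
            self.advance(25.0, fcap=strength)
        else:
            raise ConfigurationError(
                f"push-off failed to relax backbone bonds (seed {self.seed})")
        self._refresh_neighbours_and_forces(fcap=-1.0)

    def attempt_switch(self) -> int:
        """One switching attempt; returns the number of TFs that flipped."""
        new = switch_tf_states(self.tf_states, self.config.switching,
                               self._rng_switch)
        flips = int((new != self.tf_states).sum())
        if flips:
            self.tf_states[:] = new
            codes = np.where(new == TFState.ACTIVE,
                             TF_ACTIVE_CODE, TF_INACTIVE_CODE)
            self._cls[self.fibre.n_beads:] = codes.astype(np.int8)
            # class change alters cutoffs; recompute forces with fresh list
            self._refresh_neighbours_and_forces(fcap=-1.0)
        return flips

    def sample_transcription(self) -> np.ndarray:
        """Binary transcription vector over recorded TUs (or all beads)."""
        from .transcription import detect_transcription

        return detect_transcription(
            self.state, self.fibre,
            rc_transcribe=self.config.transcription_cutoff,
            all_beads=self.config.record_all_beads)

    def mean_kinetic_energy(self) -> float:
        return float(0.5 * np.mean(np.sum(self.vel ** 2, axis=1)))


def run_simulation(fibre: ChromatinFibre, config: SimulationConfig, seed: int,
                   run_id: str = "run") -> SimResult:
    """Warm-up (push-off + equilibration, unrecorded) then production.

    Transcription is sampled every ``sample_interval`` tau_B; switching is
    attempted every ``switching.attempt_interval`` during equilibration and
    production.  Fully reproducible from (fibre, config, seed).
    """
    t0 = _time.time()
    sim = Simulation(fibre, config, seed)
    log = sim.log
    log.append(f"run_id={run_id} seed={seed} config={config.config_hash()} "
               f"n_particles={sim.pos.shape[0]}")
    # --- push-off: soft pair forces remove initial overlaps, no switching
    if config.warmup_pushoff > 0:
        sim.pushoff(config.warmup_pushoff)
        log.append(f"pushoff_done t={sim.state.time:g}")
    # --- equilibration + production on a shared event grid
    att = config.switching.attempt_interval
    samp = config.sample_interval
    n_samples = int(math.floor(config.production / samp + 1e-9))
    if config.record_all_beads:
        tu_idx = np.arange(fibre.n_beads)
    else:
        tu_idx = fibre.tu_indices
    samples = np.zeros((n_samples, tu_idx.shape[0]), dtype=np.uint8)
    kinetic = np.zeros(max(n_samples, 1))
    frames: list = []

    def maybe_frame():
        if config.traj_stride > 0:
            frames.append((sim.state.time, sim.pos.copy(), sim.tf_states.copy()))

    t_equil_end = sim.state.time + config.warmup_equil
    t_end = t_equil_end + n_samples * samp
    next_switch = sim.state.time + att
    next_sample = t_equil_end + samp
    next_frame = (t_equil_end if config.traj_stride > 0 else float("inf"))
    k = 0
    while sim.state.time < t_end - 1e-9:
        t_next = min(next_switch, next_sample, next_frame, t_end)
        step_tau = t_next - sim.state.time
        if step_tau > 1e-9:
            sim.advance(round(step_tau / config.thermostat.dt) * config.thermostat.dt)
        if abs(sim.state.time - next_switch) < 1e-6:
            flips = sim.attempt_switch()
            if flips:
                log.append(f"switch t={sim.state.time:g} flips={flips}")
            next_switch += att
        if abs(sim.state.time - next_sample) < 1e-6 and k < n_samples:
            samples[k] = sim.sample_transcription()
            kinetic[k] = sim.mean_kinetic_energy()
            k += 1
            next_sample += samp
        if abs(sim.state.time - next_frame) < 1e-6:
            maybe_frame()
            next_frame += config.traj_stride
    record = ActivityRecord(
        tu_indices=np.asarray(tu_idx),
        samples=samples[:k],
        sample_interval=samp,
        run_id=run_id,
        seed=seed,
    )
    log.append(f"done t={sim.state.time:g} samples={k} "
               f"wall={_time.time() - t0:.1f}s")
    return SimResult(record, sim.state, frames, kinetic[:max(k, 1)] if n_samples else
                     np.empty(0), log, config.config_hash(), seed)


def run_ensemble(fibre: ChromatinFibre, config: SimulationConfig,
                 base_seed: int, n_runs: int,
                 run_prefix: str = "run", n_procs: int = 1) -> list[SimResult]:
    """n_runs independent runs with per-run seeds base_seed + run_index.

    With n_procs > 1 runs are farmed out to worker processes, each
    single-threaded; per-run outputs are identical to the serial path.
    """
    args = [(fibre, config, base_seed + i, f"{run_prefix}{i:03d}")
            for i in range(n_runs)]
    if n_procs <= 1:
        return [run_simulation(*a) for a in args]
    import concurrent.futures as cf

    with cf.ProcessPoolExecutor(max_workers=n_procs) as pool:
        return list(pool.map(_run_one, args))


def _run_one(args):
    return run_simulation(*args)


def langevin_step(state: SystemState, fibre: ChromatinFibre,
                  params: InteractionParams, thermostat: ThermostatParams,
                  rng: np.random.Generator,
                  confinement: Confinement | None = None) -> SystemState:
    """One BAOAB step (convenience wrapper over the chunked engine)."""
    config = SimulationConfig(
        n_tf=state.positions.shape[0] - fibre.n_beads,
        params=params, thermostat=thermostat,
        confinement=confinement or Confinement.none(),
        warmup_pushoff=0.0, warmup_equil=0.0, production=0.0)
    sim = Simulation(fibre, config, seed=int(rng.integers(2 ** 31)), state=state)
    sim.advance(thermostat.dt)
    return sim.state


# ---------------------------------------------------------------------------
# trajectory output


def write_xyz(frames, fibre: ChromatinFibre, path) -> None:
    """Extended-XYZ text trajectory: per-particle type label and position."""
    labels = {0: "TU", 1: "EU", 2: "HET"}
    with open(path, "w") as fh:
        for t, pos, tf_states in frames:
            fh.write(f"{pos.shape[0]}\n")
            fh.write(f'Time={t:g} Properties=species:S:1:pos:R:3\n')
            for i in range(fibre.n_beads):
                lab = labels[int(fibre.bead_class[i])]
                fh.write(f"{lab} {pos[i, 0]:.5f} {pos[i, 1]:.5f} {pos[i, 2]:.5f}\n")
            for q in range(pos.shape[0] - fibre.n_beads):
                lab = "TFA" if tf_states[q] == TFState.ACTIVE else "TFI"
                j = fibre.n_beads + q
                fh.write(f"{lab} {pos[j, 0]:.5f} {pos[j, 1]:.5f} {pos[j, 2]:.5f}\n")


def write_hdf5(frames, fibre: ChromatinFibre, path, config_hash: str = "",
               seed: int = 0) -> None:
    """Binary trajectory container: positions, tf_states, time stamps."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["config_hash"] = config_hash
        fh.attrs["seed"] = seed
        fh.attrs["n_beads"] = fibre.n_beads
        fh.create_dataset("bead_class", data=np.asarray(fibre.bead_class))
        if frames:
            fh.create_dataset("time", data=np.array([f[0] for f in frames]))
            fh.create_dataset("positions",
                              data=np.stack([f[1] for f in frames]))
            fh.create_dataset("tf_states",
                              data=np.stack([f[2] for f in frames]))
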