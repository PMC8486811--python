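"""Declarative run configuration (flat key = value sections, INI syntax).

A config file fully determines an experiment: fibre preset or file, TF
counts and switching rates, interaction parameters, confinement, durations,
sampling strides, number of runs and base seed.  The parsed file is
serialised verbatim into the output directory and its hash is recorded in
every artefact header; per-run seeds are base_seed + run_index.
"""

from __future__ import annotations

import configparser
import hashlib
import io
import os
from dataclasses import dataclass, field

from .dynamics import SimulationConfig
from .fibre import ChromatinFibre, fibre_from_text, preset_fibre
from .params import (
    Confinement,
    ConfigurationError,
    InteractionParams,
    SwitchingParams,
    ThermostatParams,
)


@dataclass
class RunConfig:
    fibre_spec: str = "toy-wt"          # preset name or fibre file path
    n_runs: int = 10
    base_seed: int = 1
    out_dir: str = "chromodyn_out"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    raw_text: str = ""

    def config_hash(self) -> str:
        return hashlib.sha256(
            (self.raw_text or repr((self.fibre_spec, self.n_runs,
                                    self.base_seed, repr(self.sim)))).encode()
        ).hexdigest()[:12]

    def load_fibre(self) -> ChromatinFibre:
        if os.path.exists(self.fibre_spec):
            with open(self.fibre_spec) as fh:
                return fibre_from_text(fh.read())
        return preset_fibre(self.fibre_spec)


def _get(cp, section, key, cast, default):
    if cp.has_option(section, key):
        raw = cp.get(section, key)
        if cast is bool:
            return raw.strip().lower() in ("1", "true", "yes", "on")
        return cast(raw)
    return default


def parse_config(text: str) -> RunConfig:
    cp = configparser.ConfigParser()
    cp.read_string(text)
    base = SimulationConfig()
    ip = InteractionParams(
        eps_strong=_get(cp, "interaction", "eps_strong", float, 8.0),
        eps_weak=_get(cp, "interaction", "eps_weak", float, 3.0),
        rc_attr=_get(cp, "interaction", "rc_attr", float, 1.8),
        lp=_get(cp, "interaction", "lp", float, 3.0),
    )
    mode = _get(cp, "tf", "switching_mode", str, "toy")
    if mode == "toy":
        sw = SwitchingParams.toy()
    elif mode == "chromosome":
        sw = SwitchingParams.chromosome()
    else:
        sw = SwitchingParams(
            alpha_off=_get(cp, "tf", "alpha_off", float, 1e-5),
            alpha_on=_get(cp, "tf", "alpha_on", float, 1e-5),
        )
    kind = _get(cp, "confinement", "kind", str, "sphere")
    if kind == "none":
        conf = Confinement.none()
    elif kind == "sphere":
        conf = Confinement.sphere(_get(cp, "confinement", "radius", float, 25.0))
    elif kind == "ellipsoid":
        axes = tuple(float(v) for v in
                     cp.get("confinement", "semi_axes").split(","))
        conf = Confinement(kind="ellipsoid", semi_axes=axes)  # type: ignore[arg-type]
    else:
        raise ConfigurationError(f"unknown confinement kind {kind!r}")
    sim = SimulationConfig(
        n_tf=_get(cp, "tf", "n_tf", int, 20),
        params=ip,
        thermostat=ThermostatParams(
            dt=_get(cp, "durations", "dt", float, 0.01),
            seed=0),
        switching=sw,
        confinement=conf,
        warmup_pushoff=_get(cp, "durations", "warmup_pushoff", float,
                            base.warmup_pushoff),
        warmup_equil=_get(cp, "durations", "warmup_equil", float,
                          base.warmup_equil),
        production=_get(cp, "durations", "production", float, base.production),
        sample_interval=_get(cp, "durations", "sample_interval", float, 100.0),
        traj_stride=_get(cp, "durations", "traj_stride", float, 0.0),
        record_all_beads=_get(cp, "output", "record_all_beads", bool, False),
    )
    return RunConfig(
        fibre_spec=_get(cp, "fibre", "spec", str, "toy-wt"),
        n_runs=_get(cp, "run", "n_runs", int, 10),
        base_seed=_get(cp, "run", "base_seed", int, 1),
        out_dir=_get(cp, "output", "out_dir", str, "chromodyn_out"),
        sim=sim,
        raw_text=text,
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(fh.read())


def dump_config(cfg: RunConfig) -> str:
    """Round-trippable text for a RunConfig built programmatically."""
    if cfg.raw_text:
        return cfg.raw_text
    s = cfg.sim
    buf = io.StringIO()
    buf.write("[fibre]\n")
    buf.write(f"spec = {cfg.fibre_spec}\n\n")
    buf.write("[run]\n")
    buf.write(f"n_runs = {cfg.n_runs}\nbase_seed = {cfg.base_seed}\n\n")
    buf.write("[tf]\n")
    buf.write(f"n_tf = {s.n_tf}\n")
    buf.write(f"alpha_off = {s.switching.alpha_off}\n")
    buf.write(f"alpha_on = {s.switching.alpha_on}\n\n")
    buf.write("[interaction]\n")
    buf.write(f"eps_strong = {s.params.eps_strong}\n")
    buf.write(f"eps_weak = {s.params.eps_weak}\n\n")
    buf.write("[confinement]\n")
    if s.confinement.kind == "none":
        buf.write("kind = none\n\n")
    else:
        a, b, c = s.confinement.semi_axes
        if a == b == c:
            buf.write(f"kind = sphere\nradius = {a}\n\n")
        else:
            buf.write(f"kind = ellipsoid\nsemi_axes = {a},{b},{c}\n\n")
    buf.write("[durations]\n")
    buf.write(f"warmup_pushoff = {s.warmup_pushoff}\n")
    buf.write(f"warmup_equil = {s.warmup_equil}\n")
    buf.write(f"production = {s.production}\n")
    buf.write(f"sample_interval = {s.sample_interval}\n\n")
    buf.write("[output]\n")
    buf.write(f"out_dir = {cfg.out_dir}\n")
    buf.write(f"record_all_beads = {s.record_all_beads}\n")
    return buf.getvalue()
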