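"""Parameter containers and unit conventions.

Reduced units throughout: the bead diameter sigma is the length unit
(30 nm ~ 3 kbp of chromatin), kBT the energy unit, and the Brownian time
tau_B = sigma^2/D the time unit (0.6--6 ms depending on the assumed
nucleoplasm viscosity).  Masses and frictions are 1, so tau_LJ = tau_B.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class ChromodynError(Exception):
    """Base class for all package errors."""


class GeometryError(ChromodynError):
    """Invalid geometry handed to a potential (non-positive separation etc.)."""


class OverstretchError(ChromodynError):
    """A FENE bond reached its maximum extension R0; the run must abort."""


class ConfigurationError(ChromodynError):
    """Inconsistent or out-of-range configuration."""


class BeadClass(enum.IntEnum):
    """Binding class of a chromatin bead.

    TU beads carry high-affinity TF binding sites (8 kBT), euchromatin binds
    active TFs weakly (3 kBT), heterochromatin does not bind at all.
    """

    TU = 0
    EUCHROMATIN = 1
    HETEROCHROMATIN = 2


class TFState(enum.IntEnum):
    ACTIVE = 0
    INACTIVE = 1


#: Particle-class codes used by the compiled kernels: chromatin beads keep
#: their BeadClass value, TFs are appended after the chain.
TF_ACTIVE_CODE = 3
TF_INACTIVE_CODE = 4

RC_REP_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class InteractionParams:
    """Force-field parameters (reduced units).

    Defaults are the published parameterisation: WCA repulsion between all
    particles, FENE backbone springs (Kf = 30 kBT/sigma^2, R0 = 1.6 sigma),
    harmonic springs for looped chains (Kh = 100 kBT/sigma^2, Rbar = 1.1
    sigma backbone / 1.8 sigma loop), a Kratky-Porod bending term with
    lp = 3 sigma, and truncated-shifted Lennard-Jones TF-chromatin
    attraction with cutoff 1.8 sigma (well depth 8 kBT for TUs, 3 kBT for
    euchromatin).
    """

    sigma: float = 1.0
    kBT: float = 1.0
    eps_strong: float = 8.0
    eps_weak: float = 3.0
    rc_attr: float = 1.8
    Kf: float = 30.0
    R0: float = 1.6
    Kh: float = 100.0
    Rbar_backbone: float = 1.1
    Rbar_loop: float = 1.8
    lp: float = 3.0

    @property
    def rc_rep(self) -> float:
        """Repulsive (WCA) cutoff, exactly 2^(1/6) sigma."""
        return RC_REP_FACTOR * self.sigma

    def __post_init__(self) -> None:
        for name in ("sigma", "rc_attr", "Kf", "R0", "Kh",
                     "Rbar_backbone", "Rbar_loop", "lp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.eps_strong < self.eps_weak or self.eps_weak < 0:
            raise ConfigurationError("need eps_strong >= eps_weak >= 0")
        if self.R0 <= self.sigma:
            raise ConfigurationError("FENE R0 must exceed sigma")


@dataclass(frozen=True)
class ThermostatParams:
    """Langevin thermostat: dt = 0.01 tau_B, gamma = 1, T = kBT in reduced units."""

    dt: float = 0.01
    gamma: float = 1.0
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.gamma < 0 or self.temperature < 0:
            raise ConfigurationError("gamma and temperature must be >= 0")


@dataclass(frozen=True)
class SwitchingParams:
    """Two-state TF switching, attempted every 100 tau_B (10,000 steps).

    The off rate is alpha_off = 1e-5 per tau_B.  In toy mode alpha_on equals
    alpha_off (half the TFs active on average); in whole-chromosome mode
    alpha_on = alpha_off / 4 (20% active on average).
    """

    alpha_off: float = 1e-5
    alpha_on: float = 1e-5
    attempt_interval: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha_off < 0 or self.alpha_on < 0:
            raise ConfigurationError("switching rates must be >= 0")
        if self.attempt_interval <= 0:
            raise ConfigurationError("attempt_interval must be positive")
        if (self.alpha_off * self.attempt_interval > 1.0
                or self.alpha_on * self.attempt_interval > 1.0):
            raise ConfigurationError(
                "switching probability per attempt exceeds 1; reduce rates or interval")

    @property
    def stationary_active_fraction(self) -> float:
        tot = self.alpha_on + self.alpha_off
        if tot == 0:
            return float("nan")
        return self.alpha_on / tot

    @classmethod
    def toy(cls) -> "SwitchingParams":
        return cls(alpha_off=1e-5, alpha_on=1e-5)

    @classmethod
    def chromosome(cls) -> "SwitchingParams":
        return cls(alpha_off=1e-5, alpha_on=0.25e-5)


@dataclass(frozen=True)
class Confinement:
    """Confining territory: none, or an ellipsoid with semi-axes a >= b >= c.

    A sphere is the special case a = b = c.  The wall repels with a WCA-like
    force along the scaled-radius normal; particles are initialised strictly
    inside.
    """

    kind: str = "none"
    semi_axes: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "ellipsoid"):
            raise ConfigurationError(f"unknown confinement kind {self.kind!r}")
        if self.kind == "ellipsoid":
            a, b, c = self.semi_axes
            if not (a >= b >= c > 0):
                raise ConfigurationError("ellipsoid needs semi-axes a >= b >= c > 0")

    @classmethod
    def sphere(cls, radius: float) -> "Confinement":
        return cls(kind="ellipsoid", semi_axes=(radius, radius, radius))

    @classmethod
    def none(cls) -> "Confinement":
        return cls(kind="none")

    def volume(self) -> float:
        if self.kind != "ellipsoid":
            return float("inf")
        import math

        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c
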